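"""Full pipeline on a synthetic survey: preprocess, classify, diagnose.

Generates a 47-cultivar survey in signal mode (yield declines with
compositional distance from each cultivar's optimum), discretizes yield per
cultivar at the 65th percentile, trains the three classifier families,
tests them against a random classifier, and diagnoses one imbalanced test
specimen against the bank of true-negative references.
"""

import numpy as np

import ionodiag as io
from ionodiag.coda import PARTS, close
from ionodiag.pipeline import add_compositions, discretize_yield
from ionodiag.classify import random_classifier_test

cfg = io.GeneratorConfig(seed=42)
df, truth = io.generate_dataset(io.sample_cultivar_params(cfg), cfg)
print(f"survey: {len(df)} records, {df['cultivar'].nunique()} cultivars")

labelled, _ = add_compositions(df)
labelled, cutoffs = discretize_yield(labelled)
labelled = labelled.dropna(subset=["yield_class"])
print(f"yield cut-offs range {cutoffs['cutoff'].min():.1f}–"
      f"{cutoffs['cutoff'].max():.1f} Mg ha⁻¹; "
      f"{(labelled['yield_class'] == 'high').mean():.0%} high-yielders")

train, test = io.split_by_cultivar(labelled, seed=cfg.seed)
models = {}
for algo in ("knn", "rf", "svm"):
    model = io.train_classifier(train, algo, seed=cfg.seed)
    report = io.evaluate(model, test)
    models[algo] = (model, report)
    stat, p = random_classifier_test(report.counts)
    print(f"{algo:<4} CV accuracy {model.cv_accuracy:.3f}  "
          f"test accuracy {report.accuracy:.3f} "
          f"({report.counts.n_correct}/{report.counts.total}; "
          f"χ² vs coin flip = {stat:.1f}, p = {p:.2e})")

best = io.select_best_model([m for m, _ in models.values()])
report = models[best.algorithm][1]
print(f"\nbest model by CV accuracy: {best.algorithm}")

imp = io.permutation_importance(best, test, repeats=10, seed=cfg.seed)
print("permutation importance (accuracy drop on the test set):")
for e in imp:
    flag = "  (negligible)" if e.negligible else ""
    print(f"  {e.feature:<7} {e.importance:+.3f}{flag}")

bank = io.build_reference_bank(best, train)
print(f"\nreference bank: {len(bank)} true negatives, "
      f"{len(bank.cultivars)} cultivars")

worst = test.loc[test["yield_class"] == "low"].iloc[0]
query = close(worst.loc[list(PARTS)].to_numpy(dtype=float), PARTS)
result = io.diagnose(query, bank, cultivar=worst["cultivar"])
print(f"diagnosis of one low-yield specimen ({worst['cultivar']}, "
      f"{result.scope}): distance {result.distance:.3f}")
print("  corrective perturbation:", np.round(result.perturbation.values, 4))
for e in result.ranking[:3]:
    print(f"  {e.part}: apparently {e.status} (|clr delta| {e.magnitude:.3f})")
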