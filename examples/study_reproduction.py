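"""Reproduce the survey-scale summaries on the real potato data set.

The Québec potato leaf survey (raw_leaf_df.csv, distributed with the study
as supplementary data) is not bundled here; download it separately and pass
its path. The script reruns the pipeline: per-cultivar 65th-percentile
discretization (reporting the mean marketable yield of each class and the
extreme cut-offs) and the mean test accuracy of the three classifier
families over several split seeds.

Usage:  python examples/study_reproduction.py /path/to/raw_leaf_df.csv
"""

import sys

import numpy as np

import ionodiag as io
from ionodiag.pipeline import add_compositions, discretize_yield, filter_records

if len(sys.argv) != 2:
    sys.exit(__doc__)

# the survey file uses per-cent concentrations and its own column names;
# adjust the mapping to the local copy if headers differ
df, rejects = io.read_ionome_table(
    sys.argv[1],
    schema={"trial_id": "NoEssai", "cultivar": "Cultivar",
            "maturity_class": "Maturity5", "yield_mg_ha": "RendVendable",
            "N": "PCN", "P": "PCP", "K": "PCK", "Mg": "PCMg", "Ca": "PCCa"},
    nutrient_unit="percent",
)
print(f"{len(df)} records read, {len(rejects)} rejected rows")

filtered, _ = filter_records(df)
labelled, _ = add_compositions(filtered)
labelled, cutoffs = discretize_yield(labelled)
labelled = labelled.dropna(subset=["yield_class"])

high = labelled.loc[labelled["yield_class"] == "high", "yield_mg_ha"]
low = labelled.loc[labelled["yield_class"] == "low", "yield_mg_ha"]
print(f"mean marketable yield: high {high.mean():.1f} Mg/ha, "
      f"low {low.mean():.1f} Mg/ha")
print(f"per-cultivar cut-offs: min {cutoffs['cutoff'].min():.1f}, "
      f"max {cutoffs['cutoff'].max():.1f} Mg/ha")

accs = []
for seed in range(20):
    train, test = io.split_by_cultivar(labelled, seed=seed)
    model = io.train_classifier(train, "knn", seed=seed)
    accs.append(io.evaluate(model, test).accuracy)
print(f"kNN test accuracy over 20 split seeds: "
      f"mean {np.mean(accs):.3f} ± {np.std(accs):.3f}")
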