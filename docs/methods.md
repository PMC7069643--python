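# Methods

## The model

A leaf ionome is treated as a 6-part composition `(N, P, K, Mg, Ca, Fv)` on
the simplex, where the filling value `Fv = 1 − ΣNutrients` amalgamates all
unquantified dry matter. All statistics are computed on centred log-ratios,
`clr_i = ln(x_i / g(x))` with the geometric mean taken over all six parts.
The clr image is a sum-zero vector, so the six clr variables carry five
degrees of freedom; Euclidean distance between clr images is the Aitchison
distance, the natural metric of the simplex and the one invariant under
perturbation (the simplex's translation, `A ⊕ B = C(a·b)`).

The diagnostic premise is that nutritionally balanced, high-yield-potential
compositions form pockets in clr space. Operationally, *balanced* means a
training specimen that is observed high-yielding **and** predicted
high-yielding by the most accurate classifier (a true negative under the
medical polarity positive = low yield = intervention needed). Diagnosis of
a new specimen is nearest-neighbour search in that bank under the Aitchison
metric, and the prescription is the perturbation vector `C(reference /
observed)` — exact by construction: applying it with ⊕ reproduces the
reference. The sign of each nutrient's clr difference (reference −
observed) labels it apparently deficient (positive) or in excess
(negative); magnitudes rank the corrections.

### Conventions with substantive effect

- **Distances for diagnosis use the 5-nutrient subcomposition** (Fv
  excluded); perturbation vectors use all six parts. Recomputing the
  published worked example from its printed compositions gives 1.1417 on
  five parts versus 1.2272 on six against a printed 1.135 — only the
  5-part reading is consistent. The 6-part distance remains available via
  the `parts` argument.
- **Part order** is fixed once as `(N, P, K, Mg, Ca, Fv)`.
- **No zero replacement** anywhere in the algebra: upstream filtering must
  guarantee strictly positive parts, mirroring a survey in which
  unquantified nutrients are filtered, never imputed.
- **Yield classes**: per cultivar, the cut-off is the 65th percentile of
  marketable yield with linear interpolation between order statistics
  (`numpy.percentile` default, matching the common statistical-environment
  default); strictly-above goes to `high`, the cut-off value itself to
  `low`. Cultivars with one record are left unlabelled.
- **The 20 % clr increase** in the perturbation simulation is
  multiplicative on the *signed* clr value (×1.2), so components below the
  geometric mean move further down — this reproduces the characteristic
  drop of the P proportion when "increasing" P's clr. An additive reading
  (+0.2 log units) is available via `mode="additive"`.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `percentile` | 65 | per-cultivar yield cut-off (percent) |
| `alpha` | 0.01 | Mahalanobis outlier significance in clr space |
| `train_fraction` | 0.75 | per-cultivar training share |
| `folds` | 10 | CV folds for hyperparameter selection |
| kNN grid | k ∈ {3,5,…,21} | neighbourhood sizes |
| RF grid | 500 trees, max_features ∈ {1,2,3} | per-split candidate features |
| SVM grid | C ∈ {0.25,…,4}, RBF | kernel width from the median heuristic |

Outlier screening uses the classical Mahalanobis distance against the
chi-square quantile at `1 − alpha` on the clr matrix with one coordinate
dropped (the sum-zero constraint makes the full covariance singular; a
pseudo-inverse fallback handles degenerate inputs). Robust-estimator
variants with adaptive quantiles exist and flag more points on heavy-tailed
data; their exact counts are estimator-specific and not reproduced here.

DBSCAN parameters default to `minPts = 7` (clr dimension + 1) with `eps`
from the knee (maximum chord deviation) of the sorted 6-NN distance curve;
clustering operates on record-level clr vectors of the high-yield subset.
Class imbalance from the 65/35 discretization is deliberately left
unadjusted in training.

Permutation importance is the mean accuracy drop over repeated shuffles of
one feature. A feature is flagged *negligible* when its importance is below
`max(2·SE over repeats, 1/√n)`: an accuracy estimated on `n` rows cannot
resolve differences below its own sampling noise, and the repeats-SE alone
grossly understates that. For unbiased readings, compute importance on data
the model was not fitted to — on the training set itself a forest assigns
small positive importance to memorised noise.

## Synthetic surveys

The generator draws, per cultivar, an optimal composition (a Gaussian
clr-space displacement of scale `separation = 0.15` from a typical potato
leaf centre: N 5.8 %, P 0.40 %, K 5.0 %, Mg 0.45 %, Ca 1.0 %, Fv ≈ 0.87), a
random sum-zero-constrained clr covariance with component scale
`clr_sd = 0.2`, a long-tailed sample size (log-normal(3, 1), clipped to
[2, 300]), and a yield model
`yield = intercept − 35 · d₅(x, optimum) + N(0, 3²)` Mg ha⁻¹, floored at 0,
with intercepts ~N(45, 8²). `d₅` is the 5-nutrient Aitchison distance, so
the yield link respects the same convention as the diagnosis. In `null`
mode the slope is 0. The default effect size was calibrated once so the
full pipeline's held-out accuracy sits near 0.70 (measured mean 0.708 over
six seeds for kNN), the regime a well-powered field survey supports.

What the generator emulates: unequal cultivar coverage, overlapping
cultivar clouds (no separable ionomic islands), logistic-normal scatter,
and a monotone yield–imbalance link. What it does not: measurement-method
differences, site/weather/management confounders, non-Gaussian clr tails,
and correlated trial effects. Green tests on synthetic data therefore
demonstrate that the machinery recovers structure *of the assumed form*;
they do not validate the agronomic assumptions on real surveys.

## Numerical choices and edge cases

- Algebraic identities are asserted at 1e-9; worked-example comparisons at
  ±0.002 per proportion and ±0.02 in distance, the scatter induced by
  4-decimal rounding of the printed inputs.
- Compositions are validated (positive, unit sum within 1e-9); closure is
  the only constructor from raw positive data. clr inversion rejects
  |clr| > 500 to avoid overflow.
- Nearest-reference ties break toward the smallest reference id (bank rows
  are kept id-sorted). Same-cultivar search falls back to the global bank
  with an explicit cross-cultivar flag when the cultivar has no reference.
- The CSV reader parses numerics with Python `float` for bit-exact
  round-trips of generated data; unparseable cells reject the row into a
  reports table rather than silently coercing.
- Duplicate rows in outlier screening exercise the pseudo-inverse path; a
  constant PCA column is excluded with a warning.

## Known limitations

- The no-information check on accuracy is prior-dependent: under the 65/35
  class split a majority-collapsed classifier reaches ~0.65 raw accuracy
  with zero information. Balanced accuracy (≈0.5 in null mode) is the
  meaningful chance-level reference; raw accuracy is not.
- The true-negative bank inherits classifier errors: false negatives can
  enter it, and small-sample cultivars may contribute none.
- Perturbation vectors are compositional prescriptions; translating them
  into fertilizer doses is out of scope.
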