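"""Density-based clustering and PCA of high-yield ionomes in clr space.

On overlapping cultivar clouds (the realistic default) DBSCAN finds a
single dense region — cultivars do not separate into ionomic islands —
while the PCA biplot shows which clr variables drive the scatter.
"""

import numpy as np

import ionodiag as io
from ionodiag.pipeline import add_compositions, clr_matrix, discretize_yield

cfg = io.GeneratorConfig(seed=7)
df, _ = io.generate_dataset(io.sample_cultivar_params(cfg), cfg)
labelled, _ = add_compositions(df)
labelled, _ = discretize_yield(labelled)
high = labelled.loc[labelled["yield_class"] == "high"]
x = clr_matrix(high)
print(f"clustering {len(high)} high-yield records, "
      f"{high['cultivar'].nunique()} cultivars")

eps, curve = io.suggest_eps(x, min_pts=7)
print(f"suggested eps from the 7-NN distance knee: {eps:.3f}")

result = io.dbscan_cluster(x, eps=eps, min_pts=7)
print(f"DBSCAN: {result.n_clusters} cluster(s), {result.n_noise} noise points")
# overlapping cultivars -> one dense region, no cultivar partition

biplot = io.pca_biplot(x, columns=io.CLR_COLUMNS)
evr = biplot.explained_variance_ratio
print(f"PCA explained variance: PC1 {evr[0]:.1%}, PC2 {evr[1]:.1%}")
print("correlation loadings on PC1:")
for name, row in zip(biplot.columns, biplot.loadings):
    print(f"  {name:<7} {row[0]:+.2f}")
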