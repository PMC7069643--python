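"""Ripple effect of increasing N and P clr values by 20 %.

Because the simplex is closed, changing the clr coordinates of two
components moves every proportion. Notably, when a component's clr value is
negative (below the geometric mean), multiplying it by 1.2 pushes it
further down: its proportion *decreases* even though its clr value was
"increased".
"""

import numpy as np

import ionodiag as io
from ionodiag.coda import PARTS, close, clr_transform
from ionodiag.pipeline import add_compositions

cfg = io.GeneratorConfig(seed=3)
df, _ = io.generate_dataset(io.sample_cultivar_params(cfg), cfg)
labelled, _ = add_compositions(df)
sample = labelled.sample(n=200, random_state=0)

offsets = {p: [] for p in PARTS}
for _, row in sample.iterrows():
    comp = close(row.loc[list(PARTS)].to_numpy(dtype=float), PARTS)
    _, off = io.simulate_clr_perturbation(comp, ("N", "P"), factor=1.2)
    for p in PARTS:
        offsets[p].append(off[p])

print("mean proportion offset (new − old) after ×1.2 on clr_N and clr_P:")
for p in PARTS:
    print(f"  {p:<3} {np.mean(offsets[p]):+.5f}")

frac_p_down = np.mean([o < 0 for o in offsets["P"]])
print(f"\nP proportion decreased in {frac_p_down:.0%} of specimens "
      "(P's clr value is typically negative, so ×1.2 lowers it)")
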