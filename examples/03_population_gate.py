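"""Gate the HSC population with a PCA+LDA plane and report gate fractions.

Runs the full demo pipeline (simulate -> phasor -> extract -> gate), then
prints the fraction of each population on the HSC side of the plane and the
population centroids in MOB space.
"""

import tempfile

from mobflim.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    seed=3,
    acquisition={"frame_shape": [200, 200]},
    populations=[{"name": "HSC", "n_cells": 30},
                 {"name": "LinNegCD45", "n_cells": 30},
                 {"name": "CD45", "n_cells": 30}],
    gate={"target": "HSC", "features": "all"},
)
with tempfile.TemporaryDirectory() as tmp:
    report = run_pipeline(cfg, tmp)

print("explained variance of the top-3 PCs:",
      [round(v, 3) for v in report["gate"]["explained_variance_ratio"]])
print("fraction of cells on the HSC side of the LDA plane:")
for pop, frac in sorted(report["gate"]["target_side_fraction"].items()):
    print(f"  {pop:>12}: {100 * frac:5.1f}%")
print()
print("A high HSC fraction with near-zero off-target fractions means the")
print("five-MOB profile linearly separates stem cells from the rest.")
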