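"""Track tau_bound in paired single cells before and after LDH inhibition.

The generator's perturbation model shifts each cell's bound-NAD(P)H
lifetime by delta = a + b*tau_initial + noise; pairing pre/post tables by
cell id and regressing delta on the initial value recovers the response
slope -- the same analysis used to show that cells with a longer initial
tau_bound lose more of it when lactate dehydrogenase is inhibited.
"""

import pandas as pd

import mobflim as mf
from mobflim.features import paired_delta
from mobflim.presets import preset_spec
from mobflim.synthetic import apply_perturbation, sample_population

cells = sample_population(preset_spec("HSC", 200), seed=4)
post = apply_perturbation(
    cells, mf.PerturbationModel(intercept=0.2, slope=-0.1, noise_sd=0.02), seed=5)

pre_df = pd.DataFrame({"cell_id": [c.cell_id for c in cells],
                       "tau_bound_ns": [c.tau_bound_true for c in cells]})
post_df = pd.DataFrame({"cell_id": [c.cell_id for c in post],
                        "tau_bound_ns": [c.tau_bound_true for c in post]})
paired, fit = paired_delta(pre_df, post_df)

print(f"mean tau_bound before: {pre_df['tau_bound_ns'].mean():.3f} ns")
print(f"mean tau_bound after:  {post_df['tau_bound_ns'].mean():.3f} ns")
print(f"regression of delta on initial tau_bound over {fit['n']} cells:")
print(f"  slope {fit['slope']:+.3f} (true -0.100), "
      f"intercept {fit['intercept']:+.3f} ns, r = {fit['pearson_r']:.2f}")
print()
print("The negative slope means cells starting with a longer tau_bound drop")
print("further under inhibition, as expected if tau_bound reports LDH activity.")
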