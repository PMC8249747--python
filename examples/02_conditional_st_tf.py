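"""A conditional single-target TF: one site without effector, a dozen with.

Mirrors response regulators whose unmodified form binds a single spacer but
whose activated form recognizes many targets: the screen is run once per
effector state and the per-state classifications are combined.
"""

import gselex as gx
from gselex.selex import SelexParams

scen = gx.conditional_scenario(seed=11)
per_state = []
for i, state in enumerate(sorted(scen.aff.sites_by_state)):
    res = gx.run_tf_assay(
        scen.ann, scen.aff.with_state(state),
        SelexParams(cycles=4, seed=11), noise_sd=0.1, seed=11 + i,
    )
    cls = gx.classify_tf(res.n_targets, n_sites=len(res.peaks), effector_state=state)
    per_state.append(cls)
    print(f"state {state:>14}: {len(res.peaks)} peaks, "
          f"{res.n_targets} distinct targets -> {cls.group}")

combined = gx.classify_conditional(per_state)
print(f"\nconditional ST-TF: {combined.conditional_st} "
      f"(single-target form: {combined.effector_state})")
# Expect: ST in the apo state, local with effector, conditional flag True.
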