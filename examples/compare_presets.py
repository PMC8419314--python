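"""Compare the micro-dynamics of the five bundled mechanism templates.

Each preset is simulated under the 17-pulse protocol at its own
concentration series and pushed through the full analysis.  The printed
table shows how compounds with similar equilibrium affinities can differ
radically in the millisecond-scale dynamics of their effect.
"""

import numpy as np

import eipkit as ek
from eipkit.pipeline import RunConfig, analyze_measurement, simulate_measurement


def describe(name):
    mech = ek.compound_preset(name)
    mech.perfusion_tau_s = min(mech.perfusion_tau_s, 3.0)  # keep the demo short
    cfg = RunConfig(
        mechanism=mech, concentrations_uM=ek.preset_concentrations_uM(name),
        seed=5,
    )
    exp = simulate_measurement(cfg)
    summary, curves = analyze_measurement(exp.amplitudes, cfg, measurement_id=name)
    off = summary.micro_offset
    offset = (
        f"{off.t_lo_snapped_ms:g}-{off.t_hi_snapped_ms:g} ms"
        if off is not None and off.detectable else "flat"
    )
    return summary, offset


print(f"{'preset':<18} {'K_R (uM)':>10} {'K_I (uM)':>9} {'K_R/K_I':>8} "
      f"{'micro-offset':>14}")
for name in sorted(ek.COMPOUND_PRESETS):
    s, offset = describe(name)
    print(f"{name:<18} {s.K_R:>10.3g} {s.K_I:>9.3g} {s.ratio:>8.3g} {offset:>14}")

print()
print("High K_R/K_I with a fast micro-offset (riluzole-like) favors")
print("high-frequency-selective inhibition; slow micro-dynamics")
print("(bupivacaine-like) compresses the observable potency range; a nearly")
print("state-independent pore blocker (TTX-like) shows a flat landscape.")
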