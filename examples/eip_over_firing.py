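"""Overlay effective inhibitor potency on a 25 Hz firing pattern.

Micro-onset (SDO curve) is triggered by each action-potential upstroke,
micro-offset (RFI curve) by each repolarization.  The printed numbers show
how much potency a fast-offset compound loses between spikes.
"""

import numpy as np

import eipkit as ek
from eipkit.pipeline import RunConfig, analyze_measurement, simulate_measurement

mech = ek.CompoundMechanism(
    name="fast_offset", k_on=1 / 30, K_R=1000.0, K_I=10.0, perfusion_tau_s=2.0
)
config = RunConfig(mechanism=mech, concentrations_uM=(3.0, 10.0, 30.0, 100.0),
                   seed=11)
exp = simulate_measurement(config)
_, curves = analyze_measurement(exp.amplitudes, config, measurement_id="demo")

# 25 Hz train: upstrokes every 40 ms, repolarization 4 ms after each upstroke
upstrokes = [0.0, 40.0, 80.0]
repolarizations = [4.0, 44.0, 84.0]
tc = ek.overlay_eip(curves["SDO"], curves["RFI"], upstrokes, repolarizations,
                    dt_ms=0.2)

for t_up in upstrokes:
    just_after = tc.ic50[np.searchsorted(tc.times_ms, t_up + 3.8)]
    before_next = tc.ic50[np.searchsorted(tc.times_ms, t_up + 39.5)]
    print(f"upstroke at {t_up:5.1f} ms: IC50 ~{just_after:7.1f} uM during the "
          f"spike, ~{before_next:7.1f} uM just before the next spike")

print()
print("Low IC50 = high potency.  The compound becomes potent during each")
print("depolarization but releases the channel within tens of ms of")
print("repolarization, so at 25 Hz it re-arms between spikes - the signature")
print("of a use-dependent inhibitor selective for high firing rates.")
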