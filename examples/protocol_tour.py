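"""Tour of the 17-pulse SDO/RFI/SSI voltage protocol.

Builds the default 1 Hz protocol and prints, for each test pulse, its
section membership and the x-axis value used for effective-inhibitor-potency
plots (conditioning duration, preceding gap, or holding potential).
"""

import eipkit as ek

protocol = ek.build_seventeen_pulse_protocol()
print(f"segments: {len(protocol.segments)}, "
      f"active time {protocol.total_segment_ms():.0f} ms "
      f"of a {protocol.sweep_period_ms:.0f} ms sweep (1 Hz)\n")

print(f"{'pulse':>5}  {'sections':<10} {'x-axis'}")
for p in range(1, 18):
    cond = ek.condition_of(protocol, p)
    xs = []
    if cond.conditioning_ms is not None:
        xs.append(f"conditioning {cond.conditioning_ms:g} ms")
    if cond.gap_ms is not None:
        xs.append(f"gap {cond.gap_ms:g} ms")
    if cond.holding_mV is not None:
        xs.append(f"holding {cond.holding_mV:g} mV")
    tag = "+".join(cond.sections)
    base = " (rested baseline)" if cond.is_rested_baseline else ""
    print(f"{p:>5}  {tag:<10} {'; '.join(xs)}{base}")

print()
print("SDO pulses probe how inhibition develops during depolarizations of")
print("increasing length; RFI pulses probe how it dissipates during")
print("hyperpolarizing gaps; SSI pulses probe the resting-inactivated")
print("equilibrium at different holding potentials.")
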