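"""Experimental-design utilities: ensemble QC filtering and power analysis.

Applies the four exclusion rules to a mock plate of 12 cell ensembles, keeps
the best six by seal resistance, and reports the detectable effect size at
that sample size.
"""

import pandas as pd

from eipkit import power_detectable_effect, qc_filter

metrics = pd.DataFrame(
    {
        "ensemble_id": [f"ens{i:02d}" for i in range(12)],
        "control_amplitude_nA": [1.4, 3.8, 4.1, 5.0, 2.9, 3.3, 4.6, 2.5,
                                 3.9, 4.4, 3.1, 2.8],
        "seal_resistance_MOhm": [150, 70, 180, 160, 140, 130, 175, 95,
                                 165, 110, 145, 120],
        "seal_loss_pct": [3, 4, 28, 6, 8, 5, 2, 9, 4, 7, 6, 5],
        "sudden_drop": [False, False, False, True, False, False, False,
                        False, False, False, False, False],
    }
)

result = qc_filter(metrics, n_select=6)
excluded = result.table[result.table["reason"] != ""]
print("excluded ensembles:")
for r in excluded.itertuples():
    print(f"  {r.ensemble_id}: {r.reason}")
print(f"included (best {len(result.included)} by seal resistance): "
      f"{', '.join(result.included)}")

power = power_detectable_effect(n=len(result.included), effect_sd=2.0, alpha=0.05)
print(f"\nwith n = {len(result.included)} per group, a 2-SD effect is detected "
      f"with power {power:.2f} at p < 0.05")
print("(0.80 is the conventional adequacy threshold)")
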