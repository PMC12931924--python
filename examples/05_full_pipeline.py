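"""The full laminar variability analysis on one synthetic session.

Gates units (responsiveness + size tuning), measures Fano-factor and
shared-variance size tuning, fits the tuning functions, and prints the
per-layer report of median % changes.
"""

from lamvar import RunConfig, make_report, run_full_analysis
from lamvar.pipeline import layer_sign_summary

cfg = RunConfig(seed=7, n_penetrations=2, channels_per_penetration=24,
                n_diameters=10, trials_per_diameter=40,
                rate_restarts=4, double_restarts=2)
summary, per_unit = run_full_analysis(cfg)
print(make_report(summary))

signs = layer_sign_summary(summary)
print("laminar sign pattern vs generator ground truth:")
for key, val in signs.items():
    if key == "all_match":
        continue
    print(f"  {key:12s} median {val['median']:+7.1f}%  "
          f"matches={val['matches']}")
print(f"all contrasts match: {signs['all_match']}")
# SG far-surround stimulation amplifies variability and shared variability,
# IG near-surround stimulation quenches both, and G stays flat beyond the RF.
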