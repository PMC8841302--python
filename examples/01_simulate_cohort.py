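"""Simulate a small synthetic cohort and inspect its clinical structure.

Each subject gets six-ROI epoched time series with alpha->gamma coupling
along the two amygdala pathways, plus a HAM-D-6 outcome linked to the
subject's coupling depth. Patient labels follow the >= 50% reduction rule.
"""

import numpy as np

from megpac import SimulationConfig, simulate_cohort

config = SimulationConfig(
    n_responder=6, n_nonresponder=6, n_hc=4,
    n_trials=10, epoch_len_s=1.0, fs=600.0, seed=7,
)
roi_list, records = simulate_cohort(config)

print(f"cohort of {len(records)} subjects; tensor shape per subject:", roi_list[0].data.shape)
for group in ("responder", "non_responder", "HC"):
    n = sum(r.group == group for r in records)
    print(f"  {group:14s} n={n}")

print("\nfirst patient:")
r = records[0]
print(f"  id={r.id} group={r.group} HAM-D-6 {r.hamd6_baseline:.0f} -> {r.hamd6_endpoint:.0f}"
      f"  reduction ratio={r.reduction_ratio:.2f}  true kappa={r.true_kappa:.2f}")

ratios = [r.reduction_ratio for r in records if r.group != "HC"]
kappas = [r.true_kappa for r in records if r.group != "HC"]
print(f"\ncorrelation(kappa, reduction ratio) over patients: "
      f"{np.corrcoef(kappas, ratios)[0, 1]:.2f}")
print("-> higher injected coupling depth tracks larger symptom improvement,")
print("   the statistical link the analysis is supposed to recover.")
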