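"""End-to-end run: simulate -> comodulograms -> cluster test -> prediction.

A default-sized cohort (33 non-responders / 32 responders / 29 controls)
is pushed through the whole pipeline; per-subject cluster strengths are
correlated with HAM-D-6 reduction ratios and combined into an in-sample
ROC classifier of non-response.
"""

from megpac.pipeline import CfcBlock, RunConfig, SimulationBlock, StatsBlock, run_all

config = RunConfig(
    seed=3,
    simulation=SimulationBlock(epoch_len_s=0.5),   # analysis ends at 200 ms
    cfc=CfcBlock(amp_freqs=(30.0, 80.0, 2.0)),     # gamma band used for stats
    stats=StatsBlock(n_permutations=500),
)
report = run_all(config)

print("group sizes:", report.group_sizes)
for path in report.pathways:
    ps = ", ".join(f"{p:.3f}" for p in report.cluster_p[path])
    r, p = report.feature_correlations[path]
    print(f"\npathway {path}")
    print(f"  cluster p-values: [{ps}]")
    print(f"  cluster strength vs reduction ratio: r={r:.2f} (p={p:.1e})")
print(f"\ncombined-feature ROC (non-responder = positive class):")
print(f"  AUC={report.roc.auc:.3f}  sensitivity={report.roc.sensitivity:.2f} "
      f"specificity={report.roc.specificity:.2f} (in-sample, Youden operating point)")
print(f"  single-feature AUCs: {[round(a, 3) for a in report.roc.single_feature_aucs]}")
print("-> attenuated coupling marks non-responders: cluster strength correlates")
print("   positively with symptom improvement and discriminates the groups.")
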