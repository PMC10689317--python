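"""Run the complete study design end to end on a synthetic cohort.

simulate -> PK mapping -> feature extraction -> 7:3 split -> MR / DCE /
combined LASSO-Cox models -> C-index, Kaplan-Meier risk stratification and
NRI -> figures.  Takes a few minutes at n = 60; shrink n_subjects for a
quick look.
"""

import json

from radsurv import CohortConfig, StudyConfig, make_figures, run_study

config = StudyConfig(cohort=CohortConfig(n_subjects=60, seed=7), n_boot=200)
bundle = run_study(config, out_dir="scratch/full_study")
report = bundle["report"]

print(f"n = {report['n_subjects']} (train {report['n_train']} / test {report['n_test']})\n")
for name in ("mr", "dce", "combined"):
    ev = report["evaluation"][name]
    feats = report["models"][name]["features"]
    print(f"{name:9s} {len(feats)} features; "
          f"train C {ev['train']['c_index']:.3f}, test C {ev['test']['c_index']:.3f}, "
          f"test log-rank p {ev['test']['log_rank_p']}")

nri = report["nri"].get("combined_vs_mr")
if isinstance(nri, dict):
    print(f"\nNRI combined vs MR at {nri['horizon']:.0f} months: {nri['nri']:.3f} "
          f"(counts: {nri['counts']})")

figures = make_figures(bundle, "scratch/full_study/figures")
print(f"\nreport bundle in scratch/full_study; {len(figures)} figures written.")
print("The combined model pools decorrelated DCE features with the MR model's "
      "prediction; on small synthetic cohorts the selected features and test "
      "C-indices vary with the seed, exactly as they would across real cohorts.")
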