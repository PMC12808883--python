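"""Run the full synthetic cohort study and summarize group statistics.

Generates a cohort of healthy and infarcted animals, quantifies contrast
by both MTR asymmetry and Lorentzian difference analysis plus T1/T2, and
compares groups with exact Wilcoxon / Mann-Whitney tests.  Writes the
report directory (CSV tables, contrast maps, spectrum plots, provenance).
"""

import tempfile
from pathlib import Path

import pandas as pd

from glucocest.phantom import CohortSpec
from glucocest.study import StudyConfig, run_study

out = Path(tempfile.mkdtemp(prefix="glucocest_report_"))
cfg = StudyConfig(
    cohort=CohortSpec(n_healthy=4, n_mi=4, image_size=(64, 64), annulus_radii=(9.0, 15.0)),
    seed=11,
)
run_study(cfg, out)

summary = pd.read_csv(out / "roi_summary.csv")
stats = pd.read_csv(out / "group_stats.csv")

print("Per-region mean band contrast (integral units):")
print(
    summary.pivot_table(
        index="region", columns="state", values="contrast_mean"
    ).round(4)
)
print("\nGroup comparisons (contrast_mean):")
cols = ["comparison", "p_value", "stars", "mean_delta"]
print(stats.loc[stats["value"] == "contrast_mean", cols].to_string(index=False))
print(f"\nfull report in {out}")
print(
    "\nA negative healthy delta with a positive MI delta, and the remote "
    "region near\nzero, is the group-level fingerprint of infarct glucose "
    "accumulation."
)
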