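"""The complete fine- vs coarse-grained contrast on a reduced cohort.

Simulates a cohort with the trait planted mainly in fine-grained
connectivity, derives g from the ten test scores with the bifactor model,
hyperaligns, and compares three conditions region by region:
hyperaligned residual fine-grained, coarse-grained, and identity-aligned
(no hyperalignment) residual fine-grained.

The full default desk-scale experiment (120 subjects, 24 regions) is what
scripts/acceptance.py runs; this example uses a smaller cohort so it
finishes in ~20 s.
"""

import numpy as np

from fgconn.cohort import CohortConfig
from fgconn.experiment import ExperimentConfig, compare_conditions, run_all

config = ExperimentConfig(
    cohort=CohortConfig(
        family_histogram={1: 12, 2: 15, 3: 6},   # 60 subjects, 33 families
        n_vertices=240,
        n_regions=12,
        n_timepoints_per_run=300,
    ),
    pc_grid=(10, 20, "all"),
    n_alphas=41,
    seed=0,
)
report = run_all(config)

print("mean cross-validated R² (percent of g variance accounted for):")
for cond in report.conditions():
    r2 = report.r2_by_region(cond)
    print(f"  {cond:18s} {r2.mean():6.1f}  (across-region SE "
          f"{r2.std(ddof=1) / np.sqrt(len(r2)):.2f})")

table = compare_conditions(report, "cha_residual", "cha_coarse",
                           n_boot=2000, seed=1)
summary = table.iloc[-1]
print(f"\nfine vs coarse: difference {summary['difference']:.1f} "
      f"[{summary['diff_ci_low']:.1f}, {summary['diff_ci_high']:.1f}], "
      f"ratio {summary['ratio']:.2f} "
      f"[{summary['ratio_ci_low']:.2f}, {summary['ratio_ci_high']:.2f}]")
print(f"regions where fine > coarse: "
      f"{int(table[table.region_id >= 0]['a_greater'].sum())} of "
      f"{report.parcellation.n_regions}")
# Positive margins with difference CIs excluding 0 reproduce the planted
# ordering: the trait lives in fine-grained topography-resolved
# connectivity, not in region-pair means. (The VAF ratio is only
# interpretable when the denominator is clearly positive; at this reduced
# cohort size the coarse effect is too weak to detect, so rely on the
# difference.)
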