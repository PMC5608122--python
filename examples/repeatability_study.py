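"""Small end-to-end repeatability study on a synthetic cohort.

Simulates an 8-subject T1W cohort (cropped FOV for speed), quantifies every
acquisition, and prints the distribution-comparison and repeatability tables:
per-arm Bland-Altman bias and 95% LOA range, plus the permutation test on
the gated/ungated variance ratio of repeat differences.
"""

from vesselrep.cohort import CohortConfig, simulate_cohort
from vesselrep.pipeline import quantify_cohort
from vesselrep.stats import build_comparison_table, build_repeatability_table

config = CohortConfig(n_subjects=8, weightings=("T1W",), matrix=(96, 96), seed=7)
records, truth = simulate_cohort(config)
metrics = quantify_cohort(records)

cols = ["snr_muscle", "snr_wall", "cnr_wall", "lumen_area_cm2", "wall_area_cm2"]
print("Distribution comparison (repeat 1, gated vs ungated):")
print(build_comparison_table(metrics, cols).round(3).to_string(index=False))
print()
table = build_repeatability_table(metrics, cols, n_perm=5000, seed=1)
print("Repeatability (bias / 95% LOA range per arm, permutation p):")
print(table.round(3).to_string(index=False))
print()
print("Heart-rate variability enters only the gated arm's R-R-locked TR, so")
print("gated intensity metrics show the larger LOA ranges; small permutation")
print("p values flag arms whose repeat differences vary significantly more.")
print("Ungated areas are exactly reproducible here (zero LOA, infinite ratio)")
print("because ROIs come from simulation ground truth with no pulsation and")
print("no observer variability - see the limitations in docs/methods.md.")
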