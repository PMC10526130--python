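"""Two-arm longitudinal cohort on ground truth: relative changes and
Mann-Whitney arm comparisons.

The default arm effects encode the observed clinical pattern: the
bevacizumab arm reduces Ktrans/kep/vp already at 1 week, the
chemotherapy-only arm mostly later. With n=15/arm the 1-week Ktrans
difference is reliably detected.
"""

import dcevasc as dv
from dcevasc.stats import compare_arms, relative_change
from dcevasc.synthetic import generate_cohort

cohort = dv.CohortSpec(n_per_arm=15, inter_subject_cv=0.2, seed=1)
truth, specs = generate_cohort(cohort, dv.PhantomSpec())
print("truth table:", len(truth), "rows;", len(specs), "acquisitions")

changes = relative_change(truth)
med = changes.groupby(["arm", "timepoint", "metric"])["pct_change"].median()
print("\nmedian relative change [%] (ground truth):")
print(med.round(1).unstack("metric")[["ktrans", "kep", "vp", "volume_cm3"]])

print("\narm comparisons (two-sided Mann-Whitney):")
for tp in ("1w", "12w", "25w"):
    for metric in ("ktrans", "vp", "volume_cm3"):
        r = compare_arms(changes, metric, tp)
        star = "*" if r.significant else " "
        print(f"  {tp:4} {metric:11} U={r.u_statistic:6.1f} "
              f"p={r.p_value:.4f}{star} ({r.method})")
print("\n'*' marks p < 0.05; Ktrans and vp separate at 1 week, volume does"
      " not - matching the intended treatment-effect pattern.")
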