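"""Decompose a change in vascular-bundle number into spacing and
cell-number contributions, with rank-sum tests per variable.

Generates two synthetic cohorts with planted medians (a wild-type-like
group and a mutant-like group with fewer, wider-spaced bundles) and runs
the morphometric comparison.
"""

from auxring.morphometrics import decompose_change, wilcoxon_rank_sum
from auxring.synth import CohortSpec, make_cohort

wt = make_cohort(CohortSpec(n_plants=24, median_V=8, median_lambda=10,
                            dispersion_V=0.8, dispersion_lambda=1.5,
                            group="WT", seed=1))
mut = make_cohort(CohortSpec(n_plants=18, median_V=6, median_lambda=12,
                             dispersion_V=0.8, dispersion_lambda=1.5,
                             group="mut", seed=2))
gc = decompose_change(wt, mut)

print("group medians (V, mean lambda, N):")
print(f"  WT : {gc.medians_wt}")
print(f"  mut: {gc.medians_other}")
print(f"fractional effects: spacing f_lam = {gc.f_spacing:+.3f}, "
      f"cell number f_N = {gc.f_cellnumber:+.3f}")
print(f"contributions: spacing {gc.contribution_spacing_pct:.1f}% , "
      f"cell number {gc.contribution_cellnumber_pct:.1f}%  (sum = 100%)")
print(f"Wilcoxon rank-sum p-values: {gc.p_values}")

stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
print(f"\nexact rank-sum check on fully separated samples: W = {stat}, p = {p}")
print("Most of the bundle-number change comes from wider vascular-unit "
      "spacing; the rest from a smaller provascular ring.")
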