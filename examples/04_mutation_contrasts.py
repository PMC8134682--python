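"""Contrast somatic mutation patterns between ICI-score groups.

Computes per-sample tumor mutation burden (TMB), the Spearman association
between ICI score and TMB, and Yates-corrected chi-square tests of per-gene
mutation frequency between high and low score groups — the same statistics
reported for driver genes in melanoma cohorts.
"""

import pandas as pd

from iciscope import compute_tmb, gene_group_chisq, score_tmb_correlation
from iciscope.mutation import load_published_driver_contingency, contingency_chisq
from iciscope.simulate import simulate_cohort

cohort = simulate_cohort(n_samples=200, seed=5)
groups = pd.Series(
    ["high" if z >= cohort.immune_activity.median() else "low"
     for z in cohort.immune_activity],
    index=cohort.immune_activity.index,
)

tmb = compute_tmb(cohort.mutations, list(groups.index))
rho, p = score_tmb_correlation(cohort.immune_activity, tmb.data["nonsyn_count"])
print(f"Spearman(immune activity, TMB) = {rho:.3f} (p = {p:.3g})")
# the generator plants a higher mutation burden in the immune-low half, so
# rho is negative, echoing the infiltration/TMB anticorrelation in melanoma

res = gene_group_chisq(cohort.mutations, groups, "DRV00")
print(f"DRV00: high {res.high_mut}/{res.high_mut + res.high_wild} mutated, "
      f"low {res.low_mut}/{res.low_mut + res.low_wild}, p = {res.p:.3g}")

# the published regression fixture: recompute one printed p-value
table = load_published_driver_contingency().set_index("gene")
row = table.loc["GLRB"]
check = contingency_chisq("GLRB", row.high_wild, row.high_mut,
                          row.low_wild, row.low_mut)
print(f"GLRB published p {row.p_published:.9f} vs recomputed {check.p:.9f}")
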