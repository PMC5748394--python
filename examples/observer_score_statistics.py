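"""Fracture-risk statistics of the ordinal observer score.

Loads the packaged 304-subject cross-tabulation of the trabecular-pattern
observer score (dense / alternating / sparse) against 26-year fracture
outcome and computes the headline statistics: the fracture odds ratio of a
sparse pattern, the fracture-free odds ratio of a dense pattern, the
sensitivity/specificity of the sparse cutoff, and the ordinal ROC AUC.
"""

from trabtex import (
    ContingencyTable,
    load_table2,
    odds_ratio_ci,
    ordinal_auc,
    sensitivity_specificity,
)

table = load_table2()
print("fracture x score counts (rows: fractured, fracture-free):")
print(table.counts)

or_s, lo, hi = odds_ratio_ci(table.collapse({2}))
print(f"\nsparse pattern, fracture OR: {or_s:.1f} (95% CI {lo:.1f}-{hi:.1f})")
# a sparse trabecular pattern multiplies the fracture odds ~12-fold

or_d, lo_d, hi_d = odds_ratio_ci(ContingencyTable(table.counts[::-1]).collapse({0}))
print(f"dense pattern, fracture-free OR: {or_d:.1f} (95% CI {lo_d:.1f}-{hi_d:.1f})")

sens, spec = sensitivity_specificity(table, positive_scores={2})
print(f"sparse cutoff: sensitivity {100 * sens:.0f}%, specificity {100 * spec:.0f}%")

print(f"ordinal ROC AUC of the score: {ordinal_auc(table):.3f}")
# 0.8 means a random fractured subject outranks a random fracture-free
# subject on the score in 80% of pairs (ties counted half)
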