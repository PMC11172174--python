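"""Silencing-potential classification of the seven derepressed TE families.

Feeds the published antisense TE-mapped piRNA abundances (rpm, 0-3
mismatches) for D. simulans, D. melanogaster and hybrid ovaries through
the >100 rpm silencing rule and the fivefold-reduction cohort counts.
"""

from hspirna import datasets, tequant

table = datasets.derepressed_te_antisense_rpm()
profiles = tequant.profiles_from_rpm_table(table, datasets.DEREPRESSED_TE_CLASSES)
summary = tequant.cohort_summary(profiles, parents=("mel", "sim"))

print(table)
print()
print("silencing potential retained in hybrids:", ", ".join(summary.silencing_pass))
print("silencing potential lost in hybrids:   ", ", ".join(summary.silencing_fail))

folds = {
    fam: tequant.fold_reduction(row["mel"], row["hybrid"])
    for fam, row in table.iterrows()
}
print("fold reduction vs D. melanogaster parent:", folds)
print(
    f"range: {min(folds.values())}- to {max(folds.values())}-fold; "
    f"{summary.n_reduced_vs_both} families lost >=5-fold vs both parents, "
    f"{summary.n_reduced_vs_at_least_one} vs at least one."
)
print()
print(
    "Families above 100 rpm antisense piRNAs retain the capacity to silence\n"
    "their TE in hybrid ovaries; the four below it are derepressed with\n"
    "insufficient piRNA cover."
)
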