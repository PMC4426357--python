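"""Brood-viability statistics: summaries, group comparison, verdicts.

Percent hatching is hatched larvae over eggs laid per brood; summaries
average within replicate experiments first and report mean +/- SD across
the replicate means.  Complementation crosses are scored from the
trans-heterozygote viability (fails < 10%, complements > 50%).
"""

from hawmap import compare_viability, complementation_verdict, summarize_broods
from hawmap.fixtures import load_complementation_results, synthetic_broods_path
from hawmap.viability_stats import read_broods_tsv

records = read_broods_tsv(synthetic_broods_path())
print("synthetic demonstration broods:")
print(summarize_broods(records).to_string(index=False))

wt24 = [r for r in records if r.genotype == "wildtype" and r.temperature == 24]
ts24 = [r for r in records if r.genotype == "ts-mutant" and r.temperature == 24]
res = compare_viability(ts24, wt24)
print(
    f"\nts-mutant vs wildtype at 24C: {res.mean_a:.1f}% vs {res.mean_b:.1f}% "
    f"hatching (Welch p = {res.welch_p:.2g}, Fisher p = {res.fisher_p:.2g})"
)

print("\ncomplementation crosses scored from the printed percentages:")
for row in load_complementation_results().itertuples():
    note = row.sterility_note if isinstance(row.sterility_note, str) else None
    v = complementation_verdict(row.percent_hatching, sterility_note=note)
    flag = "  [sterility note]" if v.sterility_flag else ""
    print(
        f"  {row.strain:>14} x {row.partner_allele:<16} "
        f"{row.percent_hatching:>5}% -> {v.verdict}{flag}"
    )
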