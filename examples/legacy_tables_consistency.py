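"""Check the transcribed legacy-mutant candidate tables for internal
consistency.

Each table row prints a nucleotide change and an amino-acid change (e.g.
"G->A, Gly42Arg").  Because the genomic substitution is strand-agnostic,
the amino-acid change must be reachable from the printed change on one of
the two strands through the genetic code — a transcription error in either
half breaks that.  The EMS signature (G:C -> A:T) is flagged too.
"""

from hawmap import check_substitution_consistency, ems_flag, truncation_length
from hawmap.candidate_annotation import EffectClass, parse_descriptor
from hawmap.fixtures import load_variant_tables

df = load_variant_tables()
print(f"{len(df)} candidate rows across {df.strain.nunique()} strains\n")

n_ok = n_minus_only = 0
for row in df.itertuples():
    parsed = parse_descriptor(row.mutation)
    if parsed.effect is EffectClass.FRAMESHIFT:
        print(f"  {row.strain:>14} {row.gene:<10} frameshift (no codon check)")
        continue
    ok, witnesses = check_substitution_consistency(
        parsed.aa_from, parsed.aa_to, parsed.nt_from, parsed.nt_to
    )
    n_ok += ok
    strands = {s for _f, _t, s in witnesses}
    if strands == {"-"}:
        n_minus_only += 1
print(f"single-substitution consistent: {n_ok}/{len(df) - 1} SNV rows")
print(f"rows explainable only via the complementary strand: {n_minus_only}")

causal = df[df.causal == 1]
ems = sum(
    ems_flag(parse_descriptor(r.mutation).nt_from, parse_descriptor(r.mutation).nt_to)
    for r in causal.itertuples()
)
print(f"causal lesions with the EMS G:C->A:T signature: {ems}/{len(causal)}")

print("\nper-strain candidate counts:")
print(df.strain.value_counts().to_string())

print("\ntruncation arithmetic for the premature stops:")
print(f"  mus-101 Trp1062stop in a 1227-aa protein removes "
      f"{truncation_length(1227, 1062)} codons")
print(f"  tofu-6  Gln52stop   in a  367-aa protein removes "
      f"{truncation_length(367, 52)} codons")
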