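"""Simulate one full mapping-by-sequencing experiment and map the lesion.

A mutagenized N2 strain carrying one recessive lethal lesion is crossed to
the Hawaiian strain; 200 F2 progeny are singled, homozygous-mutant lines are
pooled (20-50 of them) and sequenced to ~22x.  The mapping interval is the
chromosomal span devoid of Hawaiian marker SNPs, and the candidate list is
every novel, homozygous, nonsynonymous variant inside it.
"""

from hawmap.candidate_annotation import candidates_to_frame
from hawmap.pipeline import run_mapping, run_simulation

sim = run_simulation(seed=1)  # defaults = the study conditions
causal = sim.model.causal
print(
    f"pooled {sim.pool.n_pooled} homozygous-mutant lines "
    f"({sim.pool.n_mutant_found}/{sim.pool.n_f2_screened} F2s were mutant); "
    f"{len(sim.calls)} variant calls"
)
print(f"hidden causal lesion: {causal.chrom}:{causal.pos} {causal.ref}>{causal.alt}")

res = run_mapping(sim)
sel = res.selected
print(
    f"\nselected interval: {sel.chrom}:{sel.start:,}-{sel.end:,} "
    f"({sel.width_mb:.2f} Mb, {sel.genetic_width_cm:.2f} cM)"
)
print(f"interval contains the causal locus: {sel.contains(causal.chrom, causal.pos)}")

print("\ncandidate lesions (novel, homozygous, nonsynonymous, inside interval):")
print(candidates_to_frame(res.candidates).to_string(index=False))
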