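# Methods

This document records the models, conventions, parameter choices, and known
limitations behind `hawmap`. Every statistical claim here is exercised by the
test suite (`tests/`), usually against an independently coded oracle in
`tests/oracles.py`.

## 1. Genetic model of the mapping cross

A mutagenized N2 (Bristol) hermaphrodite carrying one recessive lethal lesion
is crossed to CB4856 (Hawaiian). F2 self-progeny are singled, homozygous-mutant
lines are identified phenotypically, and 20–50 of them are pooled for
whole-genome sequencing.

### 1.1 Meiosis: obligate single crossover, complete interference

Each gamete chromosome is drawn as:

- with probability 1/2, a whole non-recombinant chromosome (N2 or Hawaiian,
  equiprobable);
- otherwise, a single breakpoint uniform on the genetic map (in cM), with the
  two flanks assigned the two parental genotypes (orientation equiprobable).

This reproduces the two C. elegans facts that make the method work: exactly
0 or 1 crossover per chromosome per meiosis (complete interference) and a
marginal recombinant-gamete fraction of 1/2.

Conditioning a gamete on being N2 at the causal position `g0` (in cM, on a
chromosome of genetic length `L`) gives a closed form used as the test oracle:

- P(whole-chromosome N2) = 1/2;
- a breakpoint at map position `u` contributes density `du / (2L)`, with the
  Hawaiian segment on the side **away** from `g0`;
- hence the Hawaiian-allele frequency at genetic distance `d` from the causal
  locus, in a pool of chromosomes all N2 at `g0`, has expectation `d / (2L)`.

With `L = 50 cM` this is the familiar linear ramp: 0 at the causal locus,
2% per cM of separation. `tests/oracles.py` re-derives this both by Monte
Carlo over the conditioned gamete law and by grid enumeration
(trapezoid integration of the breakpoint indicator divided by `2L`), and the
simulator is checked against both.

### 1.2 Genetic maps

Two map shapes are provided per chromosome (total genetic length fixed at
50 cM by default):

- `uniform`: constant cM/bp;
- `three_domain`: recombination-rich arms (40% of the cM in each outer
  physical quarter) and a cold center (20% of the cM across the middle half),
  approximating the *C. elegans* arm/center domain structure.

All breakpoints are drawn in cM and converted to bp through the map, so the
conditional-frequency results above hold in genetic coordinates under either
map.

### 1.3 F2 pool composition

Each F2 is two independent gametes. A line is "mutant" iff homozygous for the
causal lesion (expected 1/4 of F2s). `simulate_mutant_pool` screens `n_f2`
F2s (default 200), collects the mutant ones, and pools a uniform-random
number between 20 and 50 of them (or all found, if fewer — but an explicitly
requested pool size that cannot be met raises instead of silently shrinking).

## 2. Sequencing model

Pooled sequencing is simulated per catalog site:

- depth ~ Poisson(`mean_depth`), default 22;
- alt reads ~ Binomial(depth, `f(1 − e) + (1 − f)e`) with per-read error
  `e = 0.001` and `f` the true pool alt-allele frequency at the site;
- for Hawaiian marker SNPs, `f` is the pooled Hawaiian chromosome fraction;
  for parental (pre-existing background) and induced (EMS) variants, `f` is
  `1 −` (Hawaiian fraction), because those alleles ride the N2 haplotype;
- the causal site has `f = 1` exactly (every pooled line is homozygous
  mutant by construction);
- sites with zero alt reads are suppressed from the VCF (as a real variant
  caller would), unless `emit_zero_alt` is set.

Induced mutations follow the EMS spectrum (G:C → A:T transitions dominate),
and the causal lesion is guaranteed nonsynonymous within a gene model.

## 3. Variant classification

Calls are matched to the Hawaiian and parental catalogs **allele-exactly** on
`(chrom, pos, alt)`; a matching position with a different alt allele is
`novel`. Two thresholds, both pinned to the published protocol:

- **homozygous**: alt fraction **strictly** greater than 0.85 (a call at
  exactly 0.85 is not homozygous);
- **Hawaiian marker present**: alt depth ≥ 2 reads.

The presence rule is deliberately permissive (2 reads at 22× is reachable by
sequencing error with probability ≈ 2.4 × 10⁻⁴ per site); see §8 for the
consequence.

## 4. Interval detection

The mapping interval is the span devoid of *present* Hawaiian markers:

- per chromosome, sort present marker positions; each maximal gap between
  consecutive present markers is an interval `(left + 1, right − 1)`;
- chromosome ends are open flanks (an interval may run to position 1 or to
  the chromosome length);
- a chromosome with **no** present marker yields one whole-chromosome
  interval flagged `ambiguous`;
- the **selected** interval is the one of largest *genetic* width (cM under
  the supplied map; physical width is the fallback when no map is given),
  ties broken by chromosome then start;
- a reduction mode (`max_present_per_bin = k`) instead takes the longest run
  of fixed-width bins each containing ≤ k present markers, for noisy data.

Candidate lesions are the novel, homozygous (alt fraction > threshold),
nonsynonymous variants inside the selected interval.

## 5. Functional annotation

- Gene models come from GFF3; CDS segments are held in translation order and
  spliced before translation (standard codon table, `*` for stops).
- SNV effects: `synonymous`, `missense`, `nonsense` (gain of stop),
  `start_loss`, `stop_loss`, by full-protein comparison.
- Indels in CDS: length not divisible by 3 → `frameshift`; in-frame indels
  are reported as `missense` (a simplification: no separate in-frame-indel
  class is carried).
- `splice`: an SNV within 2 intronic bp of a CDS boundary.
- "Nonsynonymous" for candidate filtering = {missense, nonsense, frameshift,
  splice, start_loss, stop_loss}.
- Legacy-table descriptors ("G->A, Gly42Arg", "…stop", frameshift text) are
  parsed by regex, and each printed substitution is checked for genetic-code
  consistency on *both* strands, returning explicit codon witnesses
  `(codon_from, codon_to, strand)`.
- Truncation arithmetic: a premature stop at codon `s` in an `n`-codon
  protein removes `n − s` codons.

## 6. CRISPR edit verification

- Protospacer scan: exact guide match followed by NGG on either strand.
- SpCas9 blunt cut is 3 bp 5′ of the PAM: plus strand `cut_after = end − 3`,
  minus strand `cut_after = start + 2`, in 1-based target coordinates.
- Repair-oligo comparison reports every mismatch position plus the 5′/3′
  homology-arm lengths; > 10 differences is rejected as a likely alignment
  error rather than an edit set.
- Restriction scans use IUPAC-degenerate site patterns on both strands
  (e.g. EaeI = YGGCCR); positions are 1-based site starts. Results are
  cross-checked in the tests against `Bio.Restriction` (whose `search`
  returns site start + 1).
- Silent PAM-destroying edits: given a CDS and a protospacer site, the
  package enumerates synonymous single-base changes that abolish the NGG.

## 7. Viability statistics

- Percent hatching = hatched / eggs × 100 per brood.
- Summaries average **within replicate first**, then report mean ± SD across
  replicate means (SD with ddof = 1; a single replicate reports SD 0).
- Group comparison needs ≥ 2 broods per group: Welch's t-test on per-brood
  percentages (primary) plus Fisher's exact test on pooled egg counts
  (secondary); identical degenerate groups report p = 1.
- Complementation verdicts from trans-heterozygote viability: `fails` if
  hatching < 10%, `complements` if > 50%, `ambiguous` otherwise (boundaries
  are ambiguous — the inequalities are strict). Sterility is carried as a
  separate flag, never folded into the verdict.
- Mendelian expectations (`mendelian_fraction`): het self-cross → 1/4
  homozygous mutant, etc.

## 8. Numerical and reproducibility choices

- All randomness flows from `numpy.random.SeedSequence`; the reference
  model, pool, and sequencing draws use distinct `spawn_key` substreams so a
  run is byte-reproducible from one integer seed (derived seeds < 2³¹).
- The reference genome is procedural: each base is a 64-bit hash of
  (chromosome, position), so arbitrarily large genomes cost no storage and
  any window can be re-fetched deterministically. FASTA export wraps at a
  fixed line width with a carry buffer so the file indexes cleanly.
- Hypothesis property tests run under a derandomized `ci` profile with no
  deadline.

## 9. Limitations

- **Interval-recovery failure mode (~6–9% of runs at study conditions).**
  The presence rule (alt ≥ 2) fires inside the true Hawaiian-free gap in two
  ways: pure sequencing error (P ≈ 2.4 × 10⁻⁴ per site; the gap spans ~1,200
  catalog sites on average, so ~24% of runs see at least one such site) and
  sporadic detection of segments carried by a *single* recombinant pooled
  line (true frequency ≈ 1/n_pooled ≈ 0.02, P(alt ≥ 2) ≈ 8% per site at
  22×). When such a site splits the gap and the fragment *away* from the
  causal locus is wider (~1/4 of splits), the selected interval misses the
  lesion. In a pre-registered 100-run batch, 91/100 runs recovered the
  causal lesion. Raising `min_alt_reads` or using the bin-reduction mode
  suppresses this at the cost of wider intervals; the defaults are kept at
  the published protocol values.
- The meiosis model forbids double crossovers entirely; real chromosome
  arms show near-complete but not perfect interference.
- Depth is i.i.d. Poisson per site (no mappability, GC, or duplication
  structure), and errors are symmetric and independent.
- In-frame CDS indels are labeled `missense` rather than given their own
  effect class.
- The procedural genome has uniform base composition and no repeats, so
  alignment artifacts are out of scope.
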