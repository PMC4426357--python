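"""Simulator for the Hawaiian mapping cross and pooled short-read sampling.

The emulated experiment: a mutagenized N2 hermaphrodite carrying one causal
recessive lesion is crossed to Hawaiian (CB4856) males; ~200 F2 progeny are
singled; F2s homozygous mutant at the causal locus are selected and 20-50 of
them pooled; the pool is sequenced to ~22x and variants are called at every
Hawaiian-catalog, parental-background, and induced-mutation site.

Meiosis uses an obligate-single-crossover model with complete interference,
which is the textbook approximation for *C. elegans* bivalents: each gamete
is non-recombinant with probability 1/2 (whole chromosome from either
parental homolog, equiprobably) and otherwise carries a single exchange at a
position uniform in genetic (cM) coordinates.  Under this model the marginal
Hawaiian allele frequency is 1/2 everywhere, and conditioning on N2 at the
causal locus depletes Hawaiian alleles linearly with genetic distance.

Intergenic sequence is procedural (a deterministic per-position hash), so
whole 13-21 Mb chromosomes never need to be held in memory; explicit
sequence exists only where toy genes were placed.
"""

from __future__ import annotations

import itertools
import zlib
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats_io import (
    GeneModel,
    SnpCatalog,
    VariantCall,
    reverse_complement,
)

N2 = "N2"
HAW = "HAW"

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}

# C. elegans WS220 chromosome sizes, rounded to 10 kb.
DEFAULT_CHROMOSOMES = {
    "I": 15_070_000,
    "II": 15_280_000,
    "III": 13_780_000,
    "IV": 17_490_000,
    "V": 20_920_000,
    "X": 17_720_000,
}


# --- configuration --------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions of the emulated mapping experiment.

    Defaults mirror the printed experimental design: ~200 singled F2s,
    20-50 pooled homozygous-mutant lines, >=22-fold coverage, a genome-wide
    Hawaiian marker background, and EMS-style induced mutations with a
    single causal nonsynonymous lesion.
    """

    chromosomes: dict = field(default_factory=lambda: dict(DEFAULT_CHROMOSOMES))
    total_cm: float = 50.0  # genetic length per chromosome
    map_style: str = "uniform"  # "uniform" or "three_domain"
    hawaiian_density: float = 1e-3  # SNPs per bp (~1 per kb)
    parental_variant_count: int = 150  # pre-mutagenesis background variants
    induced_mutation_count: int = 300  # EMS lesions incl. the causal one
    mutation_spectrum: str = "ems"  # "ems" (G:C->A:T only) or "uniform"
    causal_chrom: str = "V"
    causal_pos: int = 6_500_000
    genes_per_chromosome: int = 25
    n_f2: int = 200
    n_pooled: Optional[int] = None  # None -> drawn uniformly from [20, 50]
    n_pooled_range: tuple = (20, 50)
    mean_depth: float = 22.0
    error_rate: float = 0.001
    emit_zero_alt: bool = False
    contamination_rate: float = 0.0  # heterozygous escapers in the pool

    def validate(self) -> None:
        if self.causal_chrom not in self.chromosomes:
            raise ValueError(
                f"causal chromosome {self.causal_chrom!r} not in genome"
            )
        if not (1 <= self.causal_pos <= self.chromosomes[self.causal_chrom]):
            raise ValueError(
                f"causal position {self.causal_pos} outside chromosome "
                f"{self.causal_chrom}"
            )
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["chromosomes"] = dict(self.chromosomes)
        d["n_pooled_range"] = list(self.n_pooled_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "n_pooled_range" in d:
            d["n_pooled_range"] = tuple(d["n_pooled_range"])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str) -> SimConfig:
    """Load a flat TOML config file; missing keys take the defaults."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return SimConfig.from_dict(data)


# --- genetic map ----------------------------------------------------------


@dataclass
class ChromosomeMap:
    """Monotone piecewise-linear bp<->cM mapping for one chromosome."""

    length_bp: int
    bp_knots: np.ndarray
    cm_knots: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.bp_knots, dtype=float)
        cm = np.asarray(self.cm_knots, dtype=float)
        if bp[0] != 0 or bp[-1] != self.length_bp or cm[0] != 0:
            raise ValueError("map knots must span [0, length] and start at 0 cM")
        if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
            raise ValueError("map knots must be nondecreasing")
        self.bp_knots = bp
        self.cm_knots = cm

    @property
    def total_cm(self) -> float:
        return float(self.cm_knots[-1])

    def cm_at(self, bp) -> np.ndarray:
        return np.interp(bp, self.bp_knots, self.cm_knots)

    def bp_at(self, cm) -> np.ndarray:
        return np.interp(cm, self.cm_knots, self.bp_knots)


@dataclass
class GeneticMap:
    chroms: dict

    def __getitem__(self, chrom: str) -> ChromosomeMap:
        return self.chroms[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def cm_width(self, chrom: str, start: int, end: int) -> float:
        m = self.chroms[chrom]
        return float(m.cm_at(end) - m.cm_at(start))


def build_genetic_map(config: SimConfig) -> GeneticMap:
    """Construct the genetic map the simulator recombines on.

    ``uniform``: constant cM/bp.  ``three_domain``: the *C. elegans*-like
    pattern of high-recombination arms (outer quarters, 40% of the genetic
    length each) around a low-recombination center.
    """
    chroms = {}
    for name, length in config.chromosomes.items():
        if config.map_style == "uniform":
            bp = np.array([0.0, float(length)])
            cm = np.array([0.0, config.total_cm])
        elif config.map_style == "three_domain":
            bp = np.array([0.0, 0.25 * length, 0.75 * length, float(length)])
            cm = config.total_cm * np.array([0.0, 0.4, 0.6, 1.0])
        else:
            raise ValueError(f"unknown map_style {config.map_style!r}")
        chroms[name] = ChromosomeMap(length_bp=length, bp_knots=bp, cm_knots=cm)
    return GeneticMap(chroms=chroms)


# --- recombinant chromosomes ---------------------------------------------


@dataclass(slots=True)
class RecombinantChromosome:
    """An ancestry mosaic: breakpoints and the ancestry of each segment.

    Positions ``<= breakpoints[i]`` (and ``> breakpoints[i-1]``) carry
    ``ancestries[i]``; segments tile ``[1, length]`` and ancestries
    alternate.
    """

    chrom: str
    breakpoints: tuple
    ancestries: tuple

    def __post_init__(self) -> None:
        if len(self.ancestries) != len(self.breakpoints) + 1:
            raise ValueError("need one more ancestry than breakpoints")
        for a, b in zip(self.ancestries, self.ancestries[1:]):
            if a == b:
                raise ValueError("ancestries must alternate across breakpoints")

    def ancestry_at(self, pos: int) -> str:
        return self.ancestries[bisect_left(self.breakpoints, pos)]

    def ancestry_at_many(self, positions: np.ndarray) -> np.ndarray:
        """Boolean array: True where ancestry is Hawaiian."""
        idx = np.searchsorted(
            np.asarray(self.breakpoints, dtype=np.int64), positions, side="left"
        )
        is_haw = np.asarray(
            [a == HAW for a in self.ancestries], dtype=bool
        )
        return is_haw[idx]


def simulate_gamete(
    genetic_map: GeneticMap, chrom: str, rng: np.random.Generator
) -> RecombinantChromosome:
    """Draw one F1 gamete under the obligate-single-crossover model.

    With probability 1/2 the bivalent's exchange is not inherited and the
    gamete is a whole parental chromosome (N2 or Hawaiian, equiprobably);
    otherwise a single breakpoint falls uniformly in cM with random
    orientation.  A chromosome of zero genetic length never recombines.
    """
    m = genetic_map[chrom]
    if m.length_bp < 1:
        raise ValueError(f"degenerate zero-length chromosome {chrom}")
    if m.total_cm == 0.0 or rng.random() < 0.5:
        anc = N2 if rng.random() < 0.5 else HAW
        return RecombinantChromosome(chrom, (), (anc,))
    b_cm = rng.uniform(0.0, m.total_cm)
    bp = int(round(float(m.bp_at(b_cm))))
    bp = min(max(bp, 1), m.length_bp - 1)
    left = N2 if rng.random() < 0.5 else HAW
    right = HAW if left == N2 else N2
    return RecombinantChromosome(chrom, (bp,), (left, right))


# --- reference model ------------------------------------------------------


class SyntheticGenome:
    """Reference sequence with procedural filler outside gene loci.

    ``fetch``/``base`` use 1-based inclusive coordinates.  Per-position
    filler bases are a deterministic 64-bit hash of (chromosome salt,
    position), so any window can be regenerated without storing it.
    """

    _MULT = np.uint64(6364136223846793005)
    _INC = np.uint64(1442695040888963407)

    def __init__(self, lengths: dict, seed: int):
        self.chrom_lengths = dict(lengths)
        self._salts = {
            name: np.uint64((zlib.crc32(name.encode()) ^ (seed & 0xFFFFFFFF)))
            for name in lengths
        }
        self._regions: dict = {name: [] for name in lengths}  # (start,end,seq)

    def add_region(self, chrom: str, start: int, seq: str) -> None:
        end = start + len(seq) - 1
        for s, e, _ in self._regions[chrom]:
            if start <= e and s <= end:
                raise ValueError(f"overlapping explicit regions on {chrom}")
        self._regions[chrom].append((start, end, seq))
        self._regions[chrom].sort()

    def _filler(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        x = positions.astype(np.uint64) + self._salts[chrom]
        x = x * self._MULT + self._INC
        x ^= x >> np.uint64(33)
        x = x * self._MULT
        return _BASES[(x >> np.uint64(60)) & np.uint64(3)]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.chrom_lengths:
            raise KeyError(f"contig {chrom!r} not in synthetic genome")
        if start < 1 or end > self.chrom_lengths[chrom] or end < start:
            raise ValueError(f"bad window {chrom}:{start}-{end}")
        pos = np.arange(start, end + 1, dtype=np.int64)
        arr = self._filler(chrom, pos)
        for s, e, seq in self._regions[chrom]:
            lo, hi = max(s, start), min(e, end)
            if lo <= hi:
                sub = np.frombuffer(
                    seq[lo - s : hi - s + 1].encode(), dtype="S1"
                )
                arr[lo - start : hi - start + 1] = sub
        return arr.tobytes().decode()

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def bases_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized single-base lookup; returns an array of 1-char strings."""
        positions = np.asarray(positions, dtype=np.int64)
        arr = self._filler(chrom, positions)
        for s, e, seq in self._regions[chrom]:
            mask = (positions >= s) & (positions <= e)
            if mask.any():
                idx = positions[mask] - s
                arr[mask] = np.frombuffer(seq.encode(), dtype="S1")[idx]
        return arr.astype("U1")

    def lengths(self) -> dict:
        return dict(self.chrom_lengths)


def write_genome_fasta(genome, path: str, wrap: int = 70) -> None:
    """Write the full genome as FASTA (intended for small configs)."""
    with open(path, "w") as fh:
        for chrom, length in genome.lengths().items():
            fh.write(f">{chrom}\n")
            pending = ""
            for start in range(1, length + 1, 100_000):
                end = min(start + 100_000 - 1, length)
                pending += genome.fetch(chrom, start, end)
                full = len(pending) // wrap * wrap
                for i in range(0, full, wrap):
                    fh.write(pending[i : i + wrap] + "\n")
                pending = pending[full:]
            if pending:
                fh.write(pending + "\n")


@dataclass(slots=True)
class Mutation:
    """An induced (EMS-style) lesion on the mutagenized N2 founder."""

    chrom: str
    pos: int
    ref: str
    alt: str
    causal: bool = False


@dataclass
class ReferenceModel:
    """Everything fixed before the cross: genome, catalogs, lesions, genes."""

    config: SimConfig
    genetic_map: GeneticMap
    genome: SyntheticGenome
    hawaiian: SnpCatalog
    parental: SnpCatalog
    induced: list  # list[Mutation], includes the causal one
    gene_models: list
    seed: int

    @property
    def causal(self) -> Mutation:
        return next(m for m in self.induced if m.causal)


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random ORF: ATG, internal non-stop codons, one stop codon."""
    codons = ["ATG"]
    sense = [
        c
        for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
        if c not in _STOPS and c != "ATG"
    ]
    idx = rng.integers(0, len(sense), size=n_codons - 2)
    codons.extend(sense[i] for i in idx)
    codons.append("TAA")
    return "".join(codons)


def _make_gene(
    gene_id: str,
    chrom: str,
    anchor: int,
    chrom_len: int,
    rng: np.random.Generator,
) -> tuple:
    """Build one toy gene near ``anchor``; returns (GeneModel, region_start, seq)."""
    n_codons = int(rng.integers(100, 400))
    n_exons = int(rng.integers(1, 4))
    cds = _random_cds(n_codons, rng)
    # split CDS into exons
    if n_exons == 1:
        pieces = [cds]
    else:
        cuts = sorted(rng.choice(np.arange(30, len(cds) - 30), size=n_exons - 1, replace=False))
        pieces = [cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(cds)])]
    introns = [
        "GT" + "".join(_BASES[rng.integers(0, 4, size=int(rng.integers(46, 200)))].astype(str)) + "AG"
        for _ in range(n_exons - 1)
    ]
    strand = "+" if rng.random() < 0.5 else "-"
    # pre-mRNA in transcript orientation
    parts, exon_bounds, off = [], [], 0
    for i, piece in enumerate(pieces):
        exon_bounds.append((off, off + len(piece) - 1))
        parts.append(piece)
        off += len(piece)
        if i < len(introns):
            parts.append(introns[i])
            off += len(introns[i])
    pre = "".join(parts)
    start = max(1, min(anchor - len(pre) // 2, chrom_len - len(pre)))
    if strand == "+":
        region = pre
        segs = [(start + a, start + b) for a, b in exon_bounds]
    else:
        region = reverse_complement(pre)
        end = start + len(pre) - 1
        segs = [(end - b, end - a) for a, b in exon_bounds]  # translation order
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds=tuple(segs),
        protein_length=n_codons,
    )
    return model, start, region


def _translate_codon(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def build_reference_model(config: SimConfig = None, seed: int = 0) -> ReferenceModel:
    """Generate the fixed substrate of one simulated experiment.

    Deterministic for a fixed (config, seed).  The causal lesion is an
    EMS-compatible change placed inside a CDS so that it is nonsynonymous;
    it is forced to lie in a gene spanning ``config.causal_pos``.
    """
    if config is None:
        config = SimConfig()
    config.validate()
    ss = np.random.SeedSequence(seed, spawn_key=(0,))
    rng_genome, rng_genes, rng_haw, rng_par, rng_mut = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    genome = SyntheticGenome(config.chromosomes, seed=int(rng_genome.integers(2**31)))
    gmap = build_genetic_map(config)

    # genes: one forced over the causal position, the rest spread out
    gene_models: list = []
    for chrom, length in config.chromosomes.items():
        anchors = np.sort(
            rng_genes.integers(1000, length - 1000, size=config.genes_per_chromosome)
        )
        if chrom == config.causal_chrom:
            anchors[np.argmin(np.abs(anchors - config.causal_pos))] = config.causal_pos
        placed_end = 0
        for k, anchor in enumerate(anchors):
            model, start, region = _make_gene(
                f"gene_{chrom}_{k:03d}", chrom, int(anchor), length, rng_genes
            )
            if start <= placed_end:  # avoid overlaps; skip crowded anchors
                if int(anchor) != config.causal_pos:
                    continue
                start = placed_end + 10
                end = start + len(region) - 1
                if end > length:
                    raise ValueError("cannot place causal gene inside chromosome")
                shift = start - model.span[0]
                model = GeneModel(
                    gene_id=model.gene_id,
                    chrom=chrom,
                    strand=model.strand,
                    cds=tuple((s + shift, e + shift) for s, e in model.cds),
                    protein_length=model.protein_length,
                )
            genome.add_region(chrom, start, region)
            placed_end = start + len(region) - 1
            gene_models.append(model)

    # Hawaiian catalog: Poisson-dense marker SNPs along every chromosome
    haw_rows = []
    for chrom, length in config.chromosomes.items():
        n = rng_haw.poisson(config.hawaiian_density * length)
        pos = np.unique(rng_haw.integers(1, length + 1, size=n))
        refs = genome.bases_at(chrom, pos)
        # alt: a uniformly random base other than ref
        shift = rng_haw.integers(1, 4, size=len(pos))
        base_idx = np.searchsorted(np.array(list("ACGT")), refs)
        alts = np.array(list("ACGT"))[(base_idx + shift) % 4]
        for p, ref, alt in zip(pos, refs, alts):
            haw_rows.append((chrom, int(p), str(ref), str(alt)))
    hawaiian = SnpCatalog(entries=frozenset(haw_rows), source="hawaiian")
    haw_positions = {(c, p) for (c, p, _r, _a) in haw_rows}

    # parental (pre-mutagenesis) background variants on the N2 founder
    par_rows = []
    chrom_names = list(config.chromosomes)
    probs = np.array([config.chromosomes[c] for c in chrom_names], dtype=float)
    probs /= probs.sum()
    while len(par_rows) < config.parental_variant_count:
        chrom = chrom_names[int(rng_par.choice(len(chrom_names), p=probs))]
        p = int(rng_par.integers(1, config.chromosomes[chrom] + 1))
        if (chrom, p) in haw_positions:
            continue
        ref = genome.base(chrom, p)
        par_rows.append((chrom, p, ref, _other_base(ref, rng_par)))
    parental = SnpCatalog(entries=frozenset(par_rows), source="parental")

    # induced EMS lesions, incl. one causal nonsynonymous change in a CDS
    causal = _place_causal(config, genome, gene_models)
    induced = [causal]
    taken = {(causal.chrom, causal.pos)}
    while len(induced) < config.induced_mutation_count:
        chrom = chrom_names[int(rng_mut.choice(len(chrom_names), p=probs))]
        p = int(rng_mut.integers(1, config.chromosomes[chrom] + 1))
        if (chrom, p) in taken:
            continue
        ref = genome.base(chrom, p)
        if config.mutation_spectrum == "ems":
            if ref not in ("G", "C"):
                continue
            alt = "A" if ref == "G" else "T"
        else:
            alt = _other_base(ref, rng_mut)
        taken.add((chrom, p))
        induced.append(Mutation(chrom, p, ref, alt))
    induced.sort(key=lambda m: (m.chrom, m.pos))
    return ReferenceModel(
        config=config,
        genetic_map=gmap,
        genome=genome,
        hawaiian=hawaiian,
        parental=parental,
        induced=induced,
        gene_models=gene_models,
        seed=seed,
    )


def _other_base(ref: str, rng: np.random.Generator) -> str:
    options = [b for b in "ACGT" if b != ref]
    return options[int(rng.integers(0, 3))]


def _place_causal(config: SimConfig, genome, gene_models) -> Mutation:
    """Pick the CDS position nearest the configured causal locus at which an
    EMS transition (G->A or C->T on the coding strand) is nonsynonymous."""
    candidates = [
        m for m in gene_models
        if m.chrom == config.causal_chrom
        and m.span[0] <= config.causal_pos <= m.span[1]
    ]
    if not candidates:
        # fall back to the nearest gene on the causal chromosome
        on_chrom = [m for m in gene_models if m.chrom == config.causal_chrom]
        if not on_chrom:
            raise ValueError("no gene available on the causal chromosome")
        candidates = [
            min(on_chrom, key=lambda m: abs((m.span[0] + m.span[1]) // 2 - config.causal_pos))
        ]
    model = candidates[0]
    from .formats_io import cds_sequence

    cds = cds_sequence(model, genome)
    best = None
    idx = 0
    for s, e in model.cds:
        seg_len = e - s + 1
        for k in range(seg_len):
            gpos = (s + k) if model.strand == "+" else (e - k)
            coding_base = cds[idx + k]
            if coding_base not in ("G", "C"):
                continue
            new_base = "A" if coding_base == "G" else "T"
            ci = (idx + k) // 3
            off = (idx + k) % 3
            codon = cds[3 * ci : 3 * ci + 3]
            new_codon = codon[:off] + new_base + codon[off + 1 :]
            if _translate_codon(new_codon) == _translate_codon(codon):
                continue
            if ci == 0 or _translate_codon(codon) == "*":
                continue  # keep it a plain missense/nonsense in the body
            d = abs(gpos - config.causal_pos)
            if best is None or d < best[0]:
                ref = coding_base if model.strand == "+" else reverse_complement(coding_base)
                alt = new_base if model.strand == "+" else reverse_complement(new_base)
                best = (d, gpos, ref, alt)
        idx += seg_len
    if best is None:
        raise ValueError("no nonsynonymous EMS site available in the causal gene")
    _d, gpos, ref, alt = best
    return Mutation(config.causal_chrom, int(gpos), ref, alt, causal=True)


# --- the pool -------------------------------------------------------------


@dataclass
class Pool:
    """The pooled homozygous-mutant F2 lines plus the simulation truth."""

    lines: list  # list of dict chrom -> (RecombinantChromosome, RecombinantChromosome)
    causal_chrom: str
    causal_pos: int
    n_f2_screened: int
    n_mutant_found: int
    seed: int

    @property
    def n_pooled(self) -> int:
        return len(self.lines)

    def hawaiian_frequency(self, chrom: str, positions) -> np.ndarray:
        """Pooled Hawaiian allele frequency at each position."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        acc = np.zeros(len(positions), dtype=float)
        for line in self.lines:
            for gam in line[chrom]:
                acc += gam.ancestry_at_many(positions)
        return acc / (2 * len(self.lines))


def simulate_mutant_pool(
    model: ReferenceModel,
    n_f2: Optional[int] = None,
    n_pooled: Optional[int] = None,
    seed: int = 0,
) -> Pool:
    """Single F2s from the cross and pool the homozygous-mutant ones.

    Each F2 pairs two independent F1 gametes per chromosome; an F2 is
    'mutant' iff both homologs are N2 at the causal locus (the Mendelian
    expectation is 1/4).  The first ``n_pooled`` mutants found among
    ``n_f2`` singled F2s form the pool; running short raises with advice
    to raise ``n_f2``.
    """
    cfg = model.config
    if n_f2 is None:
        n_f2 = cfg.n_f2
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    if n_pooled is None:
        n_pooled = cfg.n_pooled
    n_pooled_floor = None
    if n_pooled is None:
        # as in the experiment: pool however many mutant plates turn up,
        # within the configured range
        lo, hi = cfg.n_pooled_range
        n_pooled = int(rng.integers(lo, hi + 1))
        n_pooled_floor = lo
    causal = model.causal
    lines = []
    n_mutant = 0
    for _ in range(n_f2):
        f2 = {
            chrom: (
                simulate_gamete(model.genetic_map, chrom, rng),
                simulate_gamete(model.genetic_map, chrom, rng),
            )
            for chrom in cfg.chromosomes
        }
        g1, g2 = f2[causal.chrom]
        is_mutant = (
            g1.ancestry_at(causal.pos) == N2 and g2.ancestry_at(causal.pos) == N2
        )
        if not is_mutant and cfg.contamination_rate > 0:
            # phenotype mis-scoring: a het escaper may slip into the pool
            het = (g1.ancestry_at(causal.pos) == N2) != (
                g2.ancestry_at(causal.pos) == N2
            )
            is_mutant = het and rng.random() < cfg.contamination_rate
        if is_mutant:
            n_mutant += 1
            if len(lines) < n_pooled:
                lines.append(f2)
    if len(lines) < n_pooled:
        if n_pooled_floor is not None and len(lines) >= n_pooled_floor:
            pass  # pool what was found, still within the configured range
        else:
            raise ValueError(
                f"only {len(lines)} homozygous-mutant F2s among {n_f2} singled; "
                f"needed {n_pooled} — increase n_f2"
            )
    return Pool(
        lines=lines,
        causal_chrom=causal.chrom,
        causal_pos=causal.pos,
        n_f2_screened=n_f2,
        n_mutant_found=n_mutant,
        seed=seed,
    )


# --- pooled sequencing ----------------------------------------------------


def simulate_pool_vcf(
    pool: Pool,
    model: ReferenceModel,
    mean_depth: Optional[float] = None,
    error_rate: Optional[float] = None,
    seed: int = 0,
    emit_zero_alt: Optional[bool] = None,
) -> list:
    """Sample pooled read counts at every informative site.

    Site depth ~ Poisson(mean_depth); alt reads ~ Binomial(depth, p) with
    p = freq*(1-e) + (1-freq)*e, where freq is the pool allele frequency:
    the Hawaiian-ancestry fraction for catalog SNPs and the N2-ancestry
    fraction for parental-background and induced sites (both of which ride
    the mutagenized N2 founder haplotype).  The causal site has freq 1
    exactly before error.  Sites drawing zero alt reads are suppressed
    unless ``emit_zero_alt`` (a variant caller would not report them).
    """
    cfg = model.config
    if mean_depth is None:
        mean_depth = cfg.mean_depth
    if error_rate is None:
        error_rate = cfg.error_rate
    if emit_zero_alt is None:
        emit_zero_alt = cfg.emit_zero_alt
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))

    by_chrom: dict = {c: [] for c in cfg.chromosomes}
    for chrom, p, ref, alt in sorted(model.hawaiian.entries):
        by_chrom[chrom].append((p, ref, alt, "hawaiian"))
    for chrom, p, ref, alt in sorted(model.parental.entries):
        by_chrom[chrom].append((p, ref, alt, "parental"))
    for m in model.induced:
        by_chrom[m.chrom].append((m.pos, m.ref, m.alt, "induced"))

    calls = []
    for chrom in cfg.chromosomes:
        sites = sorted(by_chrom[chrom])
        if not sites:
            continue
        pos = np.array([s[0] for s in sites], dtype=np.int64)
        haw_freq = pool.hawaiian_frequency(chrom, pos)
        freq = np.array(
            [
                hf if origin == "hawaiian" else 1.0 - hf
                for (hf, (_p, _r, _a, origin)) in zip(haw_freq, sites)
            ]
        )
        p_err = freq * (1.0 - error_rate) + (1.0 - freq) * error_rate
        depth = rng.poisson(mean_depth, size=len(sites))
        alt_reads = rng.binomial(depth, p_err)
        for (p_, ref, alt, _origin), d, a in zip(sites, depth, alt_reads):
            if a == 0 and not emit_zero_alt:
                continue
            calls.append(
                VariantCall(
                    chrom=chrom,
                    pos=int(p_),
                    ref=ref,
                    alt=alt,
                    ref_depth=int(d - a),
                    alt_depth=int(a),
                )
            )
    return calls


# --- output ---------------------------------------------------------------


def write_pool_vcf(calls: Sequence[VariantCall], config: SimConfig, path: str) -> None:
    """Emit the pooled calls as a minimal VCF 4.2 with GT:AD:DP.

    Output is byte-deterministic for a fixed call list.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hawmap-synthetic-cross\n")
        for chrom, length in config.chromosomes.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool\n")
        for c in calls:
            dp = c.ref_depth + c.alt_depth
            gt = "1/1" if dp and c.alt_depth / dp > 0.85 else "0/1"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{c.ref_depth},{c.alt_depth}:{dp}\n"
            )


def write_truth(pool: Pool, model: ReferenceModel, path: str) -> None:
    """Per-line breakpoint truth plus the causal lesion and stream seeds."""
    with open(path, "w") as fh:
        fh.write(f"#causal\t{pool.causal_chrom}\t{pool.causal_pos}\n")
        fh.write(f"#model_seed\t{model.seed}\n")
        fh.write(f"#pool_seed\t{pool.seed}\n")
        fh.write(
            f"#n_f2_screened\t{pool.n_f2_screened}\t"
            f"n_mutant\t{pool.n_mutant_found}\tn_pooled\t{pool.n_pooled}\n"
        )
        fh.write("line\tchrom\tcopy\tbreakpoints\tancestries\n")
        for i, line in enumerate(pool.lines):
            for chrom, pair in line.items():
                for j, gam in enumerate(pair):
                    bks = ",".join(str(b) for b in gam.breakpoints) or "."
                    anc = ",".join(gam.ancestries)
                    fh.write(f"{i}\t{chrom}\t{j}\t{bks}\t{anc}\n")
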