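"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
All coordinates are **1-based inclusive** internally (the VCF/GFF3
convention).  The single place where that changes is BED export, which is
0-based half-open; :func:`write_interval_bed` performs that conversion and
:func:`read_interval_bed` reverses it.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# --- variant labels -------------------------------------------------------

LABEL_HAWAIIAN = "hawaiian"
LABEL_PARENTAL = "parental"
LABEL_NOVEL = "novel"
LABEL_UNCLASSIFIED = "unclassified"
VALID_LABELS = frozenset(
    {LABEL_HAWAIIAN, LABEL_PARENTAL, LABEL_NOVEL, LABEL_UNCLASSIFIED}
)


@dataclass(slots=True)
class VariantCall:
    """One called site from a pooled-sequencing experiment.

    ``pos`` is 1-based.  ``ref_depth``/``alt_depth`` are per-allele read
    counts (the VCF ``AD`` field).  ``label`` records the inferred origin of
    the alternate allele: a known Hawaiian (CB4856) polymorphism, a known
    pre-mutagenesis (parental background) variant, or a novel call.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_depth: int
    alt_depth: int
    label: str = LABEL_UNCLASSIFIED
    effect: Optional[object] = None  # EffectAnnotation, set by annotation

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(
                f"ref and alt alleles are identical at {self.chrom}:{self.pos}"
            )
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError(
                f"negative read depth at {self.chrom}:{self.pos}"
            )
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def alt_fraction(self) -> float:
        """Alternate-read fraction; raises on zero total depth."""
        total = self.total_depth
        if total == 0:
            raise ZeroDivisionError(
                f"zero total depth at {self.chrom}:{self.pos}"
            )
        return self.alt_depth / total

    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class SnpCatalog:
    """A set of known strain-background polymorphisms.

    Entries are allele-exact ``(chrom, pos, ref, alt)`` tuples; membership
    tests use ``(chrom, pos, alt)`` so a novel allele at a catalogued
    position is *not* treated as a catalog hit.
    """

    entries: frozenset = field(default_factory=frozenset)
    source: str = "hawaiian"

    def __post_init__(self) -> None:
        if self.source not in ("hawaiian", "parental"):
            raise ValueError(f"unknown catalog source {self.source!r}")
        keys = {(c, p, a) for (c, p, _r, a) in self.entries}
        if len(keys) != len(self.entries):
            raise ValueError("duplicate (chrom, pos, alt) entries in catalog")
        for (_c, p, _r, _a) in self.entries:
            if p < 1:
                raise ValueError(f"catalog position {p} < 1")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def key_set(self) -> frozenset:
        """The allele-exact ``(chrom, pos, alt)`` membership set."""
        return frozenset((c, p, a) for (c, p, _r, a) in self.entries)

    def __contains__(self, key) -> bool:
        return key in self.key_set

    def positions_on(self, chrom: str) -> np.ndarray:
        """Sorted unique positions of catalog entries on ``chrom``."""
        pos = sorted({p for (c, p, _r, _a) in self.entries if c == chrom})
        return np.asarray(pos, dtype=np.int64)


@dataclass
class GeneModel:
    """A minimal protein-coding gene model for effect annotation.

    ``cds`` holds 1-based inclusive genomic intervals in *translation order*
    (descending coordinates for minus-strand genes).  ``usable`` is cleared
    when the total CDS length is not a multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: tuple  # tuple of (start, end) in translation order
    protein_length: Optional[int] = None
    usable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        spans = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        if self.cds_length % 3 != 0:
            if self.protein_length is not None:
                raise ValueError(
                    f"CDS length of {self.gene_id} not divisible by 3"
                )
            self.usable = False

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for (s, e) in self.cds)

    @property
    def span(self) -> tuple:
        """Genomic (start, end) covered by the CDS segments."""
        return (min(s for s, _ in self.cds), max(e for _, e in self.cds))


# --- genome stores --------------------------------------------------------


class FastaGenome:
    """Thin 1-based-inclusive fetch interface over an indexed FASTA."""

    def __init__(self, path: str):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fa:
            raise KeyError(f"contig {chrom!r} not present in FASTA")
        return str(self._fa[chrom][start - 1 : end]).upper()

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def lengths(self) -> dict:
        return {name: len(rec) for name, rec in self._fa.items()}


def read_genome(path: str) -> FastaGenome:
    """Open a FASTA for 1-based random access."""
    return FastaGenome(path)


# --- variant call input ---------------------------------------------------

_TSV_CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_depth", "alt_depth"]


def read_variant_calls(path: str) -> list:
    """Read pooled variant calls from a VCF (with AD) or a TSV.

    Returns one :class:`VariantCall` per biallelic record with
    ``label='unclassified'``; multiallelic VCF records are split per alt
    allele (the depths of the other alts are dropped, with a warning).
    A VCF record lacking allelic-depth information raises ``ValueError``
    naming the record.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_calls_vcf(path)
    return _read_calls_tsv(path)


def _read_calls_vcf(path: str) -> list:
    from cyvcf2 import VCF

    calls: list = []
    last = None
    unsorted_flagged = False
    vcf = VCF(path)
    try:
        for rec in vcf:
            ad = rec.format("AD")
            if ad is None:
                raise ValueError(
                    f"record {rec.CHROM}:{rec.POS} has no AD (allelic depth) field"
                )
            ad = np.asarray(ad[0]).ravel()
            if np.any(ad < 0):
                raise ValueError(
                    f"record {rec.CHROM}:{rec.POS} has missing allelic depths"
                )
            if len(rec.ALT) > 1:
                logger.warning(
                    "multiallelic record %s:%d split into %d biallelic calls; "
                    "depths of other alts ignored",
                    rec.CHROM,
                    rec.POS,
                    len(rec.ALT),
                )
            if last is not None and rec.CHROM == last[0] and rec.POS < last[1]:
                if not unsorted_flagged:
                    logger.warning("input %s is not position-sorted", path)
                    unsorted_flagged = True
            last = (rec.CHROM, rec.POS)
            for i, alt in enumerate(rec.ALT):
                calls.append(
                    VariantCall(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        ref_depth=int(ad[0]),
                        alt_depth=int(ad[i + 1]),
                    )
                )
    finally:
        vcf.close()
    return calls


def _read_calls_tsv(path: str) -> list:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _TSV_CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"call TSV {path} missing columns: {missing}")
    return [
        VariantCall(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            ref_depth=int(r.ref_depth),
            alt_depth=int(r.alt_depth),
        )
        for r in df.itertuples()
    ]


def write_variant_calls_tsv(calls: Iterable[VariantCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_CALL_COLUMNS + ["label"]) + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t"
                f"{c.ref_depth}\t{c.alt_depth}\t{c.label}\n"
            )


# --- SNP catalogs ---------------------------------------------------------


def read_snp_catalog(path: str, source: str) -> SnpCatalog:
    """Read a strain-background SNP catalog from a VCF or a 4-column TSV.

    Duplicated rows are collapsed; the resulting size is logged.  An empty
    file yields an empty catalog with a warning.
    """
    path = str(path)
    rows: set = set()
    if path.endswith((".vcf", ".vcf.gz")):
        from cyvcf2 import VCF

        vcf = VCF(path)
        try:
            for rec in vcf:
                for alt in rec.ALT:
                    if rec.POS < 1:
                        raise ValueError(f"catalog position {rec.POS} < 1")
                    rows.add((rec.CHROM, rec.POS, rec.REF, alt))
        finally:
            vcf.close()
    else:
        with open(path) as fh:
            header_seen = False
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if not header_seen and parts[0] == "chrom":
                    header_seen = True
                    continue
                chrom, pos, ref, alt = parts[:4]
                pos = int(pos)
                if pos < 1:
                    raise ValueError(f"catalog position {pos} < 1 in {path}")
                rows.add((chrom, pos, ref, alt))
    if not rows:
        logger.warning("catalog %s is empty", path)
    cat = SnpCatalog(entries=frozenset(rows), source=source)
    logger.info("read %d %s catalog entries from %s", len(cat), source, path)
    return cat


def write_snp_catalog(catalog: SnpCatalog, path: str) -> None:
    """Write a catalog as a 4-column TSV (sorted, round-trip exact)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(catalog.entries):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


# --- BED interval export --------------------------------------------------


def write_interval_bed(intervals: Sequence, path: str) -> None:
    """Write mapping intervals as BED (0-based half-open).

    Internal 1-based inclusive ``start..end`` becomes ``start-1, end``.
    Columns beyond BED3: name, a score of the catalog-SNP count inside,
    and a selected flag.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.end < iv.start:
                raise ValueError(
                    f"interval end < start on {iv.chrom}: {iv.start}..{iv.end}"
                )
            name = f"{iv.chrom}_gap"
            sel = "selected" if getattr(iv, "selected", False) else "."
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t"
                f"{getattr(iv, 'n_catalog_snps_inside', 0)}\t{sel}\n"
            )


def read_interval_bed(path: str) -> list:
    """Read BED intervals back to 1-based inclusive (chrom, start, end, selected)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, b_start, b_end = parts[0], int(parts[1]), int(parts[2])
            selected = len(parts) > 5 and parts[5] == "selected"
            out.append((chrom, b_start + 1, b_end, selected))
    return out


# --- gene models ----------------------------------------------------------


def read_gene_models(path: str) -> list:
    """Read GFF3 gene/mRNA/CDS features into :class:`GeneModel` objects.

    CDS segments are returned in translation order (reversed for
    minus-strand genes).  Models whose total CDS length is not a multiple
    of 3 are flagged ``usable=False`` with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        segs = sorted(
            (c.start, c.end)
            for c in db.children(gene, featuretype="CDS")
        )
        if not segs:
            continue
        if gene.strand == "-":
            segs = segs[::-1]
        total = sum(e - s + 1 for s, e in segs)
        usable = total % 3 == 0
        if not usable:
            logger.warning(
                "gene %s: CDS length %d not divisible by 3; "
                "flagged unusable for annotation",
                gene.id,
                total,
            )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds=tuple(segs),
                usable=usable,
            )
        )
    return models


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cds_sequence(model: GeneModel, genome) -> str:
    """Concatenated coding sequence of ``model``, 5'->3' on the coding strand.

    Raises ``KeyError`` if the genome lacks the model's contig.
    """
    parts = []
    for s, e in model.cds:
        seg = genome.fetch(model.chrom, s, e)
        if model.strand == "-":
            seg = reverse_complement(seg)
        parts.append(seg)
    return "".join(parts)


def write_gene_models_gff3(models: Sequence[GeneModel], path: str) -> None:
    """Write minimal GFF3 (gene + mRNA + CDS with phase)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span
            fh.write(
                f"{m.chrom}\thawmap\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\thawmap\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            phase = 0
            for s, e in m.cds:
                fh.write(
                    f"{m.chrom}\thawmap\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID={m.gene_id}.cds;Parent={m.gene_id}.t1\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
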