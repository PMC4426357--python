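"""Candidate-lesion annotation: codon effects, descriptor parsing,
genetic-code consistency, and the candidate filter.

A candidate lesion is a novel, homozygous (>85% alt-read fraction),
nonsynonymous variant inside the mapping interval.  The effect annotator is
deliberately minimal: SNVs in CDS are classified by translating the
affected codon before/after (standard nuclear code, minus-strand genes via
reverse complement); indels whose length is not a multiple of 3 are
frameshifts; SNVs within 2 intronic bases of a CDS boundary are splice
variants; everything else is noncoding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Data.IUPACData import protein_letters_3to1

from .formats_io import (
    LABEL_NOVEL,
    GeneModel,
    VariantCall,
    cds_sequence,
    reverse_complement,
)
from .snp_classification import HOMOZYGOUS_THRESHOLD, is_homozygous

_CODON_TABLE = unambiguous_dna_by_id[1]  # standard nuclear code
_STOP_CODONS = set(_CODON_TABLE.stop_codons)
SPLICE_WINDOW = 2  # intronic bases on each side of a CDS boundary


class EffectClass(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    NONCODING = "noncoding"
    START_LOSS = "start_loss"
    STOP_LOSS = "stop_loss"


NONSYNONYMOUS = frozenset(
    {
        EffectClass.MISSENSE,
        EffectClass.NONSENSE,
        EffectClass.FRAMESHIFT,
        EffectClass.SPLICE,
        EffectClass.START_LOSS,
        EffectClass.STOP_LOSS,
    }
)


def translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stop."""
    codon = codon.upper()
    if codon in _STOP_CODONS:
        return "*"
    return _CODON_TABLE.forward_table[codon]


@dataclass
class EffectAnnotation:
    effect: EffectClass
    gene_id: Optional[str] = None
    codon_from: Optional[str] = None
    codon_to: Optional[str] = None
    aa_from: Optional[str] = None
    aa_to: Optional[str] = None
    aa_pos: Optional[int] = None  # 1-based from the initiator Met

    @property
    def aa_change(self) -> str:
        if self.aa_from is None:
            return self.effect.value
        to = "stop" if self.aa_to == "*" else _one_to_three(self.aa_to)
        return f"{_one_to_three(self.aa_from)}{self.aa_pos}{to}"


@dataclass
class CandidateVariant:
    """A filtered candidate lesion with its annotation."""

    call: VariantCall
    annotation: EffectAnnotation
    ems_transition: bool

    @property
    def chrom(self) -> str:
        return self.call.chrom

    @property
    def pos(self) -> int:
        return self.call.pos


_THREE_TO_ONE = {k.capitalize(): v for k, v in protein_letters_3to1.items()}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def _one_to_three(aa1: str) -> str:
    return "stop" if aa1 == "*" else _ONE_TO_THREE[aa1]


def _aa_to_one(aa: str) -> str:
    """3-letter code or 'stop' -> 1-letter; unknown codes raise."""
    key = aa.strip().capitalize()
    if key == "Stop":
        return "*"
    try:
        return _THREE_TO_ONE[key]
    except KeyError:
        raise ValueError(f"unknown amino-acid code {aa!r}") from None


# --- effect annotation ----------------------------------------------------


def _cds_index(model: GeneModel, pos: int) -> Optional[int]:
    """0-based index of ``pos`` within the coding sequence, or None."""
    acc = 0
    for s, e in model.cds:
        if s <= pos <= e:
            return acc + (pos - s if model.strand == "+" else e - pos)
        acc += e - s + 1
    return None


def _in_splice_region(model: GeneModel, pos: int) -> bool:
    spans = sorted(model.cds)
    for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
        # intron between e1 and s2 (exclusive)
        if e1 + 1 <= pos <= e1 + SPLICE_WINDOW:
            return True
        if s2 - SPLICE_WINDOW <= pos <= s2 - 1:
            return True
    return False


def annotate_effect(
    variant: VariantCall,
    gene_models: Sequence[GeneModel],
    genome,
) -> EffectAnnotation:
    """Classify one variant against the gene models.

    The variant's ref allele must match the reference base(s) at its
    position, else ``ValueError`` — that mismatch means the call and the
    reference disagree and any codon arithmetic would be fiction.
    """
    ref_here = genome.fetch(
        variant.chrom, variant.pos, variant.pos + len(variant.ref) - 1
    )
    if ref_here != variant.ref:
        raise ValueError(
            f"variant ref {variant.ref!r} inconsistent with reference "
            f"{ref_here!r} at {variant.chrom}:{variant.pos}"
        )
    for model in gene_models:
        if model.chrom != variant.chrom or not model.usable:
            continue
        lo, hi = model.span
        if not (lo - SPLICE_WINDOW <= variant.pos <= hi + SPLICE_WINDOW):
            continue
        idx = _cds_index(model, variant.pos)
        if idx is not None:
            if variant.is_snv():
                return _annotate_cds_snv(variant, model, genome, idx)
            delta = len(variant.alt) - len(variant.ref)
            if delta % 3 != 0:
                return EffectAnnotation(
                    effect=EffectClass.FRAMESHIFT, gene_id=model.gene_id
                )
            # in-frame indel: reported as missense (coding, non-frameshift)
            return EffectAnnotation(
                effect=EffectClass.MISSENSE, gene_id=model.gene_id
            )
        if variant.is_snv() and _in_splice_region(model, variant.pos):
            return EffectAnnotation(
                effect=EffectClass.SPLICE, gene_id=model.gene_id
            )
    return EffectAnnotation(effect=EffectClass.NONCODING)


def _annotate_cds_snv(
    variant: VariantCall, model: GeneModel, genome, idx: int
) -> EffectAnnotation:
    cds = _cached_cds(model, genome)
    alt_coding = (
        variant.alt if model.strand == "+" else reverse_complement(variant.alt)
    )
    ci, off = divmod(idx, 3)
    codon_from = cds[3 * ci : 3 * ci + 3]
    codon_to = codon_from[:off] + alt_coding + codon_from[off + 1 :]
    aa_from = translate_codon(codon_from)
    aa_to = translate_codon(codon_to)
    if aa_from == aa_to:
        effect = EffectClass.SYNONYMOUS
    elif aa_to == "*":
        effect = EffectClass.NONSENSE
    elif aa_from == "*":
        effect = EffectClass.STOP_LOSS
    elif ci == 0 and aa_from == "M":
        effect = EffectClass.START_LOSS
    else:
        effect = EffectClass.MISSENSE
    return EffectAnnotation(
        effect=effect,
        gene_id=model.gene_id,
        codon_from=codon_from,
        codon_to=codon_to,
        aa_from=aa_from,
        aa_to=aa_to,
        aa_pos=ci + 1,
    )


def _cached_cds(model: GeneModel, genome) -> str:
    cache = getattr(model, "_cds_cache", None)
    if cache is None:
        cache = cds_sequence(model, genome)
        try:
            model._cds_cache = cache
        except AttributeError:
            pass
    return cache


# --- candidate filter -----------------------------------------------------


def ems_flag(ref: str, alt: str) -> bool:
    """True for the EMS signature G:C->A:T on either strand."""
    return (ref, alt) in {("G", "A"), ("C", "T")}


def filter_candidates(
    calls: Iterable[VariantCall],
    interval,
    gene_models: Sequence[GeneModel],
    genome,
    threshold: float = HOMOZYGOUS_THRESHOLD,
) -> list:
    """The candidate-lesion list for one mapping interval.

    Keeps calls that are (a) inside the interval, (b) novel, (c)
    homozygous at ``threshold`` (strict), and (d) nonsynonymous; sorted by
    position.
    """
    out = []
    for c in calls:
        if not interval.contains(c.chrom, c.pos):
            continue
        if c.label != LABEL_NOVEL:
            continue
        if c.total_depth == 0 or not is_homozygous(c, threshold):
            continue
        ann = annotate_effect(c, gene_models, genome)
        if ann.effect not in NONSYNONYMOUS:
            continue
        out.append(
            CandidateVariant(
                call=c,
                annotation=ann,
                ems_transition=c.is_snv() and ems_flag(c.ref, c.alt),
            )
        )
    out.sort(key=lambda cv: (cv.chrom, cv.pos))
    return out


def candidates_to_frame(candidates: Sequence[CandidateVariant]):
    """Candidate list as a table mirroring the published column style."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in candidates],
            "pos": [c.pos for c in candidates],
            "gene": [c.annotation.gene_id for c in candidates],
            "mutation": [f"{c.call.ref}->{c.call.alt}" for c in candidates],
            "aa_change": [c.annotation.aa_change for c in candidates],
            "effect": [c.annotation.effect.value for c in candidates],
            "alt_fraction": [round(c.call.alt_fraction, 3) for c in candidates],
            "ems_transition": [c.ems_transition for c in candidates],
        }
    )


# --- printed-table descriptor handling ------------------------------------

_SNV_DESCRIPTOR = re.compile(
    r"^\s*([ACGT])\s*->\s*([ACGT])\s*,\s*"
    r"([A-Z][a-z]{2})(\d+)\s*(stop|[A-Z][a-z]{2})\s*$"
)
_INDEL_DESCRIPTOR = re.compile(r"frameshift", re.IGNORECASE)


@dataclass
class ParsedDescriptor:
    effect: EffectClass
    nt_from: Optional[str] = None
    nt_to: Optional[str] = None
    aa_from: Optional[str] = None  # 3-letter
    aa_to: Optional[str] = None  # 3-letter or 'stop'
    aa_pos: Optional[int] = None


def parse_descriptor(text: str) -> ParsedDescriptor:
    """Parse a table-style mutation descriptor.

    Recognised styles: ``"G->A, Gly42Arg"`` (missense), ``"G->A,
    Trp1062stop"`` (nonsense), and free-text insertions/deletions that name
    a frameshift.  Anything else raises with the offending text.
    """
    m = _SNV_DESCRIPTOR.match(text)
    if m:
        nt_from, nt_to, aa_from, aa_pos, aa_to = m.groups()
        _aa_to_one(aa_from)  # raises on unknown codes
        if aa_to != "stop":
            _aa_to_one(aa_to)
        effect = EffectClass.NONSENSE if aa_to == "stop" else EffectClass.MISSENSE
        return ParsedDescriptor(
            effect=effect,
            nt_from=nt_from,
            nt_to=nt_to,
            aa_from=aa_from,
            aa_to=aa_to,
            aa_pos=int(aa_pos),
        )
    if _INDEL_DESCRIPTOR.search(text):
        return ParsedDescriptor(effect=EffectClass.FRAMESHIFT)
    raise ValueError(f"unrecognised mutation descriptor: {text!r}")


def classify_descriptor(text: str) -> EffectClass:
    return parse_descriptor(text).effect


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def check_substitution_consistency(
    aa_from: str, aa_to: str, nt_from: str, nt_to: str
):
    """Can ``aa_from -> aa_to`` arise from a single ``nt_from -> nt_to``?

    The genomic substitution is strand-agnostic, so the complement change
    is tried as well.  Returns ``(ok, witnesses)`` where each witness is a
    ``(codon_from, codon_to, strand)`` triple ('+' = change as printed on
    the coding strand, '-' = via the complement).
    """
    for nt in (nt_from, nt_to):
        if nt not in _COMP:
            raise ValueError(f"bad nucleotide {nt!r}")
    one_from = _aa_to_one(aa_from)
    one_to = _aa_to_one(aa_to)
    if one_from == "*":
        codons_from = sorted(_STOP_CODONS)
    else:
        codons_from = sorted(
            c for c, a in _CODON_TABLE.forward_table.items() if a == one_from
        )
    witnesses = []
    for strand, (f, t) in (
        ("+", (nt_from, nt_to)),
        ("-", (_COMP[nt_from], _COMP[nt_to])),
    ):
        for codon in codons_from:
            for i, base in enumerate(codon):
                if base != f:
                    continue
                new = codon[:i] + t + codon[i + 1 :]
                if translate_codon(new) == one_to:
                    witnesses.append((codon, new, strand))
    return bool(witnesses), witnesses


def truncation_length(protein_length_aa: int, stop_codon_position: int) -> int:
    """Codons removed by a premature stop (strictly C-terminal residues).

    A stop at the final codon removes nothing; a stop position beyond the
    protein raises.
    """
    if not (1 <= stop_codon_position <= protein_length_aa):
        raise ValueError(
            f"stop position {stop_codon_position} outside protein of "
            f"{protein_length_aa} aa"
        )
    return protein_length_aa - stop_codon_position
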