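"""CRISPR/Cas9 HDR edit verification and design helpers.

Covers the in-silico side of single-nucleotide repair experiments:
locating a guide's protospacer next to an SpCas9 NGG PAM, the blunt cut
site 3 bp 5' of the PAM, diffing repair oligos against each other or a
reference to recover the installed edits and homology-arm lengths,
IUPAC-degenerate restriction-site scanning (for diagnostic digests of the
silent PAM-destroying edit), and enumeration of synonymous PAM-silencing
substitutions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .candidate_annotation import _cds_index, _cached_cds, translate_codon
from .formats_io import reverse_complement

# IUPAC nucleotide degeneracy
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# built-in diagnostic enzymes; extensible by passing a custom table
ENZYME_TABLE = {
    "EaeI": "YGGCCR",
    "EcoRI": "GAATTC",
    "BamHI": "GGATCC",
    "HindIII": "AAGCTT",
    "NotI": "GCGGCCGC",
    "DraI": "TTTAAA",
}


@dataclass(frozen=True)
class GuideSite:
    """A protospacer match with its NGG PAM, on the plus-strand axis.

    ``start``/``end`` are the 1-based inclusive protospacer span on the
    plus strand; ``cut_after`` is the between-base coordinate of the blunt
    cut (the cut falls between ``cut_after`` and ``cut_after + 1``),
    always 3 bp 5' of the PAM on the protospacer strand.
    """

    protospacer: str
    strand: str
    pam: str
    start: int
    end: int
    pam_start: int
    pam_end: int
    cut_after: int


def locate_protospacer(guide: str, target: str) -> list:
    """All exact protospacer+NGG matches of ``guide`` in ``target``.

    Both strands are searched; guides of 17-20 nt with unambiguous bases
    only.  Returns an empty list when the guide has no valid site (e.g.
    after a PAM-destroying silent edit).
    """
    guide = guide.upper()
    if not (17 <= len(guide) <= 20):
        raise ValueError("guide must be 17-20 nt")
    if set(guide) - set("ACGT"):
        raise ValueError("guide contains ambiguous bases")
    target = target.upper()
    sites = []
    L = len(guide)
    # plus strand: guide ... NGG
    for i in range(len(target) - L - 2):
        if target[i : i + L] != guide:
            continue
        pam = target[i + L : i + L + 3]
        if pam[1:] == "GG":
            start, end = i + 1, i + L
            sites.append(
                GuideSite(
                    protospacer=guide,
                    strand="+",
                    pam=pam,
                    start=start,
                    end=end,
                    pam_start=end + 1,
                    pam_end=end + 3,
                    cut_after=end - 3,
                )
            )
    # minus strand: CCN ... revcomp(guide) on the plus axis
    rc = reverse_complement(guide)
    for i in range(3, len(target) - L + 1):
        if target[i : i + L] != rc:
            continue
        pam_plus = target[i - 3 : i]  # plus-strand bases of the PAM triplet
        pam = reverse_complement(pam_plus)
        if pam[1:] == "GG":
            start, end = i + 1, i + L  # protospacer span on plus axis
            sites.append(
                GuideSite(
                    protospacer=guide,
                    strand="-",
                    pam=pam,
                    start=start,
                    end=end,
                    pam_start=start - 3,
                    pam_end=start - 1,
                    cut_after=start + 2,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def cut_site(site: GuideSite) -> int:
    """Blunt-cut between-base coordinate (3 bp 5' of the PAM).

    Returned on the plus-strand axis: the cut lies between ``coord`` and
    ``coord + 1``.  Always inside the protospacer span.
    """
    return site.cut_after


# --- repair oligo verification --------------------------------------------


@dataclass
class RepairOligo:
    """Edits recovered from an HDR donor and its homology-arm lengths."""

    sequence: str
    edits: list  # (1-based position in oligo, from_base, to_base)
    arm5: Optional[int]
    arm3: Optional[int]
    offset_in_reference: Optional[int] = None  # 1-based, reference mode only


def verify_repair_oligo(
    oligo: str, other: str, max_edits: int = 10
) -> RepairOligo:
    """Diff a repair oligo against its sibling oligo or a reference.

    Equal lengths: positional comparison.  Otherwise the shorter sequence
    is slid along the longer (substitution-only alignment) and the
    minimum-mismatch offset is used.  More than ``max_edits`` differences
    raises — that is a misalignment, not an edit set.  Arm lengths are the
    perfect-match flanks outside the first/last edit; identical sequences
    give no edits and undefined arms.
    """
    oligo, other = oligo.upper(), other.upper()
    offset = 0
    if len(oligo) == len(other):
        ref_window = other
    else:
        short, long_ = (oligo, other) if len(oligo) < len(other) else (other, oligo)
        s = np.frombuffer(short.encode(), dtype="S1")
        l = np.frombuffer(long_.encode(), dtype="S1")
        n = len(l) - len(s) + 1
        mismatches = np.array(
            [np.count_nonzero(s != l[i : i + len(s)]) for i in range(n)]
        )
        offset = int(mismatches.argmin())
        if len(oligo) < len(other):
            ref_window = other[offset : offset + len(oligo)]
        else:
            # oligo longer than reference window: compare the overlap only
            oligo = oligo[offset : offset + len(other)]
            ref_window = other
    edits = [
        (i + 1, r, o)
        for i, (o, r) in enumerate(zip(oligo, ref_window))
        if o != r
    ]
    if len(edits) > max_edits:
        raise ValueError(
            f"{len(edits)} differences (> {max_edits}); sequences are "
            "probably misaligned"
        )
    if edits:
        arm5 = edits[0][0] - 1
        arm3 = len(oligo) - edits[-1][0]
    else:
        arm5 = arm3 = None
    return RepairOligo(
        sequence=oligo,
        edits=edits,
        arm5=arm5,
        arm3=arm3,
        offset_in_reference=offset + 1 if len(oligo) != len(other) else None,
    )


# --- restriction scanning -------------------------------------------------


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        try:
            opts = _IUPAC[ch]
        except KeyError:
            raise ValueError(f"bad IUPAC symbol {ch!r} in site pattern") from None
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_restriction_sites(
    sequence: str, enzyme: str, table: Optional[dict] = None
) -> list:
    """1-based start positions of all (possibly overlapping) recognition
    sites of ``enzyme`` on the given strand.

    The enzyme must be in the table (default: the built-in one, which
    includes EaeI = YGGCCR — note that YGGCCR is its own reverse
    complement, so one strand suffices for it).
    """
    table = ENZYME_TABLE if table is None else table
    if enzyme not in table:
        raise ValueError(
            f"unknown enzyme {enzyme!r}; known: {sorted(table)}"
        )
    rx = _iupac_regex(table[enzyme])
    return [m.start() + 1 for m in rx.finditer(sequence.upper())]


# --- PAM silencing --------------------------------------------------------


@dataclass
class PamSilencingOption:
    """One synonymous substitution that destroys the NGG PAM."""

    position: int  # plus-strand axis, 1-based
    from_base: str
    to_base: str
    codon_from: str
    codon_to: str
    creates_sites: list  # enzyme names whose site count increases
    destroys_sites: list


def propose_pam_silencing_edit(
    site: GuideSite,
    gene_model,
    genome,
    enzyme_table: Optional[dict] = None,
    window: int = 12,
) -> list:
    """Synonymous single-base changes in the PAM's GG that kill recutting.

    Enumerates substitutions at PAM positions 2-3 (the GG on the
    protospacer strand), keeps those synonymous in the supplied gene's
    frame, and annotates which create or destroy a diagnostic restriction
    site nearby.  Options creating a new site rank first (they give a
    digest-based screen, the trick used to distinguish edited lines).
    Raises if the PAM does not overlap the gene's CDS; returns an empty
    list (with nothing to rank) when no synonymous option exists.
    """
    enzyme_table = ENZYME_TABLE if enzyme_table is None else enzyme_table
    if site.strand == "+":
        gg_positions = [site.pam_start + 1, site.pam_start + 2]
    else:
        gg_positions = [site.pam_end - 1, site.pam_end - 2]
    in_cds = [p for p in gg_positions if _cds_index(gene_model, p) is not None]
    if not in_cds:
        raise ValueError("PAM does not overlap the gene's coding sequence")
    options = []
    for pos in in_cds:
        idx = _cds_index(gene_model, pos)
        cds = _cached_cds(gene_model, genome)
        ci, off = divmod(idx, 3)
        codon_from = cds[3 * ci : 3 * ci + 3]
        plus_base = genome.base(gene_model.chrom, pos)
        for new_plus in "ACGT":
            if new_plus == plus_base:
                continue
            # the PAM GG is read on the protospacer strand
            guide_strand_base = (
                new_plus if site.strand == "+" else reverse_complement(new_plus)
            )
            if guide_strand_base == "G":
                continue  # would leave the NGG intact
            coding_base = (
                new_plus
                if gene_model.strand == "+"
                else reverse_complement(new_plus)
            )
            codon_to = codon_from[:off] + coding_base + codon_from[off + 1 :]
            if translate_codon(codon_to) != translate_codon(codon_from):
                continue
            lo = max(1, pos - window)
            hi = min(genome.lengths()[gene_model.chrom], pos + window)
            before = genome.fetch(gene_model.chrom, lo, hi)
            after = (
                before[: pos - lo] + new_plus + before[pos - lo + 1 :]
            )
            creates, destroys = [], []
            for enz in enzyme_table:
                nb = len(scan_restriction_sites(before, enz, enzyme_table))
                na = len(scan_restriction_sites(after, enz, enzyme_table))
                if na > nb:
                    creates.append(enz)
                elif na < nb:
                    destroys.append(enz)
            options.append(
                PamSilencingOption(
                    position=pos,
                    from_base=plus_base,
                    to_base=new_plus,
                    codon_from=codon_from,
                    codon_to=codon_to,
                    creates_sites=creates,
                    destroys_sites=destroys,
                )
            )
    options.sort(key=lambda o: (-len(o.creates_sites), o.position, o.to_base))
    return options
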