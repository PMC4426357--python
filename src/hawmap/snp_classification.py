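"""Variant origin labelling and homozygosity calling.

The pooled variant calls are partitioned by origin: known Hawaiian (CB4856)
marker SNPs, known pre-mutagenesis (parental) background variants, and novel
calls — the last group is where the induced lesion must be.  Matching to the
catalogs is allele-exact on (chrom, pos, alt), so a different allele at a
catalogued position counts as novel.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import replace
from typing import Iterable, Sequence

from .formats_io import (
    LABEL_HAWAIIAN,
    LABEL_NOVEL,
    LABEL_PARENTAL,
    SnpCatalog,
    VariantCall,
)

logger = logging.getLogger(__name__)

HOMOZYGOUS_THRESHOLD = 0.85  # alt-read fraction must be STRICTLY above this
MIN_ALT_READS_PRESENT = 2


def classify_variants(
    calls: Iterable[VariantCall],
    hawaiian: SnpCatalog,
    parental: SnpCatalog,
) -> list:
    """Label every call hawaiian / parental / novel (new objects).

    Hawaiian membership wins over parental when a site is somehow in both.
    Per-class counts are logged; the labels partition the input.
    """
    haw_keys = hawaiian.key_set
    par_keys = parental.key_set
    out = []
    counts: Counter = Counter()
    for c in calls:
        key = (c.chrom, c.pos, c.alt)
        if key in haw_keys:
            label = LABEL_HAWAIIAN
        elif key in par_keys:
            label = LABEL_PARENTAL
        else:
            label = LABEL_NOVEL
        counts[label] += 1
        out.append(replace(c, label=label))
    logger.info(
        "classified %d calls: %s", len(out), dict(sorted(counts.items()))
    )
    return out


def is_homozygous(call: VariantCall, threshold: float = HOMOZYGOUS_THRESHOLD) -> bool:
    """True iff the alt-read fraction exceeds ``threshold`` strictly.

    The strictness mirrors the ">85% variant call" homozygosity filter:
    a fraction of exactly 0.85 is NOT homozygous.  Zero total depth raises.
    """
    if call.total_depth == 0:
        raise ValueError(
            f"cannot call homozygosity with zero depth at {call.chrom}:{call.pos}"
        )
    return call.alt_fraction > threshold


def hawaiian_present(
    call: VariantCall, min_alt_reads: int = MIN_ALT_READS_PRESENT
) -> bool:
    """Is this catalogued Hawaiian SNP actually present in the pool?

    Presence requires ``alt_depth >= min_alt_reads``; the default of 2
    resists isolated sequencing-error reads at ~22x coverage.  Calls not
    labelled hawaiian raise.
    """
    if call.label != LABEL_HAWAIIAN:
        raise ValueError(
            f"hawaiian_present called on a {call.label!r} call at "
            f"{call.chrom}:{call.pos}"
        )
    return call.alt_depth >= min_alt_reads


def class_counts(calls: Sequence[VariantCall]) -> dict:
    """Per-label call counts (summary for logs / report TSVs)."""
    return dict(Counter(c.label for c in calls))
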