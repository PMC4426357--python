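"""Hawaiian-SNP density profiles and mapping-interval detection.

The mapping interval is the chromosomal span devoid of Hawaiian marker SNPs
in the pooled recombinants: because every pooled line is homozygous N2 at
the causal locus, Hawaiian alleles are selected away around it, leaving a
gap in the genome-wide ~50% marker background.

Interval detection is exact (run/gap based): per chromosome the interval is
the maximal gap between consecutive *present* Hawaiian SNPs, with the
chromosome ends allowed as open flanks.  Binned density profiles exist for
plotting only.  A secondary "reduction" mode finds the longest run of bins
whose present-SNP count is at most a small threshold, for pools where the
markers are depleted rather than absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import LABEL_HAWAIIAN, SnpCatalog, VariantCall
from .snp_classification import MIN_ALT_READS_PRESENT, hawaiian_present

DEFAULT_BIN_SIZE = 100_000


@dataclass
class DensityProfile:
    """Per-bin counts of present Hawaiian SNPs along one chromosome."""

    chrom: str
    bin_size: int
    bin_starts: np.ndarray  # 1-based start of each bin
    present_counts: np.ndarray
    catalog_totals: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "bin_start": self.bin_starts,
                "bin_end": self.bin_starts + self.bin_size - 1,
                "present": self.present_counts,
                "catalog_total": self.catalog_totals,
            }
        )

    def plot(self, ax=None):
        """Scatter/line plot of present-SNP density vs position (Mb)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        x = (self.bin_starts + self.bin_size / 2) / 1e6
        ax.plot(x, self.present_counts, lw=0.8)
        ax.set_xlabel(f"{self.chrom} position (Mb)")
        ax.set_ylabel(f"Hawaiian SNPs / {self.bin_size // 1000} kb")
        return ax


@dataclass
class MappingInterval:
    """A chromosome span devoid of present Hawaiian SNPs.

    Coordinates are 1-based inclusive; the flanking present SNPs themselves
    are excluded from the span.  ``ambiguous`` marks a chromosome with no
    present SNPs at all (the whole chromosome is returned).
    """

    chrom: str
    start: int
    end: int
    left_flank: Optional[int] = None  # present SNP position or None at chrom end
    right_flank: Optional[int] = None
    n_catalog_snps_inside: int = 0
    genetic_width_cm: Optional[float] = None
    selected: bool = False
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"interval end < start on {self.chrom}: {self.start}..{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def width_mb(self) -> float:
        return self.width / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def _present_positions(
    calls: Sequence[VariantCall], chrom: str, min_alt_reads: int
) -> np.ndarray:
    pos = sorted(
        {
            c.pos
            for c in calls
            if c.chrom == chrom
            and c.label == LABEL_HAWAIIAN
            and hawaiian_present(c, min_alt_reads)
        }
    )
    return np.asarray(pos, dtype=np.int64)


def density_profile(
    calls: Sequence[VariantCall],
    catalog: SnpCatalog,
    chrom: str,
    chrom_length: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_alt_reads: int = MIN_ALT_READS_PRESENT,
) -> DensityProfile:
    """Bin present Hawaiian SNPs (and catalog totals) along ``chrom``."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = int(np.ceil(chrom_length / bin_size))
    edges = np.arange(0, (n_bins + 1) * bin_size, bin_size)
    present = _present_positions(calls, chrom, min_alt_reads)
    cat_pos = catalog.positions_on(chrom)
    present_counts, _ = np.histogram(present, bins=edges)
    catalog_totals, _ = np.histogram(cat_pos, bins=edges)
    return DensityProfile(
        chrom=chrom,
        bin_size=bin_size,
        bin_starts=edges[:-1] + 1,
        present_counts=present_counts,
        catalog_totals=catalog_totals,
    )


def _gaps_for_chrom(
    present: np.ndarray, chrom_length: int
) -> list:
    """All maximal (start, end, left_flank, right_flank) gaps between
    consecutive present SNPs, chromosome ends as open flanks."""
    gaps = []
    bounds = [0, *present.tolist(), chrom_length + 1]
    for left, right in zip(bounds, bounds[1:]):
        start, end = left + 1, right - 1
        if end < start:
            continue
        gaps.append(
            (
                start,
                end,
                None if left == 0 else left,
                None if right == chrom_length + 1 else right,
            )
        )
    return gaps


def detect_interval(
    calls: Sequence[VariantCall],
    catalog: SnpCatalog,
    chrom_lengths: dict,
    genetic_map=None,
    min_alt_reads: int = MIN_ALT_READS_PRESENT,
) -> list:
    """Per-chromosome maximal Hawaiian-SNP gaps, with one marked selected.

    Selection is by largest genetic (cM) width under ``genetic_map``
    (normalising for chromosome length), falling back to physical width
    when no map is supplied; ties break to the lower chromosome name, then
    lower start.  A chromosome with no present SNP at all is returned whole
    and flagged ambiguous.  An empty call set raises.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no variant calls supplied")
    intervals = []
    for chrom, length in chrom_lengths.items():
        present = _present_positions(calls, chrom, min_alt_reads)
        cat_pos = catalog.positions_on(chrom)
        if len(present) == 0:
            iv = MappingInterval(
                chrom=chrom,
                start=1,
                end=length,
                n_catalog_snps_inside=len(cat_pos),
                ambiguous=True,
            )
            if genetic_map is not None and chrom in genetic_map:
                iv.genetic_width_cm = genetic_map.cm_width(chrom, 1, length)
            intervals.append(iv)
            continue
        best = None
        for start, end, lf, rf in _gaps_for_chrom(present, length):
            if genetic_map is not None and chrom in genetic_map:
                width = genetic_map.cm_width(chrom, start, end)
            else:
                width = end - start + 1
            if best is None or width > best[0] or (
                width == best[0] and start < best[1][0]
            ):
                best = (width, (start, end, lf, rf))
        width, (start, end, lf, rf) = best
        n_inside = int(
            np.searchsorted(cat_pos, end, side="right")
            - np.searchsorted(cat_pos, start, side="left")
        )
        iv = MappingInterval(
            chrom=chrom,
            start=start,
            end=end,
            left_flank=lf,
            right_flank=rf,
            n_catalog_snps_inside=n_inside,
        )
        if genetic_map is not None and chrom in genetic_map:
            iv.genetic_width_cm = genetic_map.cm_width(chrom, start, end)
        intervals.append(iv)

    def sel_key(iv: MappingInterval):
        width = (
            iv.genetic_width_cm
            if iv.genetic_width_cm is not None
            else float(iv.width)
        )
        # maximise width; break ties by chrom name then start (ascending)
        return (-width, iv.chrom, iv.start)

    selected = min(intervals, key=sel_key)
    selected.selected = True
    return intervals


def detect_reduction_interval(
    profile: DensityProfile, k: int = 0
) -> Optional[MappingInterval]:
    """Longest run of bins with present-count <= k (the 'reduction' mode).

    For pools where Hawaiian markers are reduced rather than absent, the
    exact gap can be tiny; this binned secondary method returns the span of
    the longest depleted bin run, or None if no bin qualifies.
    """
    ok = profile.present_counts <= k
    if not ok.any():
        return None
    best_len, best_start, run_start = 0, 0, None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    start = int(profile.bin_starts[best_start])
    end = int(profile.bin_starts[best_start + best_len - 1] + profile.bin_size - 1)
    inside = slice(best_start, best_start + best_len)
    return MappingInterval(
        chrom=profile.chrom,
        start=start,
        end=end,
        n_catalog_snps_inside=int(profile.catalog_totals[inside].sum()),
    )


def interval_report(
    intervals: Sequence[MappingInterval], candidates: Sequence = ()
) -> pd.DataFrame:
    """Summary table: chromosome, interval bounds, width (Mb), candidate count.

    One row per interval; the candidate count applies to the interval that
    contains each candidate's position.
    """
    rows = []
    for iv in intervals:
        n_cand = sum(
            1 for c in candidates if iv.contains(c.chrom, c.pos)
        )
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "width_mb": round(iv.width_mb, 3),
                "genetic_width_cm": (
                    round(iv.genetic_width_cm, 3)
                    if iv.genetic_width_cm is not None
                    else np.nan
                ),
                "selected": iv.selected,
                "ambiguous": iv.ambiguous,
                "n_candidates": n_cand,
            }
        )
    return pd.DataFrame(rows)
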