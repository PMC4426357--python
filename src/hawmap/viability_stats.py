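"""Embryonic-viability arithmetic: percent hatching, brood aggregation,
group comparison, complementation verdicts, and Mendelian expectations.

Percent hatching is hatched larvae over total eggs laid, per brood (one
hermaphrodite at one temperature).  Summaries average per-brood percentages
within replicate experiments first and report the mean and SD across the
replicate means, matching how such error bars are conventionally computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FAIL_MAX_DEFAULT = 10.0  # % hatching below which trans-hets fail to complement
COMP_MIN_DEFAULT = 50.0  # % hatching above which they complement


@dataclass(slots=True)
class BroodRecord:
    """One hermaphrodite's brood at one temperature."""

    genotype: str
    temperature: float
    eggs_laid: int
    hatched: int
    replicate: str = "1"

    def __post_init__(self) -> None:
        if not (0 <= self.hatched <= self.eggs_laid):
            raise ValueError(
                f"hatched ({self.hatched}) must be within [0, eggs_laid="
                f"{self.eggs_laid}]"
            )

    @property
    def percent(self) -> float:
        return percent_hatching(self.hatched, self.eggs_laid)


def percent_hatching(hatched: int, eggs_laid: int) -> float:
    """100 * hatched / eggs_laid; zero eggs or hatched > eggs raises."""
    if eggs_laid <= 0:
        raise ValueError("eggs_laid must be positive")
    if hatched < 0 or hatched > eggs_laid:
        raise ValueError("hatched must be between 0 and eggs_laid")
    return 100.0 * hatched / eggs_laid


def read_broods_tsv(path: str) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        BroodRecord(
            genotype=str(r.genotype),
            temperature=float(r.temperature),
            eggs_laid=int(r.eggs_laid),
            hatched=int(r.hatched),
            replicate=str(r.replicate),
        )
        for r in df.itertuples()
    ]


def summarize_broods(
    records: Iterable[BroodRecord], across_replicates: bool = True
) -> pd.DataFrame:
    """Mean %, SD, and embryo totals per (genotype, temperature) group.

    ``across_replicates=True`` (default): per-brood percentages are
    averaged within each replicate experiment, and the mean/SD are taken
    across the replicate means.  ``False``: the SD is taken across all
    broods directly.  SDs use the n-1 (sample) convention; a single
    replicate/brood yields SD 0.
    """
    records = list(records)
    if not records:
        raise ValueError("no brood records supplied")
    df = pd.DataFrame(
        {
            "genotype": [r.genotype for r in records],
            "temperature": [r.temperature for r in records],
            "replicate": [r.replicate for r in records],
            "percent": [r.percent for r in records],
            "eggs_laid": [r.eggs_laid for r in records],
            "hatched": [r.hatched for r in records],
        }
    )
    rows = []
    for (genotype, temp), grp in df.groupby(["genotype", "temperature"], sort=True):
        if across_replicates:
            vals = grp.groupby("replicate")["percent"].mean().to_numpy()
        else:
            vals = grp["percent"].to_numpy()
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "genotype": genotype,
                "temperature": temp,
                "mean_percent": float(np.mean(vals)),
                "sd_percent": sd,
                "n_broods": int(len(grp)),
                "n_replicates": int(grp["replicate"].nunique()),
                "total_eggs": int(grp["eggs_laid"].sum()),
                "total_hatched": int(grp["hatched"].sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ViabilityComparison:
    """Two-group comparison: Welch on brood percentages (primary) plus an
    exact test on pooled hatched/total counts (secondary)."""

    welch_t: float
    welch_p: float
    fisher_odds: float
    fisher_p: float
    mean_a: float
    mean_b: float


def compare_viability(
    group_a: Sequence[BroodRecord], group_b: Sequence[BroodRecord]
) -> ViabilityComparison:
    """Compare hatching between two groups of broods.

    The brood is the experimental unit, so the primary test is a Welch
    two-sample t on per-brood percentages; a two-sided Fisher exact test
    on the pooled hatched/dead counts is reported alongside.  Each group
    needs at least 2 broods.  If both groups are degenerate (zero
    variance) with equal means, p = 1.
    """
    a = np.array([r.percent for r in group_a], dtype=float)
    b = np.array([r.percent for r in group_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 broods per group")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            welch_t, welch_p = 0.0, 1.0
        else:
            welch_t, welch_p = math.inf, 0.0
    else:
        welch_t, welch_p = stats.ttest_ind(a, b, equal_var=False)
        welch_t, welch_p = float(welch_t), float(welch_p)
    ah = sum(r.hatched for r in group_a)
    at = sum(r.eggs_laid for r in group_a)
    bh = sum(r.hatched for r in group_b)
    bt = sum(r.eggs_laid for r in group_b)
    odds, fisher_p = stats.fisher_exact(
        [[ah, at - ah], [bh, bt - bh]], alternative="two-sided"
    )
    return ViabilityComparison(
        welch_t=welch_t,
        welch_p=welch_p,
        fisher_odds=float(odds),
        fisher_p=float(fisher_p),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


@dataclass(frozen=True)
class ComplementationVerdict:
    verdict: str  # 'fails' | 'complements' | 'ambiguous'
    sterility_flag: bool = False
    note: Optional[str] = None


def complementation_verdict(
    transhet_viability: float,
    fail_max: float = FAIL_MAX_DEFAULT,
    comp_min: float = COMP_MIN_DEFAULT,
    sterility_note: Optional[str] = None,
) -> ComplementationVerdict:
    """Score a complementation cross from trans-heterozygote viability (%).

    Below ``fail_max`` the alleles fail to complement (same gene); above
    ``comp_min`` they complement; between is ambiguous.  A sterility note
    on the surviving progeny is carried as a flag, not folded into the
    verdict.
    """
    if not (0.0 <= transhet_viability <= 100.0):
        raise ValueError("viability must be a percentage in [0, 100]")
    if fail_max >= comp_min:
        raise ValueError("fail_max must be below comp_min")
    if transhet_viability < fail_max:
        verdict = "fails"
    elif transhet_viability > comp_min:
        verdict = "complements"
    else:
        verdict = "ambiguous"
    return ComplementationVerdict(
        verdict=verdict,
        sterility_flag=bool(sterility_note),
        note=sterility_note,
    )


_SCHEMES = {
    # selfed heterozygote: the classic recessive-recovery expectation
    "het_self": {"hom_mut": 0.25, "het": 0.5, "hom_wt": 0.25},
    # heterozygote x homozygous mutant
    "het_x_hom": {"hom_mut": 0.5, "het": 0.5, "hom_wt": 0.0},
    # heterozygote x wild type
    "het_x_wt": {"hom_mut": 0.0, "het": 0.5, "hom_wt": 0.5},
}


def mendelian_fraction(scheme: str) -> dict:
    """Exact genotype fractions for standard single-locus cross schemes."""
    try:
        return dict(_SCHEMES[scheme])
    except KeyError:
        raise ValueError(
            f"unknown scheme {scheme!r}; options: {sorted(_SCHEMES)}"
        ) from None
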