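"""End-to-end orchestration: simulate -> classify -> map -> filter.

These functions are the library face of the pipeline; the ``hawmap`` CLI
wraps the same steps for file-based inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .candidate_annotation import filter_candidates
from .interval_mapping import detect_interval
from .snp_classification import classify_variants
from .synthetic_cross import (
    Pool,
    ReferenceModel,
    SimConfig,
    build_reference_model,
    simulate_mutant_pool,
    simulate_pool_vcf,
)


@dataclass
class SimResult:
    model: ReferenceModel
    pool: Pool
    calls: list


@dataclass
class MapResult:
    labeled: list
    intervals: list
    selected: object
    candidates: list


def run_simulation(config: Optional[SimConfig] = None, seed: int = 0) -> SimResult:
    """One full synthetic experiment: reference model, pool, pooled calls."""
    if config is None:
        config = SimConfig()
    model = build_reference_model(config, seed=seed)
    pool = simulate_mutant_pool(model, seed=seed)
    calls = simulate_pool_vcf(pool, model, seed=seed)
    return SimResult(model=model, pool=pool, calls=calls)


def run_mapping(
    sim: SimResult,
    hom_threshold: float = 0.85,
    min_alt_reads: int = 2,
) -> MapResult:
    """Classify the pooled calls, detect the interval, filter candidates."""
    model = sim.model
    labeled = classify_variants(sim.calls, model.hawaiian, model.parental)
    intervals = detect_interval(
        labeled,
        model.hawaiian,
        model.config.chromosomes,
        genetic_map=model.genetic_map,
        min_alt_reads=min_alt_reads,
    )
    selected = next(iv for iv in intervals if iv.selected)
    candidates = filter_candidates(
        labeled, selected, model.gene_models, model.genome,
        threshold=hom_threshold,
    )
    return MapResult(
        labeled=labeled,
        intervals=intervals,
        selected=selected,
        candidates=candidates,
    )


def recovery_batch(
    n_runs: int,
    base_seed: int = 0,
    config: Optional[SimConfig] = None,
) -> pd.DataFrame:
    """Repeat the full simulate->map pipeline over ``n_runs`` seeds.

    Returns one row per run: whether the selected interval contains the
    causal lesion, whether the causal lesion is in the candidate list, the
    interval widths, and the pool size.
    """
    rows = []
    for k in range(n_runs):
        seed = base_seed + k
        sim = run_simulation(config, seed=seed)
        res = run_mapping(sim)
        causal = sim.model.causal
        rows.append(
            {
                "seed": seed,
                "chrom": res.selected.chrom,
                "start": res.selected.start,
                "end": res.selected.end,
                "width_mb": res.selected.width_mb,
                "genetic_width_cm": res.selected.genetic_width_cm,
                "n_pooled": sim.pool.n_pooled,
                "contains_causal": res.selected.contains(causal.chrom, causal.pos),
                "causal_in_candidates": any(
                    c.chrom == causal.chrom and c.pos == causal.pos
                    for c in res.candidates
                ),
                "n_candidates": len(res.candidates),
            }
        )
    return pd.DataFrame(rows)
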