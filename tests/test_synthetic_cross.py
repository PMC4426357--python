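"""synthetic_cross: determinism, gamete law, pool invariants, sequencing model."""

from __future__ import annotations

import numpy as np
import pytest

from hawmap import SimConfig, build_genetic_map, simulate_gamete
from hawmap.formats_io import cds_sequence
from hawmap.synthetic_cross import (
    HAW,
    N2,
    build_reference_model,
    simulate_mutant_pool,
    simulate_pool_vcf,
    write_pool_vcf,
)

from oracles import enumerate_haw_freq, mc_haw_freq, oracle_translate


# --- config ----------------------------------------------------------------


def test_config_validation():
    with pytest.raises(ValueError, match="causal chromosome"):
        SimConfig(chromosomes={"I": 1000}, causal_chrom="V").validate()
    with pytest.raises(ValueError, match="causal position"):
        SimConfig(
            chromosomes={"I": 1000}, causal_chrom="I", causal_pos=5000
        ).validate()
    with pytest.raises(ValueError, match="error_rate"):
        SimConfig(error_rate=0.5).validate()


def test_config_round_trip_and_unknown_key():
    cfg = SimConfig()
    assert SimConfig.from_dict(cfg.to_dict()) == cfg
    with pytest.raises(ValueError, match="unknown config keys"):
        SimConfig.from_dict({"coverage": 30})


# --- genetic map ------------------------------------------------------------


def test_uniform_map_is_linear():
    cfg = SimConfig(chromosomes={"I": 1_000_000}, causal_chrom="I", causal_pos=1)
    gmap = build_genetic_map(cfg)
    assert gmap["I"].cm_at(500_000) == pytest.approx(25.0)
    assert gmap["I"].bp_at(25.0) == pytest.approx(500_000)
    assert gmap.cm_width("I", 250_000, 750_000) == pytest.approx(25.0)


def test_three_domain_map_concentrates_arms():
    cfg = SimConfig(
        chromosomes={"I": 1_000_000},
        causal_chrom="I",
        causal_pos=1,
        map_style="three_domain",
    )
    gmap = build_genetic_map(cfg)
    arm = gmap.cm_width("I", 0, 250_000)
    center = gmap.cm_width("I", 250_000, 750_000)
    assert arm == pytest.approx(20.0)
    assert center == pytest.approx(10.0)
    assert gmap["I"].total_cm == pytest.approx(50.0)


# --- gamete law -------------------------------------------------------------


def test_gamete_recombinant_fraction_near_half():
    cfg = SimConfig(chromosomes={"I": 1_000_000}, causal_chrom="I", causal_pos=1)
    gmap = build_genetic_map(cfg)
    rng = np.random.default_rng(1234)
    n = 40_000
    recomb = sum(
        bool(simulate_gamete(gmap, "I", rng).breakpoints) for _ in range(n)
    )
    p = recomb / n
    se = (0.25 / n) ** 0.5
    assert abs(p - 0.5) < 4 * se


def test_gamete_marginal_haw_frequency_half_everywhere():
    cfg = SimConfig(chromosomes={"I": 1_000_000}, causal_chrom="I", causal_pos=1)
    gmap = build_genetic_map(cfg)
    rng = np.random.default_rng(5)
    n = 40_000
    positions = np.array([50_000, 500_000, 950_000])
    acc = np.zeros(3)
    for _ in range(n):
        acc += simulate_gamete(gmap, "I", rng).ancestry_at_many(positions)
    se = (0.25 / n) ** 0.5
    assert np.all(np.abs(acc / n - 0.5) < 4 * se)


def test_zero_cm_chromosome_never_recombines():
    cfg = SimConfig(
        chromosomes={"I": 1_000_000}, causal_chrom="I", causal_pos=1, total_cm=0.0
    )
    gmap = build_genetic_map(cfg)
    rng = np.random.default_rng(0)
    for _ in range(200):
        gam = simulate_gamete(gmap, "I", rng)
        assert gam.breakpoints == ()


def test_conditional_haw_frequency_matches_enumeration_oracle():
    """Gametes conditioned on N2 at the causal locus deplete HAW linearly
    with genetic distance; compare against the independent oracle."""
    length = 20_000_000
    cfg = SimConfig(chromosomes={"V": length}, causal_chrom="V", causal_pos=1)
    gmap = build_genetic_map(cfg)
    rng = np.random.default_rng(77)
    g0_cm = 20.0
    g0_bp = int(gmap["V"].bp_at(g0_cm))
    dists = [2.0, 5.0, 10.0, 15.0, 25.0]
    marker_bp = np.array([int(gmap["V"].bp_at(g0_cm + d)) for d in dists])
    n_kept = 0
    haw_hits = np.zeros(len(dists))
    while n_kept < 30_000:
        gam = simulate_gamete(gmap, "V", rng)
        if gam.ancestry_at(g0_bp) != N2:
            continue
        n_kept += 1
        haw_hits += gam.ancestry_at_many(marker_bp)
    emp = haw_hits / n_kept
    rng_o = np.random.default_rng(78)
    for d, e in zip(dists, emp):
        exact = enumerate_haw_freq(d, g0_cm, 50.0)
        mc = mc_haw_freq(rng_o, d, g0_cm, 50.0, 30_000)
        se = (exact * (1 - exact) / n_kept) ** 0.5
        assert abs(e - exact) < 3 * se
        assert abs(mc - exact) < 3 * se  # oracle self-consistency


# --- reference model --------------------------------------------------------


def test_reference_model_deterministic(tiny_config):
    m1 = build_reference_model(tiny_config, seed=3)
    m2 = build_reference_model(tiny_config, seed=3)
    assert m1.hawaiian.entries == m2.hawaiian.entries
    assert m1.parental.entries == m2.parental.entries
    assert [(x.chrom, x.pos, x.ref, x.alt) for x in m1.induced] == [
        (x.chrom, x.pos, x.ref, x.alt) for x in m2.induced
    ]
    assert (m1.causal.chrom, m1.causal.pos) == (m2.causal.chrom, m2.causal.pos)


def test_catalog_density_poisson(tiny_config):
    model = build_reference_model(tiny_config, seed=4)
    expected = 1e-3 * sum(tiny_config.chromosomes.values())
    assert abs(len(model.hawaiian) - expected) < 4 * expected**0.5


def test_catalog_refs_match_genome(tiny_config):
    model = build_reference_model(tiny_config, seed=4)
    for chrom, pos, ref, alt in list(sorted(model.hawaiian.entries))[:200]:
        assert model.genome.base(chrom, pos) == ref
        assert alt != ref


def test_ems_spectrum(tiny_config):
    model = build_reference_model(tiny_config, seed=5)
    assert all((m.ref, m.alt) in {("G", "A"), ("C", "T")} for m in model.induced)


def test_causal_lesion_is_nonsynonymous_in_spanning_gene(tiny_config):
    model = build_reference_model(tiny_config, seed=6)
    causal = model.causal
    gene = next(
        g
        for g in model.gene_models
        if g.chrom == causal.chrom and g.span[0] <= causal.pos <= g.span[1]
    )
    cds = cds_sequence(gene, model.genome)
    # locate the causal base in the CDS and check the protein changes
    idx = 0
    hit = None
    for s, e in gene.cds:
        for k in range(e - s + 1):
            gpos = (s + k) if gene.strand == "+" else (e - k)
            if gpos == causal.pos:
                hit = idx + k
        idx += e - s + 1
    assert hit is not None
    alt_coding = causal.alt if gene.strand == "+" else {"A": "T", "T": "A", "G": "C", "C": "G"}[causal.alt]
    mutated = cds[:hit] + alt_coding + cds[hit + 1 :]
    assert oracle_translate(mutated) != oracle_translate(cds)
    assert model.genome.base(causal.chrom, causal.pos) == causal.ref


def test_parental_and_hawaiian_positions_disjoint(tiny_config):
    model = build_reference_model(tiny_config, seed=7)
    hawpos = {(c, p) for c, p, _r, _a in model.hawaiian.entries}
    parpos = {(c, p) for c, p, _r, _a in model.parental.entries}
    assert not hawpos & parpos


# --- the pool ---------------------------------------------------------------


def test_pool_lines_all_n2_at_causal(tiny_sim):
    pool = tiny_sim.pool
    for line in pool.lines:
        g1, g2 = line[pool.causal_chrom]
        assert g1.ancestry_at(pool.causal_pos) == N2
        assert g2.ancestry_at(pool.causal_pos) == N2
    assert pool.hawaiian_frequency(pool.causal_chrom, pool.causal_pos)[0] == 0.0


def test_pool_size_within_configured_range(tiny_sim):
    cfg = tiny_sim.model.config
    lo, hi = cfg.n_pooled_range
    assert lo <= tiny_sim.pool.n_pooled <= hi
    assert tiny_sim.pool.n_mutant_found >= tiny_sim.pool.n_pooled


def test_mutant_fraction_near_one_quarter(tiny_config):
    model = build_reference_model(tiny_config, seed=8)
    found = screened = 0
    for seed in range(12):
        pool = simulate_mutant_pool(model, seed=seed)
        found += pool.n_mutant_found
        screened += pool.n_f2_screened
    p = found / screened
    se = (0.25 * 0.75 / screened) ** 0.5
    assert abs(p - 0.25) < 4 * se


def test_explicit_pool_shortfall_raises(tiny_config):
    model = build_reference_model(tiny_config, seed=9)
    with pytest.raises(ValueError, match="increase n_f2"):
        simulate_mutant_pool(model, n_f2=20, n_pooled=15, seed=0)


def test_unlinked_chromosome_frequency_near_half(tiny_sim):
    pool = tiny_sim.pool
    positions = np.linspace(1, 799_999, 200).astype(np.int64)
    freq = pool.hawaiian_frequency("II", positions)
    # 2n conditioned-on-nothing gametes; average over markers ~ 0.5
    n_gam = 2 * pool.n_pooled
    se = (0.25 / n_gam) ** 0.5  # per-marker; markers correlated, be loose
    assert abs(float(freq.mean()) - 0.5) < 3 * se


# --- pooled sequencing -------------------------------------------------------


def test_pool_vcf_deterministic_bytes(tiny_sim, tmp_path):
    model, pool = tiny_sim.model, tiny_sim.pool
    c1 = simulate_pool_vcf(pool, model, seed=42)
    c2 = simulate_pool_vcf(pool, model, seed=42)
    p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
    write_pool_vcf(c1, model.config, p1)
    write_pool_vcf(c2, model.config, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_causal_site_fixed_at_error_zero(tiny_sim):
    model, pool = tiny_sim.model, tiny_sim.pool
    calls = simulate_pool_vcf(pool, model, error_rate=0.0, seed=1)
    causal = model.causal
    call = next(
        c for c in calls if c.chrom == causal.chrom and c.pos == causal.pos
    )
    assert call.alt_fraction == 1.0
    assert call.ref_depth == 0


def test_hawaiian_site_at_causal_locus_absent_at_error_zero(tiny_sim):
    """Catalog sites inside the zero-HAW region draw no alt reads at e=0."""
    model, pool = tiny_sim.model, tiny_sim.pool
    calls = simulate_pool_vcf(
        pool, model, error_rate=0.0, seed=2, emit_zero_alt=True
    )
    haw_keys = model.hawaiian.key_set
    for c in calls:
        if (c.chrom, c.pos, c.alt) not in haw_keys:
            continue
        true_freq = pool.hawaiian_frequency(c.chrom, np.array([c.pos]))[0]
        if true_freq == 0.0:
            assert c.alt_depth == 0


def test_mean_depth_respected(tiny_sim):
    model, pool = tiny_sim.model, tiny_sim.pool
    calls = simulate_pool_vcf(pool, model, mean_depth=40.0, seed=3, emit_zero_alt=True)
    depths = np.array([c.total_depth for c in calls])
    se = (40.0 / len(depths)) ** 0.5
    assert abs(depths.mean() - 40.0) < 4 * se


def test_unlinked_alt_fraction_near_half(tiny_sim):
    model, pool = tiny_sim.model, tiny_sim.pool
    calls = simulate_pool_vcf(pool, model, error_rate=0.0, seed=4)
    haw_keys = model.hawaiian.key_set
    fracs = [
        c.alt_fraction
        for c in calls
        if c.chrom == "II" and (c.chrom, c.pos, c.alt) in haw_keys
    ]
    assert len(fracs) > 300
    assert abs(float(np.mean(fracs)) - 0.5) < 0.05
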