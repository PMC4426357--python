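"""candidate_annotation: codon effects, descriptors, consistency, filtering."""

from __future__ import annotations

import numpy as np
import pytest

from hawmap import (
    EffectClass,
    GeneModel,
    MappingInterval,
    VariantCall,
    annotate_effect,
    check_substitution_consistency,
    classify_descriptor,
    ems_flag,
    filter_candidates,
    truncation_length,
)
from hawmap.candidate_annotation import (
    NONSYNONYMOUS,
    parse_descriptor,
    translate_codon,
)
from hawmap.fixtures import load_variant_tables
from hawmap.formats_io import cds_sequence

from oracles import (
    oracle_single_substitution_possible,
    oracle_snv_effect,
    oracle_translate,
)

# toy chromosome: three hand-built genes with known codons
#   gp (+): CDS 11-31   ATG GGA CAA GGA TGG TTT TAA  (M G Q G W F *)
#   gm (-): CDS 41-52, coding ATG TGT CCC TAA         (M C P *)
#   gs (+): exons 61-69 / 76-84 with GT..AG intron 70-75
_CHR = (
    "AAAAAAAAAA"
    "ATGGGACAAGGATGGTTTTAA"
    "CCCCCCCCC"
    "TTAGGGACACAT"
    "GGGGGGGG"
    "ATGAAACCC"
    "GTAAAG"
    "GGGTTTTAA"
    "TTTTTTTTTTTTTTTT"
)

GP = GeneModel("gp", "chrI", "+", ((11, 31),))
GM = GeneModel("gm", "chrI", "-", ((41, 52),))
GS = GeneModel("gs", "chrI", "+", ((61, 69), (76, 84)))
MODELS = [GP, GM, GS]


@pytest.fixture
def toy_genome(dict_genome_factory):
    return dict_genome_factory({"chrI": _CHR})


def _v(pos, ref, alt, label="novel", rd=1, ad=29):
    return VariantCall("chrI", pos, ref, alt, ref_depth=rd, alt_depth=ad, label=label)


def test_toy_genes_translate_as_designed(toy_genome):
    assert oracle_translate(cds_sequence(GP, toy_genome)) == "MGQGWF*"
    assert oracle_translate(cds_sequence(GM, toy_genome)) == "MCP*"
    assert oracle_translate(cds_sequence(GS, toy_genome)) == "MKPGF*"


@pytest.mark.parametrize(
    "pos,ref,alt,effect,aa_change",
    [
        (14, "G", "A", EffectClass.MISSENSE, "Gly2Arg"),
        (17, "C", "T", EffectClass.NONSENSE, "Gln3stop"),
        (16, "A", "G", EffectClass.SYNONYMOUS, "Gly2Gly"),
        (11, "A", "G", EffectClass.START_LOSS, "Met1Val"),
        (31, "A", "C", EffectClass.STOP_LOSS, "stop7Tyr"),
    ],
)
def test_plus_strand_snv_effects(toy_genome, pos, ref, alt, effect, aa_change):
    ann = annotate_effect(_v(pos, ref, alt), MODELS, toy_genome)
    assert ann.effect is effect
    assert ann.gene_id == "gp"
    assert ann.aa_change == aa_change


def test_minus_strand_missense(toy_genome):
    # coding TGT(Cys2) first base <-> genome pos 49, plus-strand 'A'
    ann = annotate_effect(_v(49, "A", "C"), MODELS, toy_genome)
    assert ann.effect is EffectClass.MISSENSE
    assert ann.gene_id == "gm"
    assert (ann.aa_from, ann.aa_to, ann.aa_pos) == ("C", "G", 2)


def test_frameshift_and_inframe_indel(toy_genome):
    fs = annotate_effect(_v(20, "G", "GT"), MODELS, toy_genome)
    assert fs.effect is EffectClass.FRAMESHIFT
    inframe = annotate_effect(_v(20, "G", "GTTT"), MODELS, toy_genome)
    assert inframe.effect is EffectClass.MISSENSE  # in-frame, coding


@pytest.mark.parametrize(
    "pos,ref,alt,effect",
    [
        (70, "G", "A", EffectClass.SPLICE),
        (71, "T", "C", EffectClass.SPLICE),
        (72, "A", "G", EffectClass.NONCODING),
        (75, "G", "C", EffectClass.SPLICE),
        (5, "A", "G", EffectClass.NONCODING),
    ],
)
def test_splice_window_and_noncoding(toy_genome, pos, ref, alt, effect):
    assert annotate_effect(_v(pos, ref, alt), MODELS, toy_genome).effect is effect


def test_ref_mismatch_raises(toy_genome):
    with pytest.raises(ValueError, match="inconsistent with reference"):
        annotate_effect(_v(14, "C", "A"), MODELS, toy_genome)


def test_annotation_agrees_with_full_translation_oracle(tiny_sim):
    """Random CDS SNVs in simulated genes: the codon-local annotator must
    match an oracle that translates the entire protein before/after."""
    model = tiny_sim.model
    rng = np.random.default_rng(123)
    checked = 0
    for gene in model.gene_models[:6]:
        cds = cds_sequence(gene, model.genome)
        # genome position of every CDS index, in translation order
        gpos = []
        for s, e in gene.cds:
            rng_seg = range(s, e + 1) if gene.strand == "+" else range(e, s - 1, -1)
            gpos.extend(rng_seg)
        for _ in range(40):
            idx = int(rng.integers(0, len(cds)))
            new_coding = "ACGT"[int(rng.integers(0, 4))]
            if new_coding == cds[idx]:
                continue
            if gene.strand == "+":
                ref, alt = cds[idx], new_coding
            else:
                comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
                ref, alt = comp[cds[idx]], comp[new_coding]
            call = VariantCall(
                gene.chrom, gpos[idx], ref, alt, 1, 29, "novel"
            )
            ann = annotate_effect(call, [gene], model.genome)
            assert ann.effect.value == oracle_snv_effect(cds, idx, new_coding)
            checked += 1
    assert checked > 150


# --- candidate filter -------------------------------------------------------


def test_filter_candidates_boundaries_and_labels(toy_genome):
    iv = MappingInterval(chrom="chrI", start=11, end=31)
    calls = [
        _v(14, "G", "A"),  # in, novel, hom, missense -> kept
        _v(16, "A", "G"),  # synonymous -> dropped
        _v(17, "C", "T", label="hawaiian"),  # not novel -> dropped
        _v(32, "C", "T"),  # outside interval -> dropped
        _v(20, "G", "A", rd=5, ad=25),  # 25/30 = 0.83 not hom -> dropped
    ]
    cands = filter_candidates(calls, iv, MODELS, toy_genome)
    assert [(c.pos, c.annotation.effect) for c in cands] == [
        (14, EffectClass.MISSENSE)
    ]
    assert cands[0].ems_transition is True


def test_filter_candidates_threshold_is_strict(toy_genome):
    iv = MappingInterval(chrom="chrI", start=11, end=31)
    exactly_085 = _v(14, "G", "A", rd=3, ad=17)  # 17/20 = 0.85
    assert filter_candidates([exactly_085], iv, MODELS, toy_genome) == []


def test_filter_candidates_subset_of_novel_calls(tiny_sim):
    from hawmap.pipeline import run_mapping

    res = run_mapping(tiny_sim)
    for c in res.candidates:
        assert c.call.label == "novel"
        assert c.call.alt_fraction > 0.85
        assert res.selected.contains(c.chrom, c.pos)
        assert c.annotation.effect in NONSYNONYMOUS


def test_ems_flag():
    assert ems_flag("G", "A") and ems_flag("C", "T")
    assert not ems_flag("A", "G") and not ems_flag("G", "T")


# --- descriptors ------------------------------------------------------------


def test_parse_descriptor_styles():
    d = parse_descriptor("G->A, Gly42Arg")
    assert d.effect is EffectClass.MISSENSE
    assert (d.nt_from, d.nt_to, d.aa_from, d.aa_pos, d.aa_to) == (
        "G", "A", "Gly", 42, "Arg",
    )
    assert classify_descriptor("C->T, Trp1062stop") is EffectClass.NONSENSE
    assert (
        classify_descriptor("insertion of 1 bp, frameshift")
        is EffectClass.FRAMESHIFT
    )
    with pytest.raises(ValueError, match="unrecognised"):
        parse_descriptor("banana")
    with pytest.raises(ValueError, match="unknown amino-acid"):
        parse_descriptor("G->A, Xyz42Arg")


def test_consistency_plus_strand_witness():
    ok, wits = check_substitution_consistency("Gly", "Arg", "G", "A")
    assert ok
    assert ("GGA", "AGA", "+") in wits


def test_consistency_minus_strand_only():
    # Ala->Thr by a printed C->T works only via the complement G->A
    ok, wits = check_substitution_consistency("Ala", "Thr", "C", "T")
    assert ok
    assert all(strand == "-" for _f, _t, strand in wits)


def test_consistency_impossible_change():
    # Met (ATG) -> Trp (TGG) cannot arise from any single G->A (or C->T)
    ok, wits = check_substitution_consistency("Met", "Trp", "G", "A")
    assert not ok and wits == []


def test_consistency_matches_brute_force_oracle():
    import itertools

    aas = ["Gly", "Ala", "Trp", "Gln", "Arg", "Ser", "stop"]
    one = {"Gly": "G", "Ala": "A", "Trp": "W", "Gln": "Q", "Arg": "R",
           "Ser": "S", "stop": "*"}
    for a_from, a_to in itertools.product(aas, repeat=2):
        for nt_from, nt_to in [("G", "A"), ("C", "T"), ("A", "C")]:
            ok, _ = check_substitution_consistency(a_from, a_to, nt_from, nt_to)
            assert ok == oracle_single_substitution_possible(
                one[a_from], one[a_to], nt_from, nt_to
            ), (a_from, a_to, nt_from, nt_to)


def test_truncation_length_bounds():
    assert truncation_length(1227, 1062) == 165
    assert truncation_length(367, 52) == 315
    assert truncation_length(100, 100) == 0
    with pytest.raises(ValueError):
        truncation_length(100, 101)
    with pytest.raises(ValueError):
        truncation_length(100, 0)


def test_translate_codon_stops_and_sense():
    for stop in ("TAA", "TAG", "TGA"):
        assert translate_codon(stop) == "*"
    assert translate_codon("ATG") == "M"
    assert translate_codon("tgg") == "W"


# --- the packaged legacy tables ---------------------------------------------


def test_variant_table_fixture_parses_and_is_consistent():
    df = load_variant_tables()
    assert len(df) == 38
    n_checked = 0
    for row in df.itertuples():
        parsed = parse_descriptor(row.mutation)
        if parsed.effect is EffectClass.FRAMESHIFT:
            continue
        ok, wits = check_substitution_consistency(
            parsed.aa_from, parsed.aa_to, parsed.nt_from, parsed.nt_to
        )
        assert ok, f"{row.strain} {row.gene}: {row.mutation}"
        assert wits
        n_checked += 1
    assert n_checked == 37  # one frameshift row (mel-2 / F41G3.20)


def test_variant_table_causal_rows_are_ems():
    df = load_variant_tables()
    causal = df[df.causal == 1]
    assert len(causal) == 7  # one per strain
    for row in causal.itertuples():
        d = parse_descriptor(row.mutation)
        assert ems_flag(d.nt_from, d.nt_to)
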