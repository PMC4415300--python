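import numpy as np
import pytest

from taarminer.gene_models import (
    GeneModel,
    JunctionDipeptide,
    ModelConfig,
    adjacency_report,
    build_single_exon_model,
    detect_disruptions,
    infer_spliced_model,
    junction_census,
    name_gene,
    reconstruct_locus,
)
from taarminer.seq_core import Contig, GenomicInterval, ProteinSeq, translate
from taarminer.synthetic_repertoire import make_intron, receptor_cds
from taarminer.translated_search import (
    SearchConfig,
    bait_filter,
    merge_hits,
    search_contig,
)
from taarminer.translated_search import Bait

CFG = SearchConfig()


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _plant(rng, unit, pad_left=2000, pad_right=2000, species="Til"):
    seq = _random_dna(rng, pad_left) + unit + _random_dna(rng, pad_right)
    return Contig(id="ctg", species=species, seq=seq), pad_left


def _bait_for(cds, rng):
    """A bait ~75% identical to the planted gene."""
    from taarminer.synthetic_repertoire import evolve_to_identity

    bait_cds = evolve_to_identity(cds, 75.0, 1.0, 1.0, rng)
    return Bait("bait", "positive", ProteinSeq("bait", translate(bait_cds)))


def _locus_for(contig, bait):
    hits = search_contig([bait], contig, CFG)
    retained, _ = bait_filter(merge_hits(hits, CFG.merge_gap), CFG)
    assert len(retained) == 1
    return retained[0]


@pytest.fixture(scope="module")
def planted_single_exon():
    rng = np.random.default_rng(5)
    cds = receptor_cds(rng, 320)
    unit = "TAA" + cds + "TGA"
    contig, off = _plant(rng, unit)
    bait = _bait_for(cds, rng)
    return contig, bait, (off + 3, off + 3 + len(cds) + 3), cds


@pytest.fixture(scope="module")
def planted_two_exon():
    rng = np.random.default_rng(6)
    cds = receptor_cds(rng, 320)
    k = 55
    # junction Phe|Arg
    cds = cds[: 3 * (k - 1)] + "TTTCGT" + cds[3 * (k + 1):]
    intron = make_intron(rng, 400, 0.42)
    unit = "TAA" + cds[: 3 * k] + intron + cds[3 * k :] + "TAA"
    contig, off = _plant(rng, unit)
    bait = _bait_for(cds, rng)
    exon1 = (off + 3, off + 3 + 3 * k)
    exon2 = (exon1[1] + len(intron), off + 3 + len(cds) + len(intron) + 3)
    return contig, bait, exon1, exon2, k, intron


def test_single_exon_model_exact(planted_single_exon):
    contig, bait, (start, end), cds = planted_single_exon
    locus = _locus_for(contig, bait)
    model = build_single_exon_model(locus, contig)
    assert model is not None and model.status == "complete_1exon"
    assert (model.exons[0].start, model.exons[0].end) == (start, end)
    assert model.protein == translate(cds)


def test_single_exon_below_window_returns_none(planted_single_exon):
    contig, bait, _, _ = planted_single_exon
    locus = _locus_for(contig, bait)
    tight = ModelConfig(min_codons=350, max_codons=400)
    assert build_single_exon_model(locus, contig, tight) is None


def test_spliced_model_exact(planted_two_exon):
    contig, bait, exon1, exon2, k, _ = planted_two_exon
    locus = _locus_for(contig, bait)
    model = infer_spliced_model(locus, bait.protein, contig)
    assert model is not None
    assert model.intron_codon_index == k
    assert str(model.junction) == "FR"
    spans = sorted((e.start, e.end) for e in model.exons)
    assert spans == sorted([exon1, exon2])
    # phase 0: exon 1 length is a whole number of codons
    assert (spans[0][1] - spans[0][0]) % 3 == 0


def test_spliced_model_requires_canonical_donor(planted_two_exon):
    contig, bait, exon1, _, _, _ = planted_two_exon
    # mutate the donor GT -> GC
    seq = list(contig.seq)
    assert seq[exon1[1]] == "G" and seq[exon1[1] + 1] == "T"
    seq[exon1[1] + 1] = "C"
    mutated = Contig(id="ctg", species="Til", seq="".join(seq))
    locus = _locus_for(mutated, bait)
    model = infer_spliced_model(locus, bait.protein, mutated)
    if model is not None:  # any surviving model must use a different donor
        assert model.exons[0].end != exon1[1]


def test_detect_frameshift_position():
    rng = np.random.default_rng(8)
    cds = receptor_cds(rng, 320) + "TAA"
    broken = cds[: 3 * 100] + "G" + cds[3 * 100 :]  # +1 nt at codon 100
    contig, _ = _plant(rng, "TAA" + broken)
    bait = _bait_for(cds[:-3], rng)
    locus = _locus_for(contig, bait)
    disruptions, chain, extent = detect_disruptions(locus, bait.protein, contig)
    kinds = {d.kind for d in disruptions}
    assert "frameshift" in kinds
    fs = [d for d in disruptions if d.kind == "frameshift"]
    assert any(abs(d.position - 100) <= 15 for d in fs)


def test_detect_in_frame_stop_position():
    rng = np.random.default_rng(9)
    cds = receptor_cds(rng, 320) + "TAA"
    broken = cds[: 3 * 150] + "TGA" + cds[3 * 151 :]
    contig, _ = _plant(rng, "TAA" + broken)
    bait = _bait_for(cds[:-3], rng)
    locus = _locus_for(contig, bait)
    disruptions, _, _ = detect_disruptions(locus, bait.protein, contig)
    stops = [d for d in disruptions if d.kind == "in_frame_stop"]
    assert stops and any(abs(d.position - 151) <= 2 for d in stops)


def test_intact_gene_has_no_disruptions(planted_single_exon):
    contig, bait, _, _ = planted_single_exon
    locus = _locus_for(contig, bait)
    disruptions, _, _ = detect_disruptions(locus, bait.protein, contig)
    assert disruptions == []


def test_reconstruct_classifies_pseudogene():
    rng = np.random.default_rng(10)
    cds = receptor_cds(rng, 320) + "TAA"
    broken = cds[: 3 * 120] + cds[3 * 120 + 2 :]  # 2-nt deletion
    contig, _ = _plant(rng, "TAA" + broken)
    bait = _bait_for(cds[:-3], rng)
    locus = _locus_for(contig, bait)
    model = reconstruct_locus(locus, {"bait": bait.protein}, contig)
    assert model.status == "pseudogene"
    assert model.pseudo_type == "frameshift"


def test_reconstruct_classifies_edge_and_fragment():
    rng = np.random.default_rng(12)
    cds = receptor_cds(rng, 320) + "TAA"
    bait = _bait_for(cds[:-3], rng)
    # edge: C-terminal 60% of the CDS abutting contig start
    piece = cds[int(len(cds) * 0.4) // 3 * 3 :]
    edge_contig = Contig(id="ctg", species="Til",
                         seq=piece + _random_dna(rng, 3000))
    locus = _locus_for(edge_contig, bait)
    model = reconstruct_locus(locus, {"bait": bait.protein}, edge_contig)
    assert model.status == "edge"
    # fragment: interior 55% of the CDS, well inside the contig
    n = len(cds) // 3
    frag = cds[3 * 40 : 3 * (40 + int(0.55 * n))]
    frag_contig, _ = _plant(rng, frag)
    locus = _locus_for(frag_contig, bait)
    model = reconstruct_locus(locus, {"bait": bait.protein}, frag_contig)
    assert model.status == "fragment"


@pytest.mark.parametrize("args,expected", [
    (("Bri", "edge", "A", 5), "BriTARe.A005"),
    (("Til", "pseudogene", "A", 22), "TilTARp.A022"),
    (("Bur", "complete_2exon", "A", 16), "BurTARs.A016"),
    (("Til", "complete_1exon", "B", 4), "TilTAR.B004"),
    (("Nye", "fragment", "U", 999), "NyeTARf.U999"),
])
def test_name_gene(args, expected):
    assert name_gene(*args) == expected


def test_name_gene_rejects_bad_index():
    with pytest.raises(ValueError):
        name_gene("Til", "edge", "A", 0)
    with pytest.raises(ValueError):
        name_gene("Til", "edge", "A", 1000)


def _model(species="Til", status="complete_2exon", junction=("F", "R"),
           start=0, end=900, strand="+", contig="c1", name=""):
    return GeneModel(
        species=species,
        exons=[GenomicInterval(contig, start, end, strand)],
        strand=strand, cds="", protein="", status=status,
        junction=JunctionDipeptide(*junction) if junction else None,
        name=name,
    )


def test_junction_census_counts_and_fraction():
    models = [_model(junction=("F", "R")), _model(junction=("F", "R")),
              _model(junction=("F", "K")),
              _model(status="complete_1exon", junction=None)]
    pooled, per_species, frac = junction_census(models)
    assert pooled == {"FR": 2, "FK": 1}
    assert frac == 1.0
    assert junction_census([]) == ({}, {}, pytest.approx(float("nan"), nan_ok=True))


def test_adjacency_orientations():
    a = _model(start=0, end=1000, strand="+", name="g1")
    b = _model(start=2500, end=3500, strand="+", name="g2")
    rows = adjacency_report([a, b])
    assert rows[0]["orientation"] == "tail-to-head"
    assert rows[0]["distance_nt"] == 1500
    b2 = _model(start=2500, end=3500, strand="-", name="g2")
    assert adjacency_report([a, b2])[0]["orientation"] == "tail-to-tail"
    a2 = _model(start=0, end=1000, strand="-", name="g1")
    b3 = _model(start=2500, end=3500, strand="+", name="g2")
    assert adjacency_report([a2, b3])[0]["orientation"] == "head-to-head"
    assert adjacency_report([a]) == []
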