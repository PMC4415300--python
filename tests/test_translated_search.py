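import math

import numpy as np
import pytest

from taarminer.seq_core import Contig, ProteinSeq, reverse_complement
from taarminer.translated_search import (
    AlignmentHit,
    Bait,
    Locus,
    SearchConfig,
    bait_filter,
    evalue,
    local_align,
    merge_hits,
    search_contig,
)
from taarminer.seq_core import GenomicInterval

from .oracles import sw_score_oracle

CFG = SearchConfig()
AA = "ACDEFGHIKLMNPQRSTVWY"


def test_local_align_identity_score():
    # BLOSUM62 diagonal: M=5, F=6, R=5, W=11
    score, (q, t) = local_align(ProteinSeq("q", "MFRW"), ProteinSeq("t", "MFRW"))
    assert score == 27
    assert (q, t) == ("MFRW", "MFRW")


def test_local_align_empty_target():
    score, aln = local_align(ProteinSeq("q", "MFRW"), ProteinSeq("t", ""))
    assert score == 0 and aln == ("", "")


def test_local_align_matches_exhaustive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(40):
        a = "".join(rng.choice(list(AA), size=rng.integers(1, 9)))
        b = "".join(rng.choice(list(AA), size=rng.integers(1, 9)))
        score, _ = local_align(ProteinSeq("a", a), ProteinSeq("b", b))
        assert score == sw_score_oracle(a, b), (a, b)


def test_local_align_symmetric():
    rng = np.random.default_rng(7)
    for _ in range(25):
        a = "".join(rng.choice(list(AA), size=8))
        b = "".join(rng.choice(list(AA), size=8))
        sa, _ = local_align(ProteinSeq("a", a), ProteinSeq("b", b))
        sb, _ = local_align(ProteinSeq("b", b), ProteinSeq("a", a))
        assert sa == sb


def test_evalue_formula_and_monotonicity():
    expected = 0.041 * 350 * 10000 * math.exp(-0.267 * 100)
    assert evalue(100, 350, 10000, CFG) == pytest.approx(expected, rel=1e-12)
    assert evalue(100, 350, 20000, CFG) == pytest.approx(2 * expected, rel=1e-12)
    assert evalue(110, 350, 10000, CFG) < evalue(100, 350, 10000, CFG)
    with pytest.raises(ValueError):
        evalue(100, 0, 10000, CFG)


def _hit(start, end, strand="+", role="positive", ev=1e-60, contig="c"):
    return AlignmentHit(
        bait_id="b", role=role,
        interval=GenomicInterval(contig, start, end, strand),
        frame=1, raw_score=500, bitscore=190, evalue=ev,
        protein_alignment=("", ""),
    )


def test_merge_hits_gap_and_strand_rules():
    h1, h2 = _hit(0, 300), _hit(400, 700)  # 100 nt apart
    assert len(merge_hits([h1, h2], 2000)) == 1
    h3 = _hit(0, 300, strand="-")
    assert len(merge_hits([h1, h3], 2000)) == 2
    h4 = _hit(5300, 5600)  # 5,000 nt downstream of h1's end
    assert len(merge_hits([h1, h4], 2000)) == 2


def test_bait_filter_criteria():
    def locus(pos_e, neg_e):
        hits = [_hit(0, 300, ev=pos_e)]
        if neg_e is not None:
            hits.append(_hit(0, 300, role="negative", ev=neg_e))
        return merge_hits(hits, 2000)[0]

    retained, rejected = bait_filter(
        [locus(1e-60, None), locus(1e-60, 1e-55), locus(1e-40, None)], CFG
    )
    assert len(retained) == 1
    assert retained[0].best_positive.evalue == 1e-60
    reasons = sorted(r for _, r in rejected)
    assert reasons == ["negative_bait_match", "no_positive_match"]


def test_bait_filter_order_independent():
    rng = np.random.default_rng(0)
    hits = [_hit(s, s + 300, ev=1e-60) for s in range(0, 30000, 3000)]
    base = {l.interval.start for l in bait_filter(merge_hits(hits, 2000), CFG)[0]}
    for _ in range(10):
        shuffled = list(rng.permutation(len(hits)))
        loci = merge_hits([hits[i] for i in shuffled], 2000)
        assert {l.interval.start for l in bait_filter(loci, CFG)[0]} == base


def test_plant_and_recover_hit(tiny_repertoire):
    """Every planted complete gene yields a retained locus covering its CDS."""
    rep = tiny_repertoire
    baits = rep.positive_baits + rep.negative_baits
    truth = rep.truth[rep.truth.status.str.startswith("complete")]
    contigs = {c.id: c for c in rep.all_contigs()}
    from taarminer.gene_models import split_into_gene_groups

    for row in truth.itertuples():
        spans = [tuple(map(int, p.split("-"))) for p in row.exons.split(";")]
        contig = contigs[row.contig]
        hits = search_contig(baits, contig, CFG)
        loci = merge_hits(hits, CFG.merge_gap)
        groups = [g for l in loci for g in split_into_gene_groups(l)]
        retained, _ = bait_filter(groups, CFG)
        covering = [
            l for l in retained
            if l.interval.strand == row.strand
            and l.interval.start < spans[-1][1] and l.interval.end > spans[0][0]
        ]
        assert covering, f"no locus for {row.gene}"


def test_decoys_rejected(tiny_repertoire):
    rep = tiny_repertoire
    baits = rep.positive_baits + rep.negative_baits
    decoys = rep.truth[rep.truth.status == "decoy"]
    contigs = {c.id: c for c in rep.all_contigs()}
    for row in decoys.itertuples():
        contig = contigs[row.contig]
        hits = search_contig(baits, contig, CFG)
        retained, _ = bait_filter(merge_hits(hits, CFG.merge_gap), CFG)
        spans = [tuple(map(int, p.split("-"))) for p in row.exons.split(";")]
        overlapping = [
            l for l in retained
            if l.interval.start < spans[-1][1] and l.interval.end > spans[0][0]
            and l.interval.strand == row.strand
        ]
        assert not overlapping, f"decoy {row.gene} survived the bait filter"


def test_random_contig_yields_no_hits():
    rng = np.random.default_rng(3)
    bait = Bait("b", "positive",
                ProteinSeq("b", "".join(rng.choice(list(AA), size=330))))
    for seed in range(5):
        r = np.random.default_rng(seed)
        contig = Contig(id=f"r{seed}", species="X",
                        seq="".join(r.choice(list("ACGT"), size=10000)))
        assert search_contig([bait], contig, CFG) == []


def test_minus_strand_hit_coordinates(tiny_repertoire):
    """A planted gene on the minus strand reports forward coordinates."""
    rep = tiny_repertoire
    baits = rep.positive_baits + rep.negative_baits
    contigs = {c.id: c for c in rep.all_contigs()}
    minus = rep.truth[(rep.truth.strand == "-")
                      & rep.truth.status.str.startswith("complete")]
    row = minus.iloc[0]
    contig = contigs[row.contig]
    hits = [h for h in search_contig(baits, contig, CFG)
            if h.interval.strand == "-"]
    assert hits
    assert all(0 <= h.interval.start < h.interval.end <= len(contig)
               for h in hits)
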