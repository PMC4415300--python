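import numpy as np
import pandas as pd
import pytest

from taarminer.evolution_dnds import ng86_pair
from taarminer.repertoire_classify import pairwise_identity
from taarminer.seq_core import reverse_complement, translate
from taarminer.synthetic_repertoire import (
    evolve_to_identity,
    generate,
    make_intron,
    pseudogenize,
    receptor_cds,
    truncate_to_edge,
)

from .conftest import TINY_CONFIG


def _extract(contigs, row):
    contig = next(c for group in contigs.values() for c in group
                  if c.id == row.contig)
    spans = sorted(tuple(map(int, p.split("-"))) for p in row.exons.split(";"))
    if row.strand == "+":
        return "".join(contig.seq[s:e] for s, e in spans)
    return "".join(reverse_complement(contig.seq[s:e])
                   for s, e in spans[::-1])


def test_generation_is_deterministic(tiny_repertoire):
    again = generate(TINY_CONFIG)
    assert tiny_repertoire.truth.equals(again.truth)
    for sp in tiny_repertoire.contigs:
        assert [c.seq for c in tiny_repertoire.contigs[sp]] == \
            [c.seq for c in again.contigs[sp]]
    assert [b.protein.seq for b in tiny_repertoire.positive_baits] == \
        [b.protein.seq for b in again.positive_baits]


def test_planted_counts_match_plan(tiny_repertoire):
    truth = tiny_repertoire.truth
    one, two = TINY_CONFIG.complete_counts()
    for sp in TINY_CONFIG.species:
        sub = truth[truth.species == sp]
        counts = sub.status.value_counts().to_dict()
        assert counts["complete_1exon"] == one
        assert counts["complete_2exon"] == two
        assert counts["pseudogene"] == (TINY_CONFIG.n_pseudogene_frameshift
                                        + TINY_CONFIG.n_pseudogene_stop)
        assert counts["edge"] == TINY_CONFIG.n_edge
        assert counts["fragment"] == TINY_CONFIG.n_fragment
        assert counts["decoy"] == TINY_CONFIG.n_decoy


def test_truth_fasta_consistency(tiny_repertoire):
    """Re-extracting each truth interval reproduces the stored sequence:
    complete genes translate cleanly, pseudogenes carry a disruption."""
    truth = tiny_repertoire.truth
    for row in truth.itertuples():
        extracted = _extract(tiny_repertoire.contigs, row)
        if row.status.startswith("complete"):
            prot = translate(extracted)
            assert prot[-1] == "*" and "*" not in prot[:-1]
            assert prot[:-1] == row.protein
        elif row.status == "pseudogene":
            assert extracted == row.cds
            if row.pseudo_type == "in_frame_stop":
                assert "*" in translate(extracted)[:-1]
            else:  # frameshift changed the length by 1-2 nt
                assert len(extracted) % 3 != 0 or "*" in translate(extracted)[:-1]


def test_two_exon_truth_has_canonical_intron(tiny_repertoire):
    truth = tiny_repertoire.truth
    contigs = {c.id: c for c in tiny_repertoire.all_contigs()}
    spliced = truth[truth.status == "complete_2exon"]
    assert len(spliced)
    for row in spliced.itertuples():
        spans = sorted(tuple(map(int, p.split("-"))) for p in row.exons.split(";"))
        contig = contigs[row.contig]
        if row.strand == "+":
            donor = contig.seq[spans[0][1]:spans[0][1] + 2]
            acceptor = contig.seq[spans[1][0] - 2:spans[1][0]]
        else:
            donor = reverse_complement(contig.seq[spans[1][0] - 2:spans[1][0]])
            acceptor = reverse_complement(contig.seq[spans[0][1]:spans[0][1] + 2])
        assert donor == "GT" and acceptor == "AG"
        # phase 0: exon 1 is a whole number of codons
        exon1 = spans[0] if row.strand == "+" else spans[1]
        assert (exon1[1] - exon1[0]) % 3 == 0
        assert 40 <= row.intron_codon_index <= 80


def test_evolve_identity_band():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        cds = receptor_cds(rng, 300)
        derived = evolve_to_identity(cds, 70.0, 0.5, 1.0, rng)
        p1, p2 = translate(cds), translate(derived)
        ident = 100 * sum(a == b for a, b in zip(p1, p2)) / len(p1)
        assert 67.0 <= ident <= 73.0
        assert "*" not in p2


def test_evolve_target_100_is_identity():
    rng = np.random.default_rng(0)
    cds = receptor_cds(rng, 300)
    assert evolve_to_identity(cds, 100.0, 1.0, 1.0, rng) == cds


def test_evolve_frozen_windows_untouched():
    rng = np.random.default_rng(1)
    cds = receptor_cds(rng, 300)
    frozen = ((10, 18), (100, 108))
    derived = evolve_to_identity(cds, 60.0, 1.0, 1.0, rng, frozen)
    for lo, hi in frozen:
        assert derived[3 * lo:3 * hi] == cds[3 * lo:3 * hi]


def test_evolve_omega_zero_gives_dn_zero():
    rng = np.random.default_rng(2)
    cds = receptor_cds(rng, 300)
    # omega 0: divergence is purely synonymous (target on nucleotide identity)
    derived = evolve_to_identity(cds, 97.0, 0.0, 1.0, rng)
    assert derived != cds
    rec = ng86_pair(cds, derived)
    assert rec.Sd > 0 and rec.dN == 0.0
    assert translate(cds) == translate(derived)


def test_pseudogenize_contracts():
    rng = np.random.default_rng(3)
    cds = receptor_cds(rng, 300) + "TAA"
    fs, kind, pos = pseudogenize(cds, "frameshift", rng)
    assert kind == "frameshift"
    assert abs(len(fs) - len(cds)) in (1, 2)
    stop, kind, pos = pseudogenize(cds, "in_frame_stop", rng)
    assert len(stop) == len(cds)
    assert "*" in translate(stop)[:-1]
    with pytest.raises(ValueError):
        pseudogenize(cds, "inversion", rng)


def test_truncate_to_edge_contract():
    rng = np.random.default_rng(4)
    cds = receptor_cds(rng, 300) + "TAA"
    for side in "NC":
        for _ in range(10):
            piece, n_keep = truncate_to_edge(cds, side, rng)
            frac = n_keep / (len(cds) // 3)
            assert 0.3 <= frac <= 0.7
            if side == "N":
                assert cds.endswith(piece)
            else:
                assert cds.startswith(piece)


def test_make_intron_structure():
    rng = np.random.default_rng(5)
    for length in (70, 300, 2000):
        intron = make_intron(rng, length, 0.42)
        assert len(intron) == length
        assert intron.startswith("GT") and intron.endswith("AG")
        # no ambiguous in-frame AG/GT near the true sites
        assert intron[-5:-3] != "AG" and intron[-8:-6] != "AG"
        assert intron[3:5] != "GT" and intron[6:8] != "GT"


def test_planted_identity_margins(tiny_repertoire):
    """Within-subfamily, within-family and between-family identities are
    separated by >=10-point margins around the 60/40 thresholds."""
    truth = tiny_repertoire.truth
    comp = truth[truth.status.str.startswith("complete")]
    sample = comp.groupby(["family", "subfamily"]).head(2)
    prots = dict(zip(sample.gene, sample.protein))
    meta = {r.gene: (r.family, r.subfamily) for r in sample.itertuples()}
    import itertools

    levels = {"sub": [], "fam": [], "cross": []}
    for a, b in itertools.combinations(prots, 2):
        ident = pairwise_identity(prots[a], prots[b])
        fa, sa = meta[a]
        fb, sb = meta[b]
        key = "sub" if (fa, sa) == (fb, sb) else "fam" if fa == fb else "cross"
        levels[key].append(ident)
    assert min(levels["sub"]) >= 70.0
    assert all(40.0 <= v < 60.0 for v in levels["fam"])
    assert max(levels["cross"]) < 40.0


def test_ortholog_plants_are_near_identical(tiny_repertoire):
    truth = tiny_repertoire.truth
    og = truth[truth.ortholog_group != ""]
    groups = og.groupby("ortholog_group")
    assert len(groups) >= 1
    for _, members in groups:
        assert len(members) >= 2
        prots = list(members.protein)
        for a in prots:
            for b in prots:
                if a != b:
                    assert pairwise_identity(a, b) >= 99.0
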