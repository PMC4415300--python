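import math

import numpy as np
import pytest

from taarminer.evolution_dnds import (
    DnDsConfig,
    OMEGA_UNBOUNDED,
    OMEGA_ZERO_ZERO,
    codon_align,
    codon_site_counts,
    dnds_for_pairs,
    family_summary,
    intra_inter_summary,
    ng86_pair,
    pathway_differences,
)
from taarminer.synthetic_repertoire import SENSE_CODONS

from .oracles import ng86_oracle


@pytest.mark.parametrize("codon,R,expected_s", [
    ("TTT", 1.0, 1 / 3),  # only TTC is synonymous
    ("ATG", 1.0, 0.0),  # Met: all 9 mutants nonsynonymous
    ("TTT", 2.0, 0.5),  # transition T<->C weighted 2: 2/(2+1+1)
])
def test_codon_site_counts_examples(codon, R, expected_s):
    counts = codon_site_counts(codon, R)
    assert counts.s == pytest.approx(expected_s, abs=1e-12)
    assert counts.s + counts.n == pytest.approx(3.0, abs=1e-12)


def test_site_counts_sum_to_three_for_all_codons_and_weights():
    for codon in SENSE_CODONS:
        for R in (0.5, 1.0, 2.0, 10.0):
            c = codon_site_counts(codon, R)
            assert c.s + c.n == pytest.approx(3.0, abs=1e-9)


def test_site_counts_reject_stop_codons():
    with pytest.raises(ValueError):
        codon_site_counts("TAA")


@pytest.mark.parametrize("c1,c2,expected", [
    ("GTG", "GTA", (1.0, 0.0)),  # Val->Val third-position change
    ("TTT", "GTA", (0.5, 1.5)),  # two pathways averaged
    ("TTT", "TTT", (0.0, 0.0)),
])
def test_pathway_differences_examples(c1, c2, expected):
    sd, nd = pathway_differences(c1, c2)
    assert (sd, nd) == pytest.approx(expected)


def test_pathway_differences_conserve_total():
    rng = np.random.default_rng(0)
    for _ in range(100):
        c1, c2 = rng.choice(SENSE_CODONS, size=2)
        ndiff = sum(a != b for a, b in zip(c1, c2))
        sd, nd = pathway_differences(c1, c2)
        assert sd + nd == pytest.approx(ndiff, abs=1e-9)


def test_ng86_worked_example():
    r = ng86_pair("ATGTTTGTGCTG", "ATGTTTGTACTG")
    assert r.S == pytest.approx(8 / 3, abs=1e-9)
    assert r.N == pytest.approx(28 / 3, abs=1e-9)
    assert r.Sd == pytest.approx(1.0)
    assert r.Nd == pytest.approx(0.0)
    assert r.pS == pytest.approx(0.375)
    assert r.dS == pytest.approx(-0.75 * math.log(0.5), abs=1e-9)
    assert r.dN == 0.0
    assert r.omega == 0.0


def test_ng86_flags():
    identical = ng86_pair("ATGTTT", "ATGTTT")
    assert OMEGA_ZERO_ZERO in identical.flags
    # one nonsynonymous difference, no synonymous
    unbounded = ng86_pair("ATGTGG", "ATGCGG")
    assert OMEGA_UNBOUNDED in unbounded.flags
    assert unbounded.omega_text == ">10"


def test_ng86_symmetry_and_codon_permutation_invariance():
    rng = np.random.default_rng(1)
    codons1 = list(rng.choice(SENSE_CODONS, size=30))
    codons2 = [c if rng.random() < 0.7 else str(rng.choice(SENSE_CODONS))
               for c in codons1]
    s1, s2 = "".join(codons1), "".join(codons2)
    a = ng86_pair(s1, s2)
    b = ng86_pair(s2, s1)
    for field in ("S", "N", "Sd", "Nd", "dS", "dN"):
        assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-12)
    perm = rng.permutation(30)
    p1 = "".join(codons1[i] for i in perm)
    p2 = "".join(codons2[i] for i in perm)
    c = ng86_pair(p1, p2)
    assert c.dS == pytest.approx(a.dS, abs=1e-12)
    assert c.dN == pytest.approx(a.dN, abs=1e-12)


def test_ng86_matches_independent_oracle():
    """R=1 output equals the exhaustive-enumeration NG86 oracle on 200
    random codon-sequence pairs, to 1e-9 in every field."""
    rng = np.random.default_rng(2)
    for _ in range(200):
        n = int(rng.integers(10, 40))
        codons1 = list(rng.choice(SENSE_CODONS, size=n))
        codons2 = [c if rng.random() < 0.75 else str(rng.choice(SENSE_CODONS))
                   for c in codons1]
        s1, s2 = "".join(codons1), "".join(codons2)
        mine = ng86_pair(s1, s2)
        ref = ng86_oracle(s1, s2)
        for field in ("S", "N", "Sd", "Nd", "pS", "pN"):
            assert getattr(mine, field) == pytest.approx(ref[field], abs=1e-9)
        for field in ("dS", "dN"):
            if math.isnan(ref[field]):
                assert math.isnan(getattr(mine, field))
            else:
                assert getattr(mine, field) == pytest.approx(ref[field], abs=1e-9)


def test_ng86_input_validation():
    with pytest.raises(ValueError):
        ng86_pair("ATG", "ATGTTT")
    with pytest.raises(ValueError):
        ng86_pair("ATGT", "ATGA")


def test_codon_align_strips_stops_and_gaps():
    # identical proteins, one sequence carries a terminal stop
    a, b = codon_align("ATGTTTAAA" + "TAA", "ATGTTTAAA")
    assert a == b == "ATGTTTAAA"


def test_family_summary_means():
    recs = dnds_for_pairs(
        {"a": "ATGTTTGTGCTG", "b": "ATGTTTGTACTG", "c": "ATGTTTGTGCTG"},
        [("a", "b"), ("a", "c"), ("b", "c")],
    )
    fam = {"a": "A", "b": "A", "c": "A"}
    df = family_summary(recs, fam)
    finite = [r.omega for r in recs if not math.isnan(r.omega)]
    assert df.iloc[0]["mean"] == pytest.approx(np.mean(finite))
    assert df.iloc[0]["min"] <= df.iloc[0]["mean"] <= df.iloc[0]["max"]


def test_intra_inter_single_species_leaves_inter_empty():
    recs = dnds_for_pairs(
        {"a": "ATGTTTGTGCTG", "b": "ATGTTTGTACTG"}, [("a", "b")]
    )
    df = intra_inter_summary(recs, {"a": "Til", "b": "Til"}, {"a": "A", "b": "A"})
    row = df[df.species == "Til"].iloc[0]
    assert row["intra_n"] == 1
    assert row["inter_n"] == 0 and math.isnan(row["inter_mean"])


def test_omega_recovery_under_simulation():
    """A repertoire evolved with nonsynonymous acceptance 0.4 yields a mean
    pairwise omega close to 0.4."""
    from taarminer.evaluate import omega_recovery

    mean = omega_recovery(0.4, seed=123, n_codons=300, identity=85.0)
    assert mean == pytest.approx(0.4, abs=0.05)
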