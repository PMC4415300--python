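"""Independent reference implementations used only as test oracles.

These deliberately re-derive results from first principles (exhaustive
dynamic programming, mutant enumeration, closed-form tree distances) and
share no code with the package internals they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Exhaustive affine-gap Smith–Waterman score (gap of length k costs
    gap_open + k * gap_extend)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            sub = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0.0,
                sub + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]),
            )
            best = max(best, M[i][j])
    return best


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


_STOPS = {"TAA", "TAG", "TGA"}


def _syn_fraction(codon: str) -> float:
    """NG86 synonymous site count of one codon (stop targets nonsynonymous)."""
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut not in _STOPS and _aa(mut) == _aa(codon):
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences; pathways
    through stop codons are excluded (renormalised)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd = nd = 0.0
    valid = 0
    for order in itertools.permutations(diff):
        path = [c1]
        cur = c1
        ok = True
        for pos in order:
            cur = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if cur in _STOPS and cur != c2:
                ok = False
                break
            path.append(cur)
        if not ok:
            continue
        valid += 1
        for prev, nxt in zip(path, path[1:]):
            if _aa(prev) == _aa(nxt):
                sd += 1
            else:
                nd += 1
    if valid == 0:  # all pathways blocked: count them anyway
        for order in itertools.permutations(diff):
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if "*" in (_aa(cur), _aa(nxt)) or _aa(cur) != _aa(nxt):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            valid += 1
    return sd / valid, nd / valid


def ng86_oracle(s1: str, s2: str) -> dict:
    """Textbook Nei–Gojobori (1986) dN/dS of a codon-aligned pair."""
    assert len(s1) == len(s2) and len(s1) % 3 == 0
    S1 = S2 = Sd = Nd = 0.0
    n_codons = len(s1) // 3
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        S1 += _syn_fraction(c1)
        S2 += _syn_fraction(c2)
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    S = (S1 + S2) / 2
    N = 3 * n_codons - S
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3) if 0 < p < 0.75 else (
        0.0 if p <= 0 else float("nan"))
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "dS": jc(pS), "dN": jc(pN)}


def random_additive_matrix(rng: np.random.Generator, n_taxa: int):
    """Random binary tree -> (taxon labels, exact path-distance matrix)."""
    dist = np.zeros((n_taxa, n_taxa))
    # join random clusters; each join hangs both sides on fresh branches
    pending = [([i], {i: 0.0}) for i in range(n_taxa)]
    while len(pending) > 1:
        i, j = sorted(rng.choice(len(pending), size=2, replace=False))
        (la, da), (lb, db) = pending[i], pending[j]
        ba = float(rng.uniform(0.05, 0.5))
        bb = float(rng.uniform(0.05, 0.5))
        for x in la:
            da[x] += ba
        for y in lb:
            db[y] += bb
        for x in la:
            for y in lb:
                dist[x, y] = dist[y, x] = da[x] + db[y]
        merged = la + lb
        dmerged = {**da, **db}
        pending = [p for k, p in enumerate(pending) if k not in (i, j)]
        pending.append((merged, dmerged))
    labels = [f"t{i}" for i in range(n_taxa)]
    return labels, dist
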