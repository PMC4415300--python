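"""Identity-threshold family/subfamily clustering, ortholog detection, NJ tree.

Families are single-linkage connected components of the pairwise-identity
graph at the 40% threshold; subfamilies are the components at 60% within
each family.  Orthologs are maximal cliques of size 2 or 3 at >=99%
identity spanning more than one species (single-species groups are labelled
paralogs).  The guide tree is neighbor-joining on d = 1 - identity/100.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ._align import global_alignment
from .seq_core import ProteinSeq


@dataclass(frozen=True)
class FamilyAssignment:
    gene: str
    family: str
    subfamily: int


@dataclass(frozen=True)
class OrthologGroup:
    members: tuple[str, ...]
    species: tuple[str, ...]
    min_identity: float

    @property
    def kind(self) -> str:
        return "ortholog" if len(set(self.species)) >= 2 else "paralog"


class IdentityMatrix:
    """Symmetric percent amino-acid identity over a set of gene proteins."""

    def __init__(self, ids: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(values, values.T):
            raise ValueError("identity matrix must be symmetric")
        if values.min() < 0 or values.max() > 100:
            raise ValueError("identities must lie in [0, 100]")
        self.ids = list(ids)
        self.values = values
        self._index = {g: i for i, g in enumerate(ids)}

    def __getitem__(self, pair):
        a, b = pair
        return self.values[self._index[a], self._index[b]]


def pairwise_identity(a: ProteinSeq | str, b: ProteinSeq | str) -> float:
    """Percent identity from a global alignment (identical / both-non-gap)."""
    sa = a.seq if isinstance(a, ProteinSeq) else a
    sb = b.seq if isinstance(b, ProteinSeq) else b
    if not sa or not sb:
        raise ValueError("cannot compute identity of an empty sequence")
    _, ra, rb = global_alignment(sa, sb)
    same = both = 0
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            both += 1
            same += x == y
    if both == 0:
        return 0.0
    return 100.0 * same / both


def identity_matrix(proteins: list[ProteinSeq]) -> IdentityMatrix:
    n = len(proteins)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pairwise_identity(proteins[i], proteins[j])
    return IdentityMatrix([p.id for p in proteins], vals)


def _components(ids: list[str], adj: np.ndarray) -> list[list[str]]:
    """Connected components (single linkage) of a boolean adjacency matrix."""
    n = len(ids)
    unseen = set(range(n))
    comps = []
    while unseen:
        root = min(unseen)
        stack, comp = [root], []
        unseen.discard(root)
        while stack:
            i = stack.pop()
            comp.append(i)
            nbrs = np.flatnonzero(adj[i])
            for j in nbrs:
                if j in unseen:
                    unseen.discard(int(j))
                    stack.append(int(j))
        comps.append(sorted(ids[i] for i in comp))
    return comps


def _ordered(comps: list[list[str]]) -> list[list[str]]:
    """Decreasing size, then lexicographic smallest member (presentation order)."""
    return sorted(comps, key=lambda c: (-len(c), c[0]))


def cluster_families(matrix: IdentityMatrix, family_thr: float = 40.0,
                     subfamily_thr: float = 60.0) -> list[FamilyAssignment]:
    ids = matrix.ids
    vals = matrix.values
    fam_adj = vals >= family_thr
    np.fill_diagonal(fam_adj, False)
    families = _ordered(_components(ids, fam_adj))
    if len(families) > 26:
        warnings.warn("more than 26 families; letters will repeat with suffixes")
    out: list[FamilyAssignment] = []
    for fi, members in enumerate(families):
        letter = chr(ord("A") + fi % 26) + ("" if fi < 26 else str(fi // 26))
        idx = [matrix._index[g] for g in members]
        sub_vals = vals[np.ix_(idx, idx)]
        sub_adj = sub_vals >= subfamily_thr
        np.fill_diagonal(sub_adj, False)
        subs = _ordered(_components(members, sub_adj))
        for si, sub_members in enumerate(subs, start=1):
            for g in sub_members:
                out.append(FamilyAssignment(gene=g, family=letter, subfamily=si))
    order = {g: i for i, g in enumerate(ids)}
    out.sort(key=lambda a: order[a.gene])
    return out


def find_orthologs(matrix: IdentityMatrix,
                   species_of: dict[str, str],
                   threshold: float = 99.0) -> list[OrthologGroup]:
    """Maximal cliques of size 2–3 in the >=threshold identity graph."""
    ids = matrix.ids
    vals = matrix.values
    n = len(ids)
    adj = vals >= threshold
    np.fill_diagonal(adj, False)
    neighbours = {i: set(np.flatnonzero(adj[i]).tolist()) for i in range(n)}
    groups: list[OrthologGroup] = []
    # triplets first
    in_triplet: set[frozenset[int]] = set()
    for i, j, k in itertools.combinations(range(n), 3):
        if adj[i, j] and adj[i, k] and adj[j, k]:
            # maximal: no fourth member adjacent to all three
            if neighbours[i] & neighbours[j] & neighbours[k]:
                warnings.warn("identity clique larger than 3; not reported")
                continue
            members = (ids[i], ids[j], ids[k])
            groups.append(OrthologGroup(
                members=members,
                species=tuple(species_of[g] for g in members),
                min_identity=float(min(vals[i, j], vals[i, k], vals[j, k])),
            ))
            in_triplet |= {frozenset((i, j)), frozenset((i, k)), frozenset((j, k))}
    for i, j in itertools.combinations(range(n), 2):
        if adj[i, j] and frozenset((i, j)) not in in_triplet:
            if neighbours[i] & neighbours[j]:
                continue  # part of a triplet/larger clique
            members = (ids[i], ids[j])
            groups.append(OrthologGroup(
                members=members,
                species=tuple(species_of[g] for g in members),
                min_identity=float(vals[i, j]),
            ))
    groups.sort(key=lambda g: g.members)
    return groups


def nj_tree(distances: np.ndarray, ids: list[str]) -> TreeNode:
    """Neighbor-joining tree; negative branch estimates are clamped to 0."""
    distances = np.asarray(distances, dtype=float)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    if not np.allclose(distances, distances.T):
        raise ValueError("distance matrix must be symmetric")
    if len(ids) == 2:
        half = distances[0, 1] / 2.0
        a = TreeNode(name=ids[0], length=half)
        b = TreeNode(name=ids[1], length=half)
        return TreeNode(children=[a, b])
    dm = DistanceMatrix(distances, ids)
    return nj(dm, neg_as_zero=True)


def tree_from_identity(matrix: IdentityMatrix) -> TreeNode:
    return nj_tree(1.0 - matrix.values / 100.0, matrix.ids)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
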