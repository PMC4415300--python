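"""Shared protein-alignment machinery (Bio.Align.PairwiseAligner wrappers).

Gap costs follow the BLAST convention: a gap of length k costs
``open + k * extend``, so e.g. 11/1 charges 12 for a single-residue gap.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices


@lru_cache(maxsize=8)
def get_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


@lru_cache(maxsize=32)
def make_aligner(mode: str, matrix: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = get_matrix(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_score(a: str, b: str, matrix: str = "BLOSUM62",
                gap_open: int = 11, gap_extend: int = 1) -> float:
    """Smith–Waterman score only (fast path; no traceback)."""
    if not a or not b:
        return 0.0
    return make_aligner("local", matrix, gap_open, gap_extend).score(a, b)


def local_alignment(a: str, b: str, matrix: str = "BLOSUM62",
                    gap_open: int = 11, gap_extend: int = 1):
    """Best local alignment of ``b`` (query) against ``a`` (target).

    Returns ``(score, (a_aligned, b_aligned), (a_start, a_end), (b_start, b_end))``
    with gapped alignment strings covering the aligned region only.  The
    first optimal traceback reported by the aligner is taken, which is
    deterministic for fixed inputs.
    """
    if not a or not b:
        return 0.0, ("", ""), (0, 0), (0, 0)
    aligner = make_aligner("local", matrix, gap_open, gap_extend)
    alignments = aligner.align(a, b)
    if len(alignments) == 0:  # no positive-scoring local alignment
        return 0.0, ("", ""), (0, 0), (0, 0)
    aln = alignments[0]
    tblocks, qblocks = aln.aligned
    a_span = (int(tblocks[0][0]), int(tblocks[-1][1]))
    b_span = (int(qblocks[0][0]), int(qblocks[-1][1]))
    return float(aln.score), (str(aln[0]), str(aln[1])), a_span, b_span


def global_alignment(a: str, b: str, matrix: str = "BLOSUM62",
                     gap_open: int = 10, gap_extend: int = 1):
    """Needleman–Wunsch alignment; returns (score, a_aligned, b_aligned)."""
    aligner = make_aligner("global", matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return float(aln.score), str(aln[0]), str(aln[1])
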