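"""Translated homology search: bait proteins vs six-frame contig translations.

The search strategy stands in for TBLASTN: candidate regions are located by
exact amino-acid k-mer seeding on the six frame translations, then scored by
Smith–Waterman with affine gaps; significance uses the Karlin–Altschul
approximation E = K·m·n·exp(−λS).  Candidate loci are retained when they hit
the positive (TAAR) bait set below the e-value cutoff and do not hit the
negative (non-TAAR class-A GPCR) bait set below its cutoff.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace

from . import _align
from .seq_core import Contig, Frame, GenomicInterval, ProteinSeq, six_frame_translate

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class Bait:
    id: str
    role: str  # positive | negative
    protein: ProteinSeq

    def __post_init__(self):
        if self.role not in (POSITIVE, NEGATIVE):
            raise ValueError(f"bait role must be positive/negative, got {self.role!r}")


@dataclass(frozen=True)
class SearchConfig:
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    #: Karlin–Altschul parameters (ungapped BLOSUM62 values reused for gapped
    #: scores — an approximation; absolute E-values differ from NCBI BLAST)
    lam: float = 0.267
    K: float = 0.041
    e_pos: float = 1e-50
    e_neg: float = 1e-50
    merge_gap: int = 2000
    seed_k: int = 5
    min_cluster_seeds: int = 2

    def __post_init__(self):
        if not (0 < self.e_pos <= 1 and 0 < self.e_neg <= 1):
            raise ValueError("e-value cutoffs must lie in (0, 1]")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    bait_id: str
    role: str
    interval: GenomicInterval
    frame: int
    raw_score: float
    bitscore: float
    evalue: float
    protein_alignment: tuple[str, str]
    #: query (bait) residue span covered by the alignment
    bait_span: tuple[int, int] = (0, 0)


@dataclass
class Locus:
    interval: GenomicInterval
    best_positive: AlignmentHit | None
    best_negative_evalue: float | None
    hits: list[AlignmentHit] = field(default_factory=list)


def evalue(raw_score: float, m: int, n: int, config: SearchConfig) -> float:
    """Karlin–Altschul expect value for a raw alignment score."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    return config.K * m * n * math.exp(-config.lam * raw_score)


def bitscore(raw_score: float, config: SearchConfig) -> float:
    return (config.lam * raw_score - math.log(config.K)) / math.log(2.0)


def local_align(query: ProteinSeq, target: ProteinSeq,
                config: SearchConfig = SearchConfig()):
    """Smith–Waterman local alignment; returns (raw_score, (q_aln, t_aln))."""
    score, (t_aln, q_aln), _, _ = _align.local_alignment(
        target.seq, query.seq, config.matrix, config.gap_open, config.gap_extend
    )
    return score, (q_aln, t_aln)


def _kmer_index(protein: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(protein) - k + 1):
        index[protein[i : i + k]].append(i)
    return index


def _seed_clusters(bait: str, index: dict[str, list[int]], k: int,
                   min_seeds: int) -> list[tuple[int, int]]:
    """Cluster seed matches along the target; returns (t_min, t_max) spans."""
    positions: list[int] = []
    for i in range(len(bait) - k + 1):
        positions.extend(index.get(bait[i : i + k], ()))
    if not positions:
        return []
    positions.sort()
    clusters: list[list[int]] = [[positions[0]]]
    gap = max(len(bait) // 2, 25)
    for t in positions[1:]:
        if t - clusters[-1][-1] <= gap:
            clusters[-1].append(t)
        else:
            clusters.append([t])
    return [(c[0], c[-1]) for c in clusters if len(c) >= min_seeds]


def search_contig(baits: list[Bait], contig: Contig,
                  config: SearchConfig = SearchConfig()) -> list[AlignmentHit]:
    """All significant bait hits on a contig, both strands, genomic coordinates."""
    frames = six_frame_translate(contig)
    if not frames:
        return []
    n_res = sum(len(f.protein) for f in frames)
    cutoff = max(config.e_pos, config.e_neg)
    hits: list[AlignmentHit] = []
    for frame in frames:
        if len(frame.protein) < config.seed_k:
            continue
        index = _kmer_index(frame.protein, config.seed_k)
        for bait in baits:
            m = len(bait.protein)
            for t_min, t_max in _seed_clusters(
                bait.protein.seq, index, config.seed_k, config.min_cluster_seeds
            ):
                w0 = max(0, t_min - m)
                w1 = min(len(frame.protein), t_max + m + config.seed_k)
                window = frame.protein[w0:w1]
                score, (t_aln, q_aln), t_span, q_span = _align.local_alignment(
                    window, bait.protein.seq,
                    config.matrix, config.gap_open, config.gap_extend,
                )
                if score <= 0:
                    continue
                E = evalue(score, m, n_res, config)
                if E > cutoff:
                    continue
                aa0, aa1 = w0 + t_span[0], w0 + t_span[1]
                iv0 = frame.codon_interval(aa0)
                iv1 = frame.codon_interval(aa1 - 1)
                start = min(iv0.start, iv1.start)
                end = max(iv0.end, iv1.end)
                hits.append(
                    AlignmentHit(
                        bait_id=bait.id,
                        role=bait.role,
                        interval=GenomicInterval(contig.id, start, end, frame.strand),
                        frame=frame.label,
                        raw_score=score,
                        bitscore=bitscore(score, config),
                        evalue=E,
                        protein_alignment=(q_aln, t_aln),
                        bait_span=q_span,
                    )
                )
    return _dedupe(hits)


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits duplicated by overlapping seed windows (same bait & frame)."""
    hits = sorted(hits, key=lambda h: (h.bait_id, h.frame, -h.raw_score))
    kept: list[AlignmentHit] = []
    for h in hits:
        if any(
            k.bait_id == h.bait_id and k.frame == h.frame and k.interval.overlaps(h.interval)
            for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.interval.contig_id, h.interval.strand, h.interval.start))
    return kept


def merge_hits(hits: list[AlignmentHit],
               merge_gap: int = 2000) -> list[Locus]:
    """Merge same-contig, same-strand hits within ``merge_gap`` nt into loci."""
    groups: dict[tuple[str, str], list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        groups[(h.interval.contig_id, h.interval.strand)].append(h)
    loci: list[Locus] = []
    for (cid, strand), ghits in sorted(groups.items()):
        ghits.sort(key=lambda h: (h.interval.start, h.interval.end))
        cur: list[AlignmentHit] = []
        cur_end = -1
        for h in ghits:
            if cur and h.interval.start - cur_end > merge_gap:
                loci.append(_make_locus(cid, strand, cur))
                cur = []
            cur.append(h)
            cur_end = max(cur_end, h.interval.end)
        if cur:
            loci.append(_make_locus(cid, strand, cur))
    loci.sort(key=lambda l: (l.interval.contig_id, l.interval.strand, l.interval.start))
    return loci


def _make_locus(cid: str, strand: str, hits: list[AlignmentHit]) -> Locus:
    start = min(h.interval.start for h in hits)
    end = max(h.interval.end for h in hits)
    pos = [h for h in hits if h.role == POSITIVE]
    neg = [h for h in hits if h.role == NEGATIVE]
    return Locus(
        interval=GenomicInterval(cid, start, end, strand),
        best_positive=min(pos, key=lambda h: (h.evalue, -h.raw_score, h.bait_id))
        if pos else None,
        best_negative_evalue=min(h.evalue for h in neg) if neg else None,
        hits=sorted(hits, key=lambda h: (h.interval.start, h.bait_id)),
    )


def bait_filter(loci: list[Locus], config: SearchConfig = SearchConfig()
                ) -> tuple[list[Locus], list[tuple[Locus, str]]]:
    """Apply the positive/negative bait criteria to candidate loci.

    A locus is retained iff its best positive e-value is at or below
    ``e_pos`` and it has no negative-bait match at or below ``e_neg``.
    Returns (retained, rejected-with-reason).
    """
    retained: list[Locus] = []
    rejected: list[tuple[Locus, str]] = []
    for locus in loci:
        if locus.best_positive is None or locus.best_positive.evalue > config.e_pos:
            rejected.append((locus, "no_positive_match"))
        elif locus.best_negative_evalue is not None and locus.best_negative_evalue <= config.e_neg:
            rejected.append((locus, "negative_bait_match"))
        else:
            retained.append(locus)
    return retained, rejected
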