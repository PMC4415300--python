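"""Gene-model reconstruction and status classification for candidate loci.

A retained locus is turned into one of:

* a single-exon complete model (ATG→stop ORF in the expected length window),
* a two-exon complete model with one canonical phase-0 GT–AG intron
  (donor searched near the family-typical position, around codon 55),
* a pseudogene (frameshift and/or in-frame stop disruptions),
* an edge gene (bait alignment truncated at a contig boundary), or
* a fragment (incomplete but internal, without disruptions).

Competing interpretations (contiguous ORF, spliced model, disruption chain)
are adjudicated by their bait alignment score, which resolves the inherent
ambiguity between "an intron" and "a frameshifted/stop-interrupted region":
a real intron removes non-coding sequence and so *gains* score over any
contiguous reading, while skipping coding sequence to bridge a disruption
loses it.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import bisect

from ._align import local_alignment, local_score
from .seq_core import (
    Contig,
    GenomicInterval,
    ProteinSeq,
    STOP_CODONS,
    reverse_complement,
    translate,
)
from .translated_search import Locus

COMPLETE_1EXON = "complete_1exon"
COMPLETE_2EXON = "complete_2exon"
PSEUDOGENE = "pseudogene"
EDGE = "edge"
FRAGMENT = "fragment"

STATUS_LETTER = {
    COMPLETE_1EXON: "",
    COMPLETE_2EXON: "s",
    PSEUDOGENE: "p",
    EDGE: "e",
    FRAGMENT: "f",
}

AROMATIC = set("FYW")
BASIC = set("RKH")


@dataclass(frozen=True)
class ModelConfig:
    #: accepted CDS length window, in codons including the stop codon
    min_codons: int = 250
    max_codons: int = 400
    #: donor search window (codon after which the intron falls); models with
    #: a best-scoring canonical intron outside the soft window but inside the
    #: hard bounds are accepted and flagged atypical
    intron_codon_window: tuple[int, int] = (40, 80)
    intron_codon_hard: tuple[int, int] = (20, 120)
    intron_length: tuple[int, int] = (50, 5000)
    #: local alignments trim noisy terminal residues, so "reaches the contig
    #: boundary" is tested with a tolerance of a few codons
    edge_margin: int = 30
    #: genomic flank searched around a locus for missed exons / start codons
    flank: int = 6000
    min_hit_overlap: float = 0.8
    #: a single-exon model must cover at least this fraction of the bait
    #: (an ORF spanning only part of the receptor is a fragment, not a gene)
    min_bait_coverage: float = 0.8
    #: minimum (junk-penalised) bait alignment score of a candidate exon 1;
    #: rejects "exons" assembled from background sequence
    min_exon1_score: float = 40.0
    #: alignment segments below this score are noise: the expected best
    #: chance score of a ~330-residue bait against a 10-kb random region is
    #: ~40–45 under BLOSUM62, so the floor sits above it
    min_segment_score: float = 60.0
    #: max genomic gap (nt) between alignment segments treated as a
    #: frameshift/stop bridge rather than a potential intron
    max_bridge_gap: int = 12
    #: bait-residue jump tolerated across the splice junction when checking
    #: that a candidate intron does not swallow coding sequence
    max_junction_jump: int = 3
    #: distance (nt) above which positive hits in one locus are treated as
    #: separate gene candidates (tandem genes merged at the locus stage)
    gene_group_gap: int = 800


@dataclass(frozen=True)
class Disruption:
    kind: str  # frameshift | in_frame_stop
    position: int  # codon index, 1-based, approximate for frameshifts
    detail: str = ""


@dataclass(frozen=True)
class JunctionDipeptide:
    left_aa: str
    right_aa: str

    def __str__(self) -> str:
        return self.left_aa + self.right_aa

    @property
    def aromatic_basic(self) -> bool:
        return self.left_aa in AROMATIC and self.right_aa in BASIC


@dataclass(frozen=True)
class SpliceSite:
    donor_pos: int
    acceptor_pos: int
    donor_dinuc: str
    acceptor_dinuc: str


@dataclass
class GeneModel:
    species: str
    exons: list[GenomicInterval]
    strand: str
    cds: str
    protein: str
    status: str
    pseudo_type: str = "none"
    junction: JunctionDipeptide | None = None
    intron_codon_index: int | None = None
    splice_site: SpliceSite | None = None
    disruptions: list[Disruption] = field(default_factory=list)
    atypical_junction: bool = False
    name: str = ""
    family: str = "U"
    subfamily: int = 0
    #: bait alignment score of the model protein (model selection evidence)
    score: float = 0.0

    @property
    def contig_id(self) -> str:
        return self.exons[0].contig_id

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def is_complete(self) -> bool:
        return self.status in (COMPLETE_1EXON, COMPLETE_2EXON)


class _Region:
    """Strand-local view of the genomic neighbourhood of a locus.

    ``mask`` intervals (forward coordinates) belonging to *other* gene
    candidates on the contig are blanked with 'N' so that model inference
    cannot chimerically borrow exons from a neighbouring gene.
    """

    def __init__(self, contig: Contig, locus: Locus, flank: int,
                 mask: list[GenomicInterval] | None = None):
        self.contig = contig
        self.strand = locus.interval.strand
        self.r0 = max(0, locus.interval.start - flank)
        self.r1 = min(len(contig), locus.interval.end + flank)
        seq = contig.seq[self.r0 : self.r1]
        if mask:
            chars = list(seq)
            for iv in mask:
                lo = max(iv.start - self.r0, 0)
                hi = min(iv.end - self.r0, len(chars))
                for i in range(lo, hi):
                    chars[i] = "N"
            seq = "".join(chars)
        self.s = seq if self.strand == "+" else reverse_complement(seq)

    def to_forward(self, x0: int, x1: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.r0 + x0, self.r0 + x1
        return self.r1 - x1, self.r1 - x0

    def from_forward(self, f0: int, f1: int) -> tuple[int, int]:
        if self.strand == "+":
            return f0 - self.r0, f1 - self.r0
        return self.r1 - f1, self.r1 - f0

    def interval(self, x0: int, x1: int) -> GenomicInterval:
        s, e = self.to_forward(x0, x1)
        return GenomicInterval(self.contig.id, s, e, self.strand)

    # local coordinates of the contig boundaries, in gene orientation
    @property
    def upstream_bound(self) -> int:
        return -self.r0 if self.strand == "+" else self.r1 - len(self.contig)

    @property
    def downstream_bound(self) -> int:
        return len(self.contig) - self.r0 if self.strand == "+" else self.r1


def _find_all(s: str, sub: str) -> list[int]:
    out, i = [], s.find(sub)
    while i != -1:
        out.append(i)
        i = s.find(sub, i + 1)
    return out


# ---------------------------------------------------------------------------
# single-exon models
# ---------------------------------------------------------------------------

def build_single_exon_model(locus: Locus, contig: Contig,
                            config: ModelConfig = ModelConfig(),
                            mask: list[GenomicInterval] | None = None) -> GeneModel | None:
    """Longest in-window ATG→stop ORF overlapping the best positive hit."""
    reg = _Region(contig, locus, config.flank, mask)
    hit = locus.best_positive
    if hit is None:
        return None
    best: tuple[int, int, int] | None = None  # (codons, -start, start) best key
    best_span: tuple[int, int] | None = None
    s = reg.s
    for off in range(3):
        n = (len(s) - off) // 3
        prot = translate(s[off : off + 3 * n]) if n else ""
        seg_start = 0  # codon index where current stop-free segment starts
        i = 0
        while i <= len(prot):
            if i == len(prot) or prot[i] == "*":
                if i < len(prot):  # segment ends with a real stop codon
                    atg = prot.find("M", seg_start, i)
                    if atg != -1:
                        codons = i - atg + 1  # incl. stop
                        if config.min_codons <= codons <= config.max_codons:
                            x0 = off + 3 * atg
                            x1 = off + 3 * (i + 1)
                            iv = reg.interval(x0, x1)
                            ov = min(iv.end, hit.interval.end) - max(iv.start, hit.interval.start)
                            # the ORF must reach both ends of the alignment
                            # evidence (a shorter internal ORF, e.g. downstream
                            # of a disrupting stop, is not a complete gene)
                            if (ov >= config.min_hit_overlap * len(hit.interval)
                                    and iv.start <= hit.interval.start + config.edge_margin
                                    and iv.end >= hit.interval.end - config.edge_margin):
                                key = (codons, -x0)
                                if best is None or key > best:
                                    best = key
                                    best_span = (x0, x1)
                seg_start = i + 1
            i += 1
    if best_span is None:
        return None
    x0, x1 = best_span
    cds = reg.s[x0:x1]
    return GeneModel(
        species=contig.species,
        exons=[reg.interval(x0, x1)],
        strand=reg.strand,
        cds=cds,
        protein=translate(cds)[:-1],
        status=COMPLETE_1EXON,
    )


# ---------------------------------------------------------------------------
# two-exon models
# ---------------------------------------------------------------------------

def _junction_colinear(prot: str, k: int, bait: str, max_jump: int = 3) -> bool:
    """True if the bait alignment runs contiguously across the splice junction.

    A genuine intron removes only non-coding sequence, so the bait residues
    aligned to the last exon-1 residue (index k-1) and the first exon-2
    residue (index k) must be adjacent (within ``max_jump``), and the
    alignment must not need a long gap anywhere to absorb missing residues.
    A spurious "intron" bridging a frameshift or skipping an in-frame stop
    swallows coding sequence and fails one of the two tests.
    """
    _, (t_aln, q_aln), t_span, _ = local_alignment(prot, bait)
    if not (t_span[0] <= k - 1 and k < t_span[1]):
        return False
    for aln in (t_aln, q_aln):
        run = best_run = 0
        for ch in aln:
            run = run + 1 if ch == "-" else 0
            best_run = max(best_run, run)
        if best_run > 2 * max_jump:
            return False
    tpos = t_span[0]
    qpos = None
    b_left = b_right = None
    # walk columns; record bait positions opposite prot residues k-1 and k
    bp = 0
    for tc, qc in zip(t_aln, q_aln):
        if tc != "-" and qc != "-":
            if tpos == k - 1:
                b_left = bp
            elif tpos == k:
                b_right = bp
        if tc != "-":
            tpos += 1
        if qc != "-":
            bp += 1
    if b_left is None or b_right is None:
        return False
    return 1 <= b_right - b_left <= max_jump


def infer_spliced_model(locus: Locus, bait: ProteinSeq, contig: Contig,
                        config: ModelConfig = ModelConfig(),
                        mask: list[GenomicInterval] | None = None) -> GeneModel | None:
    """Best-scoring canonical two-exon model, or None.

    Exon 2 is anchored on the best positive hit's frame; candidate acceptors
    are in-frame AG positions inside the stop-free extension of that frame,
    donors are GT dinucleotides a phase-0 codon boundary downstream of a
    candidate ATG.  Candidates are ranked by the spliced protein's local
    alignment score against the bait (exon-wise scores prescreen the
    combinations); the best candidate whose junction is colinear with the
    bait wins.  Ties prefer the shorter intron, then the smaller donor
    coordinate.
    """
    reg = _Region(contig, locus, config.flank, mask)
    hit = locus.best_positive
    if hit is None:
        return None
    s = reg.s
    lh0, lh1 = reg.from_forward(hit.interval.start, hit.interval.end)
    if lh0 < 0 or lh0 >= len(s):
        return None

    # The hit may bridge the intron (exons in the same genomic frame), in
    # which case its in-frame reading crosses intronic stop codons: anchor
    # candidate exon-2 ORF stretches at several points along the hit and
    # pool the resulting (ext_start, stop_end) stretches.
    anchors = sorted({
        x - (x - lh0) % 3
        for x in (lh1 - 3, (lh0 + lh1) // 2, lh0)
        if lh0 <= x - (x - lh0) % 3 < len(s) - 2
    })
    stretches: set[tuple[int, int]] = set()
    for anchor in anchors:
        if s[anchor : anchor + 3] in STOP_CODONS:
            continue
        p = anchor
        while p - 3 >= 0 and s[p - 3 : p] not in STOP_CODONS:
            p -= 3
        q = anchor
        while q + 3 <= len(s) and s[q : q + 3] not in STOP_CODONS:
            q += 3
        if q + 3 <= len(s):  # a stop codon terminates the stretch
            stretches.add((p, q + 3))
    if not stretches:
        return None

    atg = sorted(_find_all(s, "ATG"))
    gt = sorted(_find_all(s, "GT"))
    min_i, max_i = config.intron_length
    hard_lo, hard_hi = config.intron_codon_hard
    soft_lo, soft_hi = config.intron_codon_window

    e1_cache: dict[tuple[int, int], tuple[str, float] | None] = {}
    e2_cache: dict[tuple[int, int], float] = {}
    candidates = []
    for ext_start, stop_end in sorted(stretches):
        for p_acc in range(max(ext_start, 2), stop_end - 90 + 1):
            if (p_acc - ext_start) % 3 or s[p_acc - 2 : p_acc] != "AG":
                continue
            exon2_codons = (stop_end - p_acc) // 3
            lo_d = bisect.bisect_left(gt, p_acc - max_i)
            hi_d = bisect.bisect_right(gt, p_acc - min_i)
            for d in gt[lo_d:hi_d]:
                lo_a = bisect.bisect_left(atg, d - 3 * hard_hi)
                hi_a = bisect.bisect_right(atg, d - 3 * hard_lo)
                for a in atg[lo_a:hi_a]:
                    if (d - a) % 3:
                        continue
                    k = (d - a) // 3
                    total = k + exon2_codons  # codons incl. stop
                    if not config.min_codons <= total <= config.max_codons:
                        continue
                    if (a, d) in e1_cache:
                        cached = e1_cache[(a, d)]
                        if cached is None:
                            continue
                    else:
                        exon1_aa = translate(s[a:d])
                        if "*" in exon1_aa:
                            e1_cache[(a, d)] = None
                            continue
                        # penalise exon residues outside the bait alignment so
                        # junk-padded variants rank below the clean candidate
                        sc1, _, e1_span, _ = local_alignment(exon1_aa, bait.seq)
                        junk1 = len(exon1_aa) - (e1_span[1] - e1_span[0])
                        if sc1 - junk1 < config.min_exon1_score:
                            e1_cache[(a, d)] = None
                            continue
                        cached = (exon1_aa, sc1 - junk1)
                        e1_cache[(a, d)] = cached
                    exon1_aa, e1_score = cached
                    key2 = (p_acc, stop_end)
                    if key2 not in e2_cache:
                        exon2_aa = translate(s[p_acc:stop_end])[:-1]
                        sc2, _, e2_span, _ = local_alignment(exon2_aa, bait.seq)
                        junk2 = len(exon2_aa) - (e2_span[1] - e2_span[0])
                        e2_cache[key2] = sc2 - junk2
                    candidates.append(
                        (e1_score + e2_cache[key2], a, d, p_acc, stop_end, k, exon1_aa)
                    )
    if not candidates:
        return None

    # full-score the most promising combinations only
    candidates.sort(key=lambda c: (-c[0], c[3] - c[2], c[2]))
    scored = []
    for _, a, d, p_acc, stop_end, k, exon1_aa in candidates[:30]:
        prot = exon1_aa + translate(s[p_acc:stop_end])[:-1]
        scored.append((local_score(prot, bait.seq), a, d, p_acc, stop_end, k, prot))
    scored.sort(key=lambda c: (-c[0], c[3] - c[2], c[2]))
    best = None
    for score, a, d, p_acc, stop_end, k, prot in scored:
        if _junction_colinear(prot, k, bait.seq, config.max_junction_jump):
            best = (score, a, d, p_acc, stop_end, k, prot)
            break
    if best is None:
        return None
    score, a, d, p_acc, stop_end, k, prot = best

    exon1_iv = reg.interval(a, d)
    exon2_iv = reg.interval(p_acc, stop_end)
    donor_iv = reg.interval(d, d + 2)
    acc_iv = reg.interval(p_acc - 2, p_acc)
    cds = s[a:d] + s[p_acc:stop_end]
    protein = translate(cds)[:-1]
    return GeneModel(
        species=contig.species,
        exons=[exon1_iv, exon2_iv],
        strand=reg.strand,
        cds=cds,
        protein=protein,
        status=COMPLETE_2EXON,
        junction=JunctionDipeptide(protein[k - 1], protein[k]),
        intron_codon_index=k,
        splice_site=SpliceSite(
            donor_pos=donor_iv.start,
            acceptor_pos=acc_iv.start,
            donor_dinuc="GT",
            acceptor_dinuc="AG",
        ),
        atypical_junction=not (soft_lo <= k <= soft_hi),
        score=score,
    )


# ---------------------------------------------------------------------------
# disruption detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Segment:
    frame: int  # local frame offset 0/1/2
    q0: int
    q1: int
    t0: int  # local nt start
    t1: int
    score: float
    aligned: tuple[str, str]  # (target/frame, query/bait)


def _frame_segments(bait: str, prot: str, frame_off: int, min_score: float,
                    q_base: int = 0, t_base: int = 0, depth: int = 0) -> list[_Segment]:
    if len(bait) < 15 or len(prot) < 15 or depth > 2:
        return []
    score, (t_aln, q_aln), t_span, q_span = local_alignment(prot, bait)
    if score < min_score:
        return []
    seg = _Segment(
        frame=frame_off,
        q0=q_base + q_span[0],
        q1=q_base + q_span[1],
        t0=t_base + frame_off + 3 * t_span[0],
        t1=t_base + frame_off + 3 * t_span[1],
        score=score,
        aligned=(t_aln, q_aln),
    )
    out = [seg]
    out += _frame_segments(bait[: q_span[0]], prot[: t_span[0]], frame_off,
                           min_score, q_base, t_base, depth + 1)
    out += _frame_segments(bait[q_span[1] :], prot[t_span[1] :], frame_off,
                           min_score, q_base + q_span[1],
                           t_base + 3 * t_span[1], depth + 1)
    return out


def _collect_segments(reg: _Region, bait: str, config: ModelConfig) -> list[_Segment]:
    segments: list[_Segment] = []
    s = reg.s
    for off in range(3):
        n = (len(s) - off) // 3
        if n < 15:
            continue
        prot = translate(s[off : off + 3 * n])
        segments += _frame_segments(bait, prot, off, config.min_segment_score)
    segments.sort(key=lambda g: (g.q0, g.t0))
    return segments


def _stops_in_segment(seg: _Segment, edge_trim: int = 15) -> list[Disruption]:
    """Stop codons aligned inside the segment body (borders are noisy)."""
    out = []
    t_aln, q_aln = seg.aligned
    ncol = len(t_aln)
    qpos = seg.q0
    for col, (tc, qc) in enumerate(zip(t_aln, q_aln)):
        if tc == "*" and edge_trim <= col < ncol - edge_trim:
            out.append(Disruption("in_frame_stop", qpos + 1, detail="stop codon"))
        if qc != "-":
            qpos += 1
    return out


def detect_disruptions(locus: Locus, bait: ProteinSeq, contig: Contig,
                       config: ModelConfig = ModelConfig(),
                       mask: list[GenomicInterval] | None = None):
    """Frameshift / in-frame-stop evidence from the bait–locus alignment.

    Returns ``(disruptions, chain_score, extent)`` where ``chain_score`` is
    the summed score of the best adjacency-connected alignment chain (the
    "disrupted gene" interpretation) and ``extent`` is a dict with the local
    and bait coordinate span of all alignment evidence, used for edge /
    fragment classification.
    """
    reg = _Region(contig, locus, config.flank, mask)
    segments = _collect_segments(reg, bait.seq, config)
    if not segments:
        return [], 0.0, None

    # chain adjacency-connected segments in genomic order (frameshift
    # bridges); an intron-sized forward gap or a bait-coordinate jump breaks
    # the chain.  Segments of a frameshifted gene may overlap in both
    # coordinates, since each frame aligns a little past the break.
    segments = sorted(segments, key=lambda g: (g.t0, g.t1))
    chains: list[list[_Segment]] = [[segments[0]]]
    for seg in segments[1:]:
        prev = chains[-1][-1]
        q_gap = seg.q0 - prev.q1
        t_gap = seg.t0 - prev.t1
        q_overlap = max(0, -q_gap)
        if -120 <= q_gap <= 25 and -(3 * q_overlap + 60) <= t_gap <= max(
            config.max_bridge_gap, 3 * max(q_gap, 0) + config.max_bridge_gap
        ):
            chains[-1].append(seg)
        else:
            chains.append([seg])

    # the best-scoring chain is the "disrupted gene" interpretation; other
    # chains are unrelated flanking matches and contribute no evidence
    best_chain = max(chains, key=lambda c: sum(g.score for g in c))
    chain_score = sum(g.score for g in best_chain)

    disruptions: list[Disruption] = []
    for seg in best_chain:
        disruptions.extend(_stops_in_segment(seg))
    for prev, seg in zip(best_chain, best_chain[1:]):
        if seg.frame != prev.frame:
            shift = (seg.frame - prev.frame) % 3
            disruptions.append(
                Disruption("frameshift", prev.q1,
                           detail=f"+{shift} nt frame change")
            )

    extent = {
        "t_min": min(g.t0 for g in best_chain),
        "t_max": max(g.t1 for g in best_chain),
        "q_min": min(g.q0 for g in best_chain),
        "q_max": max(g.q1 for g in best_chain),
        "region": reg,
    }
    # deduplicate stops reported twice by overlapping recursion windows
    seen = set()
    uniq = []
    for d in sorted(disruptions, key=lambda d: d.position):
        key = (d.kind, d.position // 3)
        if key not in seen:
            seen.add(key)
            uniq.append(d)
    return uniq, chain_score, extent


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_status(locus: Locus, model: GeneModel | None,
                    disruptions: list[Disruption], contig: Contig,
                    extent=None, bait: ProteinSeq | None = None,
                    config: ModelConfig = ModelConfig()) -> tuple[str, str]:
    """Resolve the locus status per the complete/pseudo/edge/fragment rules."""
    if model is not None and model.is_complete:
        return model.status, "none"
    near_up = near_down = False
    missing_n = missing_c = False
    if extent is not None:
        reg: _Region = extent["region"]
        near_up = extent["t_min"] - reg.upstream_bound <= config.edge_margin
        near_down = reg.downstream_bound - extent["t_max"] <= config.edge_margin
        if bait is not None:
            missing_n = extent["q_min"] >= 15
            missing_c = extent["q_max"] <= len(bait) - 15
    at_edge = (near_up and missing_n) or (near_down and missing_c)
    if disruptions and not at_edge:
        kinds = {d.kind for d in disruptions}
        if kinds == {"frameshift"}:
            return PSEUDOGENE, "frameshift"
        if kinds == {"in_frame_stop"}:
            return PSEUDOGENE, "in_frame_stop"
        return PSEUDOGENE, "both"
    if at_edge:
        return EDGE, "none"
    return FRAGMENT, "none"


def split_into_gene_groups(locus: Locus, gap: int = 800) -> list[Locus]:
    """Split a locus into per-gene hit groups (tandem genes merge at the
    locus stage; their retained hits sit farther apart than one gene's own
    alignment segments)."""
    from .translated_search import merge_hits

    if len(locus.hits) <= 1:
        return [locus]
    return merge_hits(locus.hits, gap)


def reconstruct_locus(locus: Locus, baits_by_id: dict[str, ProteinSeq],
                      contig: Contig,
                      config: ModelConfig = ModelConfig(),
                      mask: list[GenomicInterval] | None = None) -> GeneModel | None:
    """Per-locus reconstruction: model inference + status adjudication.

    The three interpretations — contiguous ATG→stop ORF, junction-colinear
    spliced model, and disrupted-gene alignment chain — compete on their
    bait alignment score (with a small tolerance favouring complete
    models); loci where the chain wins are classified pseudogene / edge /
    fragment.
    """
    hit = locus.best_positive
    if hit is None:
        return None
    bait = baits_by_id[hit.bait_id]

    m1 = build_single_exon_model(locus, contig, config, mask)
    s1 = -math.inf
    m1_coverage = 0.0
    if m1 is not None:
        s1, _, _, q_span = local_alignment(m1.protein, bait.seq)
        m1_coverage = (q_span[1] - q_span[0]) / len(bait)
    m2 = infer_spliced_model(locus, bait, contig, config, mask)
    s2 = m2.score if m2 else -math.inf
    disruptions, chain_score, extent = detect_disruptions(
        locus, bait, contig, config, mask
    )

    if m2 is not None and s2 >= max(chain_score + 20.0, s1 + 15.0):
        return m2
    if (m1 is not None and s1 >= chain_score - 10.0
            and m1_coverage >= config.min_bait_coverage):
        m1.score = s1
        return m1
    if extent is None:
        return None

    status, pseudo_type = classify_status(
        locus, None, disruptions, contig, extent, bait, config
    )
    reg: _Region = extent["region"]
    t0 = max(0, extent["t_min"])
    t1 = min(len(reg.s), extent["t_max"])
    t1 -= (t1 - t0) % 3
    cds = reg.s[t0:t1]
    return GeneModel(
        species=contig.species,
        exons=[reg.interval(t0, t1)],
        strand=reg.strand,
        cds=cds,
        protein=translate(cds) if cds else "",
        status=status,
        pseudo_type=pseudo_type,
        disruptions=disruptions,
    )


# ---------------------------------------------------------------------------
# naming, censuses, adjacency
# ---------------------------------------------------------------------------

def name_gene(species: str, status: str, family: str, index: int) -> str:
    """Paper-style gene name, e.g. BriTARe.A005 (edge gene 005, family A)."""
    if not 1 <= index <= 999:
        raise ValueError(f"gene index {index} outside 1–999")
    if not (len(family) == 1 and family.isalpha() and family.isupper()):
        raise ValueError(f"family must be a single capital letter, got {family!r}")
    try:
        letter = STATUS_LETTER[status]
    except KeyError:
        raise ValueError(f"unknown status {status!r}") from None
    return f"{species}TAR{letter}.{family}{index:03d}"


def junction_census(models: list[GeneModel]):
    """Splice-junction dipeptide counts, per species and pooled.

    Returns ``(pooled, per_species, aromatic_basic_fraction)``; only
    two-exon models are counted.
    """
    pooled: Counter = Counter()
    per_species: dict[str, Counter] = defaultdict(Counter)
    n = arobasic = 0
    for m in models:
        if m.status != COMPLETE_2EXON or m.junction is None:
            continue
        dip = str(m.junction)
        pooled[dip] += 1
        per_species[m.species][dip] += 1
        n += 1
        arobasic += m.junction.aromatic_basic
    frac = arobasic / n if n else float("nan")
    return dict(pooled), {k: dict(v) for k, v in per_species.items()}, frac


def adjacency_report(models: list[GeneModel]):
    """Orientation pattern and intergenic distance for same-contig gene pairs."""
    by_contig: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        by_contig[m.contig_id].append(m)
    rows = []
    for cid in sorted(by_contig):
        genes = sorted(by_contig[cid], key=lambda m: m.start)
        for g1, g2 in zip(genes, genes[1:]):
            if g1.strand == g2.strand:
                pattern = "tail-to-head"
            elif (g1.strand, g2.strand) == ("+", "-"):
                pattern = "tail-to-tail"
            else:
                pattern = "head-to-head"
            dist = g2.start - g1.end
            rows.append({
                "contig": cid,
                "gene1": g1.name or f"{g1.contig_id}:{g1.start}",
                "gene2": g2.name or f"{g2.contig_id}:{g2.start}",
                "orientation": pattern,
                "distance_nt": max(dist, 0),
                "overlapping": dist < 0,
            })
    return rows
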