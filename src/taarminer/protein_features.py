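"""Structural annotation of receptor proteins.

Kyte–Doolittle hydropathy segmentation approximates the seven-transmembrane
architecture; the N-glycosylation sequon grammar (Asn-X-Ser/Thr, X != Pro)
is scanned without any neural "potential" scoring; conserved motifs are
found as maximum-information ungapped windows of the repertoire alignment;
splice-site logos are position frequency matrices over fixed windows around
the donor (last 3 exon nt + first 6 intron nt) and acceptor (last 12 intron
nt + first 3 exon nt).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np

from .seq_core import Contig, ProteinSeq, reverse_complement
from .gene_models import COMPLETE_2EXON, GeneModel

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0, "*": 0.0,
}

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}
DNA4 = "ACGT"

SEQUON_RE = re.compile(r"N[^P][ST]")


@dataclass(frozen=True)
class TMSegment:
    start: int
    end: int
    mean_hydropathy: float

    @property
    def canonical(self) -> bool:
        """Within the 21–28 residue band reported for TAAR TM helices."""
        return 21 <= self.end - self.start <= 28


@dataclass(frozen=True)
class Sequon:
    position: int
    triplet: str


@dataclass(frozen=True)
class MotifModel:
    start: int  # alignment column
    width: int
    pwm: np.ndarray  # width x 20 frequencies
    ic: np.ndarray  # bits per column
    consensus: str

    @property
    def mean_ic(self) -> float:
        return float(self.ic.mean())


@dataclass(frozen=True)
class SpliceLogo:
    side: str  # donor | acceptor
    pfm: np.ndarray  # window x 4 frequencies
    ic: np.ndarray
    consensus: str


def tm_segments(protein: ProteinSeq | str, window: int = 19,
                threshold: float = 1.5, merge_gap: int = 5,
                length_band: tuple[int, int] = (17, 35)) -> list[TMSegment]:
    """Maximal hydrophobic runs of the windowed Kyte–Doolittle mean."""
    seq = protein.seq if isinstance(protein, ProteinSeq) else protein
    if len(seq) <= window:
        warnings.warn("protein shorter than hydropathy window; no segments")
        return []
    vals = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in seq])
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    hot = means >= threshold  # hot[i]: window starting at residue i
    runs: list[list[int]] = []
    for i in np.flatnonzero(hot):
        if runs and i - runs[-1][-1] < merge_gap:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    lo, hi = length_band
    out = []
    for run in runs:
        # union of the above-threshold windows, trimmed to the length band
        start, end = run[0], min(len(seq), run[-1] + window)
        if end - start > hi:
            excess = end - start - hi
            start += excess // 2
            end -= excess - excess // 2
        if end - start < lo:
            continue
        out.append(TMSegment(start, end, float(np.mean(vals[start:end]))))
    return out


def sequon_scan(protein: ProteinSeq | str,
                n_terminal_window: int | None = None) -> list[Sequon]:
    """All N-X-[S/T] sequons (X != P); overlaps allowed."""
    seq = protein.seq if isinstance(protein, ProteinSeq) else protein
    limit = len(seq) if n_terminal_window is None else min(len(seq), n_terminal_window)
    out = []
    for i in range(limit - 2):
        if SEQUON_RE.match(seq, i):
            out.append(Sequon(position=i, triplet=seq[i : i + 3]))
    return out


def stack_alignment(proteins: list[str]) -> list[str]:
    """Reference-threaded multiple alignment of near-colinear proteins.

    Each sequence is globally aligned to a reference of the most common
    input length (robust against a stray outlier); residues are threaded
    onto the reference's columns and insertions relative to the reference
    are dropped.  Adequate for repertoires of receptor homologs (which
    share a common backbone); not a general-purpose MSA.
    """
    from collections import Counter

    from ._align import global_alignment

    if not proteins:
        return []
    modal_len = Counter(len(p) for p in proteins).most_common(1)[0][0]
    ref = next(p for p in proteins if len(p) == modal_len)
    ncol = len(ref)
    rows = []
    for seq in proteins:
        if seq == ref:
            rows.append(ref)
            continue
        _, ra, rs = global_alignment(ref, seq)
        row = []
        for x, y in zip(ra, rs):
            if x != "-":
                row.append(y if y != "-" else "-")
        rows.append("".join(row).ljust(ncol, "-")[:ncol])
    return rows


def _column_profile(column: list[str]) -> tuple[np.ndarray, float]:
    """(frequency vector over 20 aa, non-gap fraction) for one MSA column."""
    counts = np.zeros(20)
    nongap = 0
    for a in column:
        idx = _AA_INDEX.get(a)
        if idx is not None:
            counts[idx] += 1
            nongap += 1
    if nongap == 0:
        return counts, 0.0
    return counts / nongap, nongap / len(column)


def conserved_motifs(alignment: list[str], k: int = 5,
                     width_range: tuple[int, int] = (6, 15)) -> list[MotifModel]:
    """Top-k non-overlapping maximum-information ungapped alignment windows.

    Column score = information content (log2 20 - entropy) scaled by the
    non-gap fraction, so gappy columns are penalised.  Deterministic.
    """
    if len(alignment) < 5:
        raise ValueError("motif discovery needs at least 5 aligned sequences")
    ncol = len(alignment[0])
    if any(len(s) != ncol for s in alignment):
        raise ValueError("alignment rows must have equal length")
    profiles = []
    scores = np.zeros(ncol)
    max_ic = math.log2(20)
    for c in range(ncol):
        freqs, nongap = _column_profile([s[c] for s in alignment])
        ent = -sum(f * math.log2(f) for f in freqs if f > 0)
        ic = (max_ic - ent) if nongap else 0.0
        profiles.append((freqs, ic))
        scores[c] = ic * nongap
    lo, hi = width_range
    candidates = []
    for w in range(lo, min(hi, ncol) + 1):
        window_means = np.convolve(scores, np.ones(w) / w, mode="valid")
        for start in range(len(window_means)):
            candidates.append((float(window_means[start]), w, start))
    candidates.sort(key=lambda c: (-c[0], c[2], c[1]))
    chosen: list[tuple[int, int]] = []
    motifs: list[MotifModel] = []
    for _, w, start in candidates:
        if len(motifs) >= k:
            break
        if any(start < e and s < start + w for s, e in chosen):
            continue
        chosen.append((start, start + w))
        pwm = np.array([profiles[c][0] for c in range(start, start + w)])
        ic = np.array([profiles[c][1] for c in range(start, start + w)])
        consensus = "".join(AA20[int(np.argmax(row))] if row.sum() else "-" for row in pwm)
        motifs.append(MotifModel(start=start, width=w, pwm=pwm, ic=ic,
                                 consensus=consensus))
    motifs.sort(key=lambda m: -m.mean_ic)
    return motifs


DONOR_EXON_NT = 3
DONOR_INTRON_NT = 6
ACCEPTOR_INTRON_NT = 12
ACCEPTOR_EXON_NT = 3


def _splice_windows(model: GeneModel, contigs: dict[str, Contig]) -> tuple[str, str]:
    """(donor window, acceptor window) in transcript orientation."""
    contig = contigs[model.contig_id]
    e1, e2 = model.exons  # transcription order
    if model.strand == "+":
        donor = contig.seq[e1.end - DONOR_EXON_NT : e1.end + DONOR_INTRON_NT]
        acceptor = contig.seq[e2.start - ACCEPTOR_INTRON_NT : e2.start + ACCEPTOR_EXON_NT]
    else:
        donor = reverse_complement(
            contig.seq[e1.start - DONOR_INTRON_NT : e1.start + DONOR_EXON_NT]
        )
        acceptor = reverse_complement(
            contig.seq[e2.end - ACCEPTOR_EXON_NT : e2.end + ACCEPTOR_INTRON_NT]
        )
    return donor, acceptor


def _logo(side: str, windows: list[str]) -> SpliceLogo:
    width = DONOR_EXON_NT + DONOR_INTRON_NT if side == "donor" else \
        ACCEPTOR_INTRON_NT + ACCEPTOR_EXON_NT
    counts = np.zeros((width, 4))
    for w in windows:
        for i, b in enumerate(w[:width]):
            j = DNA4.find(b)
            if j >= 0:
                counts[i, j] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1
    pfm = counts / totals
    ic = np.array([
        2.0 + sum(f * math.log2(f) for f in row if f > 0) for row in pfm
    ])
    consensus = "".join(DNA4[int(np.argmax(row))] for row in pfm)
    return SpliceLogo(side=side, pfm=pfm, ic=ic, consensus=consensus)


def splice_logo(models: list[GeneModel],
                contigs: dict[str, Contig]) -> tuple[SpliceLogo, SpliceLogo]:
    """Donor and acceptor PFM logos over all two-exon models."""
    spliced = [m for m in models if m.status == COMPLETE_2EXON]
    if not spliced:
        raise ValueError("no two-exon models; cannot build splice logos")
    donors, acceptors = [], []
    for m in spliced:
        d, a = _splice_windows(m, contigs)
        donors.append(d)
        acceptors.append(a)
    return _logo("donor", donors), _logo("acceptor", acceptors)
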