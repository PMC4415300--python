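"""Pairwise dN/dS by Nei–Gojobori counting with Zhang's transition/transversion
site weighting.

Synonymous site fractions per codon position weight each of the three
alternative bases by R when the change is a transition and by 1 when it is a
transversion; R = 1 reduces to the unmodified NG86 fractions.  Observed
differences are averaged over all mutational pathways between the two
codons; pathways through stop codons are excluded (with renormalisation) by
default.  Proportions are corrected for multiple hits with Jukes–Cantor,
d = -(3/4)·ln(1 - 4p/3), and omega = dN/dS.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from ._align import global_alignment
from .seq_core import CODON_TABLE, STOP_CODONS

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

OMEGA_UNBOUNDED = "omega_unbounded"
OMEGA_ZERO_ZERO = "omega_zero_zero"
JC_UNDEFINED = "jc_undefined"


def is_transition(b1: str, b2: str) -> bool:
    return (b1 in PURINES and b2 in PURINES) or (b1 in PYRIMIDINES and b2 in PYRIMIDINES)


@dataclass(frozen=True)
class DnDsConfig:
    #: transition/transversion weight in site counting; 1.0 = plain NG86
    R: float = 1.0
    stop_pathways: str = "exclude"  # exclude | count
    max_p: float = 0.749999  # JC correction domain guard

    def __post_init__(self):
        if self.R < 0:
            raise ValueError("R must be non-negative")
        if self.stop_pathways not in ("exclude", "count"):
            raise ValueError("stop_pathways must be 'exclude' or 'count'")


@dataclass(frozen=True)
class CodonSiteCounts:
    s: float
    n: float


@dataclass(frozen=True)
class DnDsRecord:
    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float  # nan when flagged unbounded/zero-zero/undefined
    flags: frozenset = frozenset()
    codons: int = 0

    @property
    def omega_text(self) -> str:
        """Table convention: unbounded ratios print as '>10'."""
        if OMEGA_UNBOUNDED in self.flags:
            return ">10"
        if OMEGA_ZERO_ZERO in self.flags or math.isnan(self.omega):
            return "NA"
        return f"{self.omega:.3f}"


@lru_cache(maxsize=4096)
def _site_counts(codon: str, R: float) -> tuple[float, float]:
    if len(codon) != 3 or codon in STOP_CODONS or any(b not in "ACGT" for b in codon):
        raise ValueError(f"codon_site_counts needs a sense codon, got {codon!r}")
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn_w = tot_w = 0.0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            w = R if is_transition(codon[pos], b) else 1.0
            tot_w += w
            # changes to stop codons count as nonsynonymous
            if mut not in STOP_CODONS and CODON_TABLE[mut] == aa:
                syn_w += w
        s += syn_w / tot_w
    return s, 3.0 - s


def codon_site_counts(codon: str, R: float = 1.0) -> CodonSiteCounts:
    """Weighted synonymous/nonsynonymous site fractions of one codon."""
    s, n = _site_counts(codon, R)
    return CodonSiteCounts(s=s, n=n)


@lru_cache(maxsize=65536)
def _pathway_differences(c1: str, c2: str, stop_pathways: str) -> tuple[float, float]:
    for c in (c1, c2):
        if len(c) != 3 or c in STOP_CODONS or any(b not in "ACGT" for b in c):
            raise ValueError(f"pathway_differences needs sense codons, got {c!r}")
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd_tot = nd_tot = 0.0
    n_valid = 0
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and stop_pathways == "exclude" and nxt != c2:
                valid = False
                break
            if nxt in STOP_CODONS:
                nd += 1.0  # counted pathway through/to a stop: nonsynonymous step
            elif CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if valid:
            sd_tot += sd
            nd_tot += nd
            n_valid += 1
    if n_valid == 0:
        # all pathways pass through stops: fall back to counting them
        return _pathway_differences(c1, c2, "count")
    return sd_tot / n_valid, nd_tot / n_valid


def pathway_differences(codon1: str, codon2: str,
                        config: DnDsConfig = DnDsConfig()) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences averaged over mutational pathways."""
    return _pathway_differences(codon1, codon2, config.stop_pathways)


def jukes_cantor(p: float, max_p: float = 0.749999) -> tuple[float, bool]:
    """JC-corrected distance and a flag for p outside the correction domain."""
    if p >= max_p:
        return float("nan"), True
    if p <= 0:
        return 0.0, False
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def ng86_pair(cds1: str, cds2: str, config: DnDsConfig = DnDsConfig(),
              pair: tuple[str, str] = ("seq1", "seq2")) -> DnDsRecord:
    """dN/dS for a gap-free, codon-aligned CDS pair (no internal stops)."""
    if len(cds1) != len(cds2):
        raise ValueError("sequences must have equal length")
    if len(cds1) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    S1 = S2 = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(cds1), 3):
        c1, c2 = cds1[i : i + 3], cds2[i : i + 3]
        if "N" in c1 or "N" in c2 or "-" in c1 or "-" in c2:
            continue
        s1, _ = _site_counts(c1, config.R)
        s2, _ = _site_counts(c2, config.R)
        S1 += s1
        S2 += s2
        sd, nd = _pathway_differences(c1, c2, config.stop_pathways)
        Sd += sd
        Nd += nd
        n_codons += 1
    S = (S1 + S2) / 2.0
    N = 3.0 * n_codons - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    flags = set()
    dS, badS = jukes_cantor(pS, config.max_p)
    dN, badN = jukes_cantor(pN, config.max_p)
    if badS or badN:
        flags.add(JC_UNDEFINED)
    omega = float("nan")
    if not (badS or badN):
        if dS > 0:
            omega = dN / dS
        elif dN > 0:
            flags.add(OMEGA_UNBOUNDED)
        else:
            flags.add(OMEGA_ZERO_ZERO)
    return DnDsRecord(
        pair=pair, S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=dS, dN=dN, omega=omega, flags=frozenset(flags), codons=n_codons,
    )


def codon_align(cds1: str, cds2: str) -> tuple[str, str]:
    """Codon-aligned, gap-free CDS pair back-threaded from the protein alignment.

    Terminal stop codons are stripped; codon columns opposite a protein gap
    are dropped from both sequences.
    """
    def strip_stop(cds: str) -> str:
        if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
            return cds[:-3]
        return cds

    cds1, cds2 = strip_stop(cds1), strip_stop(cds2)
    from .seq_core import translate
    p1, p2 = translate(cds1), translate(cds2)
    _, a1, a2 = global_alignment(p1, p2)
    out1, out2 = [], []
    i = j = 0
    for x, y in zip(a1, a2):
        if x != "-" and y != "-":
            out1.append(cds1[3 * i : 3 * i + 3])
            out2.append(cds2[3 * j : 3 * j + 3])
        if x != "-":
            i += 1
        if y != "-":
            j += 1
    return "".join(out1), "".join(out2)


def dnds_for_pairs(cds_by_gene: dict[str, str], pairs,
                   config: DnDsConfig = DnDsConfig()) -> list[DnDsRecord]:
    records = []
    for g1, g2 in pairs:
        c1, c2 = codon_align(cds_by_gene[g1], cds_by_gene[g2])
        records.append(ng86_pair(c1, c2, config, pair=(g1, g2)))
    return records


def family_summary(records: list[DnDsRecord],
                   family_of: dict[str, str]) -> pd.DataFrame:
    """Mean/min/max of finite omegas per family; unbounded counted separately."""
    rows = []
    by_family: dict[str, list[DnDsRecord]] = {}
    for r in records:
        f1, f2 = family_of.get(r.pair[0]), family_of.get(r.pair[1])
        if f1 is None or f1 != f2:
            continue
        by_family.setdefault(f1, []).append(r)
    for fam in sorted(by_family):
        recs = by_family[fam]
        finite = [r.omega for r in recs if not math.isnan(r.omega)]
        unbounded = sum(OMEGA_UNBOUNDED in r.flags for r in recs)
        rows.append({
            "family": fam,
            "n_pairs": len(recs),
            "mean": float(np.mean(finite)) if finite else float("nan"),
            "min": float(np.min(finite)) if finite else float("nan"),
            "max": float(np.max(finite)) if finite else float("nan"),
            "n_unbounded": unbounded,
        })
    return pd.DataFrame(rows)


def intra_inter_summary(records: list[DnDsRecord],
                        species_of: dict[str, str],
                        family_of: dict[str, str]) -> pd.DataFrame:
    """Mean omega for same-species vs cross-species pairs, per species+family."""
    rows = []
    fams = sorted({f for f in family_of.values()})
    species = sorted({s for s in species_of.values()})
    for fam in fams:
        for sp in species:
            intra, inter = [], []
            for r in records:
                g1, g2 = r.pair
                if family_of.get(g1) != fam or family_of.get(g2) != fam:
                    continue
                if math.isnan(r.omega):
                    continue
                s1, s2 = species_of[g1], species_of[g2]
                if sp not in (s1, s2):
                    continue
                if s1 == s2 == sp:
                    intra.append(r.omega)
                elif sp in (s1, s2) and s1 != s2:
                    inter.append(r.omega)
            rows.append({
                "family": fam,
                "species": sp,
                "intra_mean": float(np.mean(intra)) if intra else float("nan"),
                "intra_n": len(intra),
                "inter_mean": float(np.mean(inter)) if inter else float("nan"),
                "inter_n": len(inter),
            })
    return pd.DataFrame(rows)
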