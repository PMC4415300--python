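"""Synthetic genome assemblies with planted receptor repertoires and truth.

The generator emulates the structures the mining pipeline must detect:
contigs carrying single-exon and two-exon receptor genes with canonical
phase-0 GT–AG introns near codon 55 and aromatic–basic junction dipeptides,
frameshift/stop pseudogenes, contig-boundary edge genes, internal fragments
and decoy (non-target GPCR-like) genes; family/subfamily structure arises
from controlled-identity divergence of ancestor coding sequences under a
codon-level accept/reject mutation process whose nonsynonymous acceptance
probability is the planted omega.

Every planted feature is recorded in a truth table against which recovery
is scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_core import (
    CODON_TABLE,
    Contig,
    ProteinSeq,
    STOP_CODONS,
    reverse_complement,
    translate,
)
from .translated_search import Bait

SENSE_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_CODONS_FOR = {}
for _c, _a in CODON_TABLE.items():
    _CODONS_FOR.setdefault(_a, []).append(_c)
for _a in _CODONS_FOR:
    _CODONS_FOR[_a].sort()


@dataclass(frozen=True)
class SubfamilyPlan:
    spliced: bool
    genes_per_species: int


@dataclass(frozen=True)
class FamilyPlan:
    name: str
    omega: float
    subfamilies: tuple[SubfamilyPlan, ...]


DEFAULT_FAMILIES = (
    FamilyPlan("A", 0.4, (
        SubfamilyPlan(True, 4), SubfamilyPlan(True, 4), SubfamilyPlan(True, 4),
        SubfamilyPlan(True, 4), SubfamilyPlan(False, 4),
    )),
    FamilyPlan("B", 0.5, (
        SubfamilyPlan(True, 3), SubfamilyPlan(False, 2),
    )),
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic repertoires (defaults are the
    conditions exercised throughout the test suite)."""

    seed: int = 0
    species: tuple[str, ...] = ("Til", "Bur", "Nye", "Bri", "Zeb")
    families: tuple[FamilyPlan, ...] = DEFAULT_FAMILIES
    # per-species counts of non-complete plants
    n_pseudogene_frameshift: int = 3
    n_pseudogene_stop: int = 2
    n_edge: int = 4
    n_fragment: int = 3
    n_decoy: int = 5
    n_decoy_ancestors: int = 3
    # protein length of the shared ancestor (codons, excluding stop)
    protein_length: tuple[int, int] = (305, 340)
    #: codon windows (0-based, half-open) frozen during receptor-family
    #: evolution — the planted conserved motifs; kept clear of the splice
    #: junction window (codons 40–80)
    motif_windows: tuple[tuple[int, int], ...] = (
        (10, 16), (100, 106), (150, 156), (210, 216), (270, 276),
    )
    # percent protein identity targets of each divergence step
    gene_vs_subfamily: float = 87.0
    subfamily_vs_family: float = 78.0
    #: deep between-family divergence: cross-family identity rests on the
    #: conserved-motif and shared-architecture floor (~30-35%), safely
    #: below the 40% family threshold even in the single-linkage tail
    family_vs_root: float = 45.0
    bait_vs_subfamily: float = 85.0
    decoy_vs_ancestor: float = 80.0
    # intron geometry: length range and position (codon after which it falls)
    intron_length: tuple[int, int] = (70, 3000)
    intron_codon_mean: float = 55.0
    intron_codon_sd: float = 8.0
    intron_codon_window: tuple[int, int] = (40, 80)
    # junction dipeptide mixture (FE stands in for the rarer exceptions)
    junction_mix: tuple[tuple[str, float], ...] = (
        ("FR", 0.79), ("FK", 0.14), ("YR", 0.04), ("FE", 0.03),
    )
    ortholog_pairs: int = 4
    ortholog_triplets: int = 2
    ortholog_identity: float = 99.4
    #: per-member divergence of triplet copies; tight enough that every
    #: within-triplet pair stays above the 99% ortholog threshold at any
    #: ancestor length in the configured range
    triplet_identity: float = 99.75
    tstv: float = 1.0
    gc: float = 0.42
    contig_length_median: float = 25000.0
    contig_length_sigma: float = 0.45
    edge_keep: tuple[float, float] = (0.5, 0.7)
    fragment_keep: tuple[float, float] = (0.5, 0.65)
    intergenic: tuple[int, int] = (1200, 6100)
    n_gene_clusters: int = 4  # tail-to-head gene pairs per species

    def complete_counts(self) -> tuple[int, int]:
        one = two = 0
        for fam in self.families:
            for sub in fam.subfamilies:
                if sub.spliced:
                    two += sub.genes_per_species
                else:
                    one += sub.genes_per_species
        return one, two


@dataclass
class SyntheticRepertoire:
    config: SynthConfig
    contigs: dict[str, list[Contig]]  # species -> contigs
    positive_baits: list[Bait]
    negative_baits: list[Bait]
    truth: pd.DataFrame

    def all_contigs(self) -> list[Contig]:
        return [c for group in self.contigs.values() for c in group]

    def write(self, outdir) -> None:
        import os
        from .seq_core import write_fasta
        os.makedirs(outdir, exist_ok=True)
        for sp, ctgs in self.contigs.items():
            write_fasta([(c.id, c.seq) for c in ctgs],
                        os.path.join(outdir, f"{sp}_assembly.fasta"))
        write_fasta([(b.id, b.protein.seq) for b in self.positive_baits],
                    os.path.join(outdir, "baits_positive.fasta"))
        write_fasta([(b.id, b.protein.seq) for b in self.negative_baits],
                    os.path.join(outdir, "baits_negative.fasta"))
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutation machinery
# ---------------------------------------------------------------------------

def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random sense-codon CDS starting with ATG (no terminal stop)."""
    codons = ["ATG"] + [SENSE_CODONS[i] for i in
                        rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)]
    return "".join(codons)


HYDROPHOBIC_AA = "AILMFVC"  # Kyte-Doolittle >= 1.8 throughout
LOOP_AA = "DENKRQHSTGPWY"


def _draw_codon(rng: np.random.Generator, pool: str) -> str:
    aa = pool[int(rng.integers(0, len(pool)))]
    choices = _CODONS_FOR[aa]
    return choices[int(rng.integers(0, len(choices)))]


def receptor_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS with a seven-transmembrane receptor architecture.

    Seven hydrophobic stretches of 21–28 codons separated by hydrophilic
    loops, an extracellular N-terminus carrying an N-glycosylation sequon
    (Asn-Gly-Ser) near the start, and a C-terminal tail; total length is
    padded/trimmed to ``n_codons``.
    """
    segments: list[str] = []
    # N-terminus with a sequon at protein position 4
    nterm = ["ATG"] + [_draw_codon(rng, LOOP_AA) for _ in range(3)]
    nterm += [_CODONS_FOR["N"][int(rng.integers(0, 2))], "GGC",
              _CODONS_FOR["S"][int(rng.integers(0, 6))]]
    nterm += [_draw_codon(rng, LOOP_AA) for _ in range(13)]
    segments.append("".join(nterm))
    tm_lengths = rng.integers(21, 29, size=7)
    loop_lengths = rng.integers(9, 15, size=6)
    for i in range(7):
        segments.append("".join(_draw_codon(rng, HYDROPHOBIC_AA)
                                for _ in range(tm_lengths[i])))
        if i < 6:
            segments.append("".join(_draw_codon(rng, LOOP_AA)
                                    for _ in range(loop_lengths[i])))
    cds = "".join(segments)
    used = len(cds) // 3
    if used < n_codons:  # C-terminal tail
        cds += "".join(_draw_codon(rng, LOOP_AA + "AILMFVWYC")
                       for _ in range(n_codons - used))
    return cds[: 3 * n_codons]


def _propose_base(rng: np.random.Generator, base: str, tstv: float) -> str:
    others = [b for b in "ACGT" if b != base]
    weights = np.array([tstv if b == _TRANSITION[base] else 1.0 for b in others])
    return others[rng.choice(3, p=weights / weights.sum())]


def evolve_to_identity(cds: str, target_identity: float, omega: float,
                       tstv: float, rng: np.random.Generator,
                       frozen: tuple[tuple[int, int], ...] = (),
                       max_steps_factor: int = 400) -> str:
    """Diverge a CDS until its protein identity to the input drops to target.

    Point mutations are proposed uniformly over positions (the start codon
    and any ``frozen`` codon windows are immutable); proposals creating
    stop codons are rejected; synonymous proposals are always accepted and
    nonsynonymous ones with probability ``omega``.  Realized identity lands
    within one residue of the target.

    With ``omega == 0`` the protein cannot change, so the target is applied
    to nucleotide identity instead (purely synonymous divergence).
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must lie in (0, 100]")
    seq = list(cds)
    n_codons = len(cds) // 3
    orig = [CODON_TABLE["".join(seq[3 * i : 3 * i + 3])] for i in range(n_codons)]
    orig_nt = list(cds)
    nt_mode = omega == 0.0
    diffs = 0
    units = len(cds) if nt_mode else n_codons
    limit = (100.0 - target_identity) / 100.0 * units
    max_steps = max_steps_factor * len(cds)
    steps = 0
    while diffs < limit:
        steps += 1
        if steps > max_steps:
            raise RuntimeError(
                f"identity target {target_identity}% unreachable at omega={omega}"
            )
        pos = int(rng.integers(3, len(seq)))  # codon 0 (ATG) frozen
        if any(lo <= pos // 3 < hi for lo, hi in frozen):
            continue
        ci = pos // 3
        codon = seq[3 * ci : 3 * ci + 3]
        new_base = _propose_base(rng, seq[pos], tstv)
        new_codon = codon.copy()
        new_codon[pos % 3] = new_base
        nc = "".join(new_codon)
        if nc in STOP_CODONS:
            continue
        old_aa = CODON_TABLE["".join(codon)]
        new_aa = CODON_TABLE[nc]
        if new_aa != old_aa and rng.random() > omega:
            continue
        if nt_mode:
            was_diff = seq[pos] != orig_nt[pos]
            now_diff = new_base != orig_nt[pos]
        else:
            was_diff = old_aa != orig[ci]
            now_diff = new_aa != orig[ci]
        seq[pos] = new_base
        diffs += int(now_diff) - int(was_diff)
    return "".join(seq)


def pseudogenize(cds: str, kind: str, rng: np.random.Generator) -> tuple[str, str, int]:
    """Disrupt a CDS; returns (mutated sequence, kind, 1-based codon position).

    ``frameshift`` inserts or deletes 1–2 nt at an internal codon boundary;
    ``in_frame_stop`` rewrites one sense codon to TAA/TAG/TGA.  Frameshifts
    that would create a stop codon in the bridge region are re-drawn so the
    planted disruption type stays unambiguous.
    """
    n_codons = len(cds) // 3
    if kind == "in_frame_stop":
        pos = int(rng.integers(40, n_codons - 40))
        stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
        return cds[: 3 * pos] + stop + cds[3 * pos + 3 :], kind, pos + 1
    if kind != "frameshift":
        raise ValueError(f"unknown pseudogene kind {kind!r}")
    for _ in range(100):
        pos = int(rng.integers(40, n_codons - 40))
        k = int(rng.integers(1, 3))
        if rng.random() < 0.5:  # insertion
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
            mutated = cds[: 3 * pos] + ins + cds[3 * pos :]
        else:  # deletion
            mutated = cds[: 3 * pos] + cds[3 * pos + k :]
        bridge = mutated[3 * pos : 3 * pos + 9]
        bridge = bridge[: len(bridge) // 3 * 3]
        if "*" not in translate(bridge):
            return mutated, kind, pos + 1
    raise RuntimeError("could not place a clean frameshift")


def _set_codon(cds: str, codon_index: int, aa: str, rng: np.random.Generator) -> str:
    choices = _CODONS_FOR[aa]
    codon = choices[int(rng.integers(0, len(choices)))]
    i = 3 * codon_index
    return cds[:i] + codon + cds[i + 3 :]


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)]) if n else ""


def make_intron(rng: np.random.Generator, length: int, gc: float) -> str:
    """Canonical GT–AG intron with a donor-consensus-like start and a
    pyrimidine-rich acceptor tail; in-frame AG within 6 nt of the acceptor
    (which would create an ambiguous alternative splice) is rejected."""
    if length < 20:
        raise ValueError("intron too short")
    for _ in range(200):
        # donor-consensus-like start (GTAAGT-ish) with per-position noise
        head = "GT"
        for consensus, p in (("A", 0.7), ("A", 0.7), ("G", 0.8), ("T", 0.5)):
            head += consensus if rng.random() < p else _random_dna(rng, 1, gc)
        tail_py = "".join("CT"[int(rng.random() < 0.5)] if rng.random() < 0.8
                          else _random_dna(rng, 1, gc) for _ in range(9))
        tail = tail_py + ("C" if rng.random() < 0.7 else "T") + "AG"
        mid = _random_dna(rng, length - len(head) - len(tail), gc)
        intron = head + mid + tail
        # reject alternative in-frame acceptors/donors within 6 nt of the
        # true sites (they would create untestable equal-scoring models)
        if intron[-5:-3] == "AG" or intron[-8:-6] == "AG":
            continue
        if intron[3:5] == "GT" or intron[6:8] == "GT":
            continue
        return intron
    raise RuntimeError("could not build an unambiguous intron")


def truncate_to_edge(cds_with_stop: str, side: str, rng: np.random.Generator,
                     keep: tuple[float, float] = (0.3, 0.7)) -> tuple[str, int]:
    """Retain a terminal fraction of a CDS for an edge-gene plant.

    ``side`` 'N' loses the N-terminal part (the kept piece abuts contig
    position 0); 'C' loses the C-terminal part (kept piece abuts the contig
    end).  Returns (kept sequence, kept codon count).
    """
    n_codons = len(cds_with_stop) // 3
    f = rng.uniform(*keep)
    n_keep = int(round(f * n_codons))
    n_keep = min(max(n_keep, 1), n_codons - 1)
    if side == "N":
        return cds_with_stop[3 * (n_codons - n_keep) :], n_keep
    if side == "C":
        return cds_with_stop[: 3 * n_keep], n_keep
    raise ValueError(f"side must be 'N' or 'C', got {side!r}")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class _Plant:
    """One genomic unit to be placed on a contig."""
    name: str
    species: str
    unit: str  # genomic sequence of the unit (gene orientation)
    #: exon spans within the unit, transcription order
    exon_spans: list[tuple[int, int]]
    status: str
    pseudo_type: str = "none"
    intron_codon_index: int | None = None
    junction: str = ""
    family: str = ""
    subfamily: int = 0
    ortholog_group: str = ""
    ancestor: str = ""
    protein: str = ""
    cds: str = ""
    placement: str = "internal"  # internal | edge_start | edge_end


def _draw_junction(rng: np.random.Generator, mix) -> str:
    dips, probs = zip(*mix)
    return dips[int(rng.choice(len(dips), p=np.array(probs) / sum(probs)))]


def _stop(rng) -> str:
    return ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]


def generate(config: SynthConfig = SynthConfig()) -> SyntheticRepertoire:
    """Deterministically generate assemblies, baits and the truth table."""
    rng = np.random.default_rng(config.seed)
    plen = int(rng.integers(*config.protein_length))
    root = receptor_cds(rng, plen)
    frozen = config.motif_windows

    # ancestors and baits -------------------------------------------------
    sub_ancestors: dict[tuple[str, int], str] = {}
    sub_intron: dict[tuple[str, int], int] = {}
    pos_baits: list[Bait] = []
    for fam in config.families:
        fam_anc = evolve_to_identity(root, config.family_vs_root, 1.0,
                                     config.tstv, rng, frozen)
        for si, sub in enumerate(fam.subfamilies, start=1):
            anc = evolve_to_identity(fam_anc, config.subfamily_vs_family,
                                     fam.omega, config.tstv, rng, frozen)
            if sub.spliced:
                k = int(np.clip(round(rng.normal(config.intron_codon_mean,
                                                 config.intron_codon_sd)),
                                *config.intron_codon_window))
                sub_intron[(fam.name, si)] = k
                # the aromatic-basic junction is conserved across the family:
                # the ancestor (and hence the baits) carries the dominant
                # dipeptide; individual genes may redraw it
                anc = _set_codon(anc, k - 1, "F", rng)
                anc = _set_codon(anc, k, "R", rng)
            sub_ancestors[(fam.name, si)] = anc
            bait_cds = evolve_to_identity(anc, config.bait_vs_subfamily, 1.0,
                                          config.tstv, rng, frozen)
            if sub.spliced:
                k = sub_intron[(fam.name, si)]
                bait_cds = _set_codon(bait_cds, k - 1, "F", rng)
                bait_cds = _set_codon(bait_cds, k, "R", rng)
            pos_baits.append(Bait(
                id=f"baitTAAR_{fam.name}{si}", role="positive",
                protein=ProteinSeq(f"baitTAAR_{fam.name}{si}", translate(bait_cds)),
            ))

    decoy_ancestors = [receptor_cds(rng, plen) for _ in range(config.n_decoy_ancestors)]
    neg_baits = [
        Bait(id=f"baitGPCR_{i+1}", role="negative",
             protein=ProteinSeq(f"baitGPCR_{i+1}",
                                translate(evolve_to_identity(a, 90.0, 1.0,
                                                             config.tstv, rng))))
        for i, a in enumerate(decoy_ancestors)
    ]

    # per-species gene plants ---------------------------------------------
    plants: dict[str, list[_Plant]] = {sp: [] for sp in config.species}
    complete_slots: dict[str, list[_Plant]] = {sp: [] for sp in config.species}
    serial = {sp: 0 for sp in config.species}

    def new_name(sp: str) -> str:
        serial[sp] += 1
        return f"{sp}_g{serial[sp]:03d}"

    def build_complete(sp: str, fam: FamilyPlan, si: int, cds: str,
                       ortholog_group: str = "",
                       junction_dip: str | None = None) -> _Plant:
        spliced = (fam.name, si) in sub_intron
        stop = _stop(rng)
        if spliced:
            k = sub_intron[(fam.name, si)]
            dip = junction_dip or _draw_junction(rng, config.junction_mix)
            cds = _set_codon(cds, k - 1, dip[0], rng)
            cds = _set_codon(cds, k, dip[1], rng)
            intron = make_intron(rng, int(rng.integers(*config.intron_length)),
                                 config.gc)
            exon1 = cds[: 3 * k]
            exon2 = cds[3 * k :] + stop
            unit = "TAA" + exon1 + intron + exon2
            spans = [(3, 3 + len(exon1)),
                     (3 + len(exon1) + len(intron), len(unit))]
            status = "complete_2exon"
            prot = translate(cds)
            junction = prot[k - 1] + prot[k]
            intron_idx = k
        else:
            unit = "TAA" + cds + stop
            spans = [(3, len(unit))]
            status = "complete_1exon"
            junction = ""
            intron_idx = None
            prot = translate(cds)
        return _Plant(
            name=new_name(sp), species=sp, unit=unit, exon_spans=spans,
            status=status, intron_codon_index=intron_idx, junction=junction,
            family=fam.name, subfamily=si, ortholog_group=ortholog_group,
            ancestor=f"{fam.name}{si}", protein=prot, cds=cds + stop,
        )

    for sp in config.species:
        for fam in config.families:
            for si, sub in enumerate(fam.subfamilies, start=1):
                anc = sub_ancestors[(fam.name, si)]
                for _ in range(sub.genes_per_species):
                    cds = evolve_to_identity(anc, config.gene_vs_subfamily,
                                             fam.omega, config.tstv, rng, frozen)
                    plant = build_complete(sp, fam, si, cds)
                    plants[sp].append(plant)
                    complete_slots[sp].append(plant)

    # orthologs: overwrite recipient slots with near-identical copies ------
    og_serial = 0
    fam_by_name = {f.name: f for f in config.families}

    def plant_ortholog_copy(donor: _Plant, recipient_sp: str, ident: float,
                            group: str) -> None:
        fam = fam_by_name[donor.family]
        cand = [p for p in complete_slots[recipient_sp]
                if p.family == donor.family and p.subfamily == donor.subfamily
                and not p.ortholog_group]
        if not cand:
            return
        slot = cand[0]
        cds = evolve_to_identity(donor.cds[:-3], ident, fam.omega,
                                 config.tstv, rng, frozen)
        fresh = build_complete(recipient_sp, fam, donor.subfamily, cds, group,
                               junction_dip=donor.junction or None)
        fresh.name = slot.name  # reuse the slot's serial
        serial[recipient_sp] -= 1
        idx = plants[recipient_sp].index(slot)
        plants[recipient_sp][idx] = fresh
        complete_slots[recipient_sp][complete_slots[recipient_sp].index(slot)] = fresh

    for size, count, ident in (
        (2, config.ortholog_pairs, config.ortholog_identity),
        (3, config.ortholog_triplets, config.triplet_identity),
    ):
        if size > len(config.species):
            continue
        for _ in range(count):
            og_serial += 1
            group = f"OG{og_serial:02d}"
            sps = list(rng.choice(len(config.species), size=size, replace=False))
            donor_sp = config.species[sps[0]]
            donors = [p for p in complete_slots[donor_sp] if not p.ortholog_group]
            if not donors:
                continue
            donor = donors[int(rng.integers(0, len(donors)))]
            donor.ortholog_group = group
            for r in sps[1:]:
                plant_ortholog_copy(donor, config.species[r], ident, group)

    # pseudogenes, edges, fragments, decoys --------------------------------
    all_subs = [(f, si) for f in config.families
                for si, _ in enumerate(f.subfamilies, start=1)]
    for sp in config.species:
        rr = 0
        def next_sub():
            nonlocal rr
            fam, si = all_subs[rr % len(all_subs)]
            rr += 1
            return fam, si

        for kind, n in (("frameshift", config.n_pseudogene_frameshift),
                        ("in_frame_stop", config.n_pseudogene_stop)):
            for _ in range(n):
                fam, si = next_sub()
                cds = evolve_to_identity(sub_ancestors[(fam.name, si)],
                                         config.gene_vs_subfamily, fam.omega,
                                         config.tstv, rng, frozen)
                mutated, _, pos = pseudogenize(cds + _stop(rng), kind, rng)
                plant = _Plant(
                    name=new_name(sp), species=sp, unit="TAA" + mutated,
                    exon_spans=[(3, 3 + len(mutated))], status="pseudogene",
                    pseudo_type=kind, family=fam.name, subfamily=si,
                    ancestor=f"{fam.name}{si}", cds=mutated,
                )
                plant.__dict__["disruption_pos"] = pos
                plants[sp].append(plant)

        for _ in range(config.n_edge):
            fam, si = next_sub()
            cds = evolve_to_identity(sub_ancestors[(fam.name, si)],
                                     config.gene_vs_subfamily, fam.omega,
                                     config.tstv, rng, frozen) + _stop(rng)
            side = "N" if rng.random() < 0.5 else "C"
            piece, n_keep = truncate_to_edge(cds, side, rng, config.edge_keep)
            if side == "C":
                unit = "TAA" + piece
                spans = [(3, 3 + len(piece))]
                placement = "edge_end"
            else:
                unit = piece
                spans = [(0, len(piece))]
                placement = "edge_start"
            plants[sp].append(_Plant(
                name=new_name(sp), species=sp, unit=unit, exon_spans=spans,
                status="edge", family=fam.name, subfamily=si,
                ancestor=f"{fam.name}{si}", cds=piece, placement=placement,
            ))

        for _ in range(config.n_fragment):
            fam, si = next_sub()
            cds = evolve_to_identity(sub_ancestors[(fam.name, si)],
                                     config.gene_vs_subfamily, fam.omega,
                                     config.tstv, rng, frozen)
            n_codons = len(cds) // 3
            f = rng.uniform(*config.fragment_keep)
            n_keep = int(round(f * n_codons))
            c0 = int(rng.integers(5, n_codons - n_keep - 5))
            piece = cds[3 * c0 : 3 * (c0 + n_keep)]
            plants[sp].append(_Plant(
                name=new_name(sp), species=sp, unit=piece,
                exon_spans=[(0, len(piece))], status="fragment",
                family=fam.name, subfamily=si, ancestor=f"{fam.name}{si}",
                cds=piece,
            ))

        for i in range(config.n_decoy):
            anc = decoy_ancestors[i % len(decoy_ancestors)]
            cds = evolve_to_identity(anc, config.decoy_vs_ancestor, 1.0,
                                     config.tstv, rng)
            unit = "TAA" + cds + _stop(rng)
            plants[sp].append(_Plant(
                name=new_name(sp), species=sp, unit=unit,
                exon_spans=[(3, len(unit))], status="decoy",
                family="decoy", subfamily=i % len(decoy_ancestors) + 1,
                ancestor=f"decoy{i % len(decoy_ancestors) + 1}",
                cds=cds, protein=translate(cds),
            ))

    # contig assembly ------------------------------------------------------
    contigs: dict[str, list[Contig]] = {}
    truth_rows = []
    for sp in config.species:
        contigs[sp] = []
        internal = [p for p in plants[sp] if p.placement == "internal"]
        edges = [p for p in plants[sp] if p.placement != "internal"]
        order = list(rng.permutation(len(internal)))
        blocks: list[list[_Plant]] = []
        i = 0
        n_pairs = config.n_gene_clusters
        while i < len(order):
            if n_pairs > 0 and len(order) - i >= 2:
                blocks.append([internal[order[i]], internal[order[i + 1]]])
                i += 2
                n_pairs -= 1
            else:
                blocks.append([internal[order[i]]])
                i += 1
        for p in edges:
            blocks.append([p])

        for bi, block in enumerate(blocks):
            strand = "+" if rng.random() < 0.5 else "-"
            # assemble block sequence with tail-to-head intergenic spacers
            seqs = []
            offsets = []
            pos = 0
            for j, p in enumerate(block):
                if j:
                    gap = int(rng.integers(*config.intergenic))
                    seqs.append(_random_dna(rng, gap, config.gc))
                    pos += gap
                offsets.append(pos)
                seqs.append(p.unit)
                pos += len(p.unit)
            block_seq = "".join(seqs)

            target = rng.lognormal(np.log(config.contig_length_median),
                                   config.contig_length_sigma)
            pad_total = max(int(target) - len(block_seq), 3000)
            placement = block[0].placement if len(block) == 1 else "internal"
            if placement == "edge_start":
                left, right = 0, pad_total
            elif placement == "edge_end":
                left, right = pad_total, 0
            else:
                left = int(rng.integers(1000, pad_total - 1000))
                right = pad_total - left
            contig_seq = (_random_dna(rng, left, config.gc) + block_seq
                          + _random_dna(rng, right, config.gc))
            if strand == "-":
                contig_seq = reverse_complement(contig_seq)
            cid = f"{sp}_ctg{bi + 1:03d}"
            contigs[sp].append(Contig(id=cid, species=sp, seq=contig_seq))
            L = len(contig_seq)
            for j, p in enumerate(block):
                base = left + offsets[j]
                fwd_spans = []
                for (s, e) in p.exon_spans:
                    if strand == "+":
                        fwd_spans.append((base + s, base + e))
                    else:
                        fwd_spans.append((L - (base + e), L - (base + s)))
                fwd_spans.sort()
                truth_rows.append({
                    "gene": p.name,
                    "species": sp,
                    "contig": cid,
                    "exons": ";".join(f"{s}-{e}" for s, e in fwd_spans),
                    "strand": strand,
                    "status": p.status,
                    "pseudo_type": p.pseudo_type,
                    "intron_codon_index": p.intron_codon_index,
                    "junction": p.junction,
                    "family": p.family,
                    "subfamily": p.subfamily,
                    "ortholog_group": p.ortholog_group,
                    "ancestor": p.ancestor,
                    "disruption_pos": p.__dict__.get("disruption_pos", ""),
                    "protein": p.protein,
                    "cds": p.cds,
                })
    truth = pd.DataFrame(truth_rows)
    return SyntheticRepertoire(
        config=config,
        contigs=contigs,
        positive_baits=pos_baits,
        negative_baits=neg_baits,
        truth=truth,
    )
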