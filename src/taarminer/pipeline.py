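"""End-to-end repertoire mining: search → gene models → classification →
dN/dS → features, with the report tables the analysis produces.

Stages communicate through plain data structures and can be run separately;
`run_pipeline` wires them together and writes TSV/GFF3/FASTA/Newick
artifacts.  `reproduce_mode` skips search/model reconstruction and runs the
downstream analyses directly on externally supplied gene catalogues.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .evolution_dnds import (
    DnDsConfig,
    dnds_for_pairs,
    family_summary,
    intra_inter_summary,
)
from .gene_models import (
    COMPLETE_1EXON,
    COMPLETE_2EXON,
    GeneModel,
    ModelConfig,
    adjacency_report,
    junction_census,
    name_gene,
    reconstruct_locus,
    split_into_gene_groups,
)
from .protein_features import (
    conserved_motifs,
    sequon_scan,
    splice_logo,
    stack_alignment,
    tm_segments,
)
from .repertoire_classify import (
    FamilyAssignment,
    cluster_families,
    find_orthologs,
    identity_matrix,
    pairwise_identity,
    tree_from_identity,
    write_newick,
)
from .seq_core import Contig, ProteinSeq, write_fasta, write_gff3
from .translated_search import Bait, SearchConfig, bait_filter, merge_hits, search_contig


@dataclass
class PipelineConfig:
    search: SearchConfig = field(default_factory=SearchConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    dnds: DnDsConfig = field(default_factory=DnDsConfig)
    family_threshold: float = 40.0
    subfamily_threshold: float = 60.0
    ortholog_threshold: float = 99.0
    n_motifs: int = 5
    min_motif_sequences: int = 5


@dataclass
class RepertoireReport:
    models: list[GeneModel]
    rejected: list  # (locus, reason)
    assignments: list[FamilyAssignment]
    status_table: pd.DataFrame  # per-species gene status tally
    pseudogene_table: pd.DataFrame  # frameshift / in-frame stop counts
    junction_table: pd.DataFrame  # splice-junction dipeptide census
    family_table: pd.DataFrame  # family x species counts
    ortholog_groups: list
    ortholog_table: pd.DataFrame  # species-pair ortholog counts
    dnds_records: list
    dnds_family_table: pd.DataFrame
    dnds_intra_inter_table: pd.DataFrame
    adjacency: list
    tree: object | None
    motifs: list
    logos: tuple | None
    aromatic_basic_fraction: float
    manifest: dict


# ---------------------------------------------------------------------------
# stage 1+2: search and model reconstruction
# ---------------------------------------------------------------------------

def mine_contig(contig: Contig, baits: list[Bait],
                baits_by_id: dict[str, ProteinSeq],
                search_cfg: SearchConfig, model_cfg: ModelConfig):
    """All gene models on one contig, plus rejected candidate loci."""
    hits = search_contig(baits, contig, search_cfg)
    loci = merge_hits(hits, search_cfg.merge_gap)
    groups = [g for locus in loci
              for g in split_into_gene_groups(locus, model_cfg.gene_group_gap)]
    retained, rejected = bait_filter(groups, search_cfg)
    models = []
    for sub in retained:
        mask = [g.interval for g in groups if g is not sub]
        model = reconstruct_locus(sub, baits_by_id, contig, model_cfg, mask=mask)
        if model is not None:
            models.append(model)
    return models, rejected


def mine_assembly(contigs: dict[str, list[Contig]],
                  positive_baits: list[Bait], negative_baits: list[Bait],
                  config: PipelineConfig = PipelineConfig()):
    if not positive_baits:
        raise ValueError("positive bait set is empty")
    if not negative_baits:
        raise ValueError("negative bait set is empty")
    baits = list(positive_baits) + list(negative_baits)
    baits_by_id = {b.id: b.protein for b in baits}
    all_models: list[GeneModel] = []
    all_rejected = []
    for species in contigs:
        for contig in contigs[species]:
            models, rejected = mine_contig(
                contig, baits, baits_by_id, config.search, config.model
            )
            all_models.extend(models)
            all_rejected.extend(rejected)
    return all_models, all_rejected


# ---------------------------------------------------------------------------
# stage 3: classification and naming
# ---------------------------------------------------------------------------

def classify_and_name(models: list[GeneModel],
                      config: PipelineConfig = PipelineConfig(),
                      rename: bool = True):
    """Family/subfamily assignment from complete models; naming of all.

    With ``rename=False`` existing model names (e.g. catalogue record ids)
    are kept."""
    complete = [m for m in models if m.is_complete]
    assignments: list[FamilyAssignment] = []
    matrix = None
    if len(complete) >= 2:
        proteins = [
            ProteinSeq(f"g{i}", m.protein) for i, m in enumerate(complete)
        ]
        matrix = identity_matrix(proteins)
        assignments = cluster_families(
            matrix, config.family_threshold, config.subfamily_threshold
        )
        for asg, m in zip(assignments, complete):
            m.family = asg.family
            m.subfamily = asg.subfamily
    # partial genes inherit the family of their closest complete relative
    for m in models:
        if m.is_complete or not m.protein:
            continue
        partial = m.protein.replace("*", "X")
        best = (0.0, "U", 0)
        for c in complete:
            ident = pairwise_identity(partial, c.protein)
            if ident > best[0]:
                best = (ident, c.family, c.subfamily)
        if best[0] >= config.family_threshold:
            m.family, m.subfamily = best[1], best[2]
    # names: per species, genomic order, three-digit serials
    if rename:
        serial: dict[str, int] = {}
        for m in sorted(models, key=lambda m: (m.species, m.contig_id, m.start)):
            serial[m.species] = serial.get(m.species, 0) + 1
            fam = m.family if m.family != "U" else "U"
            m.name = name_gene(m.species, m.status, fam, serial[m.species])
    # rebuild assignments with final names
    named = []
    for m in complete:
        named.append(FamilyAssignment(gene=m.name, family=m.family,
                                      subfamily=m.subfamily))
    return named, matrix


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

STATUS_ORDER = [COMPLETE_1EXON, COMPLETE_2EXON, "pseudogene", "edge", "fragment"]


def status_table(models: list[GeneModel]) -> pd.DataFrame:
    rows = []
    for sp in sorted({m.species for m in models}):
        counts = {s: 0 for s in STATUS_ORDER}
        for m in models:
            if m.species == sp:
                counts[m.status] += 1
        counts["total"] = sum(counts.values())
        counts["species"] = sp
        rows.append(counts)
    df = pd.DataFrame(rows)
    return df[["species"] + STATUS_ORDER + ["total"]]


def pseudogene_table(models: list[GeneModel]) -> pd.DataFrame:
    rows = []
    for sp in sorted({m.species for m in models}):
        fs = stop = both = 0
        for m in models:
            if m.species == sp and m.status == "pseudogene":
                if m.pseudo_type == "frameshift":
                    fs += 1
                elif m.pseudo_type == "in_frame_stop":
                    stop += 1
                elif m.pseudo_type == "both":
                    both += 1
        rows.append({"species": sp, "frameshift": fs,
                     "in_frame_stop": stop, "both": both})
    return pd.DataFrame(rows)


def junction_table(models: list[GeneModel]) -> tuple[pd.DataFrame, float]:
    pooled, per_species, frac = junction_census(models)
    dips = sorted(pooled, key=lambda d: (-pooled[d], d))
    rows = []
    for sp in sorted(per_species):
        row = {"species": sp}
        row.update({d: per_species[sp].get(d, 0) for d in dips})
        rows.append(row)
    total = {"species": "all"}
    total.update(pooled)
    rows.append(total)
    return pd.DataFrame(rows).fillna(0), frac


def family_table(models: list[GeneModel]) -> pd.DataFrame:
    complete = [m for m in models if m.is_complete]
    species = sorted({m.species for m in complete})
    fams = sorted({(m.family, m.subfamily) for m in complete})
    rows = []
    for fam, sub in fams:
        row = {"family": fam, "subfamily": sub}
        for sp in species:
            row[sp] = sum(1 for m in complete
                          if m.species == sp and m.family == fam
                          and m.subfamily == sub)
        rows.append(row)
    return pd.DataFrame(rows)


def ortholog_table(groups, species: list[str]) -> pd.DataFrame:
    """Species-pair counts of ortholog pairs (diagonal: within-species paralogs)."""
    counts = {(a, b): 0 for a in species for b in species}
    for g in groups:
        if len(g.members) != 2:
            continue
        a, b = sorted(g.species)
        counts[(a, b)] += 1
    rows = []
    for a in species:
        row = {"species": a}
        for b in species:
            row[b] = counts[(min(a, b), max(a, b))] if a <= b else ""
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _analyze(models: list[GeneModel], contigs: dict[str, list[Contig]] | None,
             config: PipelineConfig, cds_by_gene: dict[str, str] | None = None,
             manifest_extra: dict | None = None,
             rename: bool = True) -> RepertoireReport:
    assignments, matrix = classify_and_name(models, config, rename=rename)
    complete = [m for m in models if m.is_complete]
    species_of = {m.name: m.species for m in complete}
    family_of = {a.gene: a.family for a in assignments}

    groups = []
    tree = None
    if matrix is not None:
        named_matrix = matrix
        named_matrix.ids = [m.name for m in complete]
        named_matrix._index = {g: i for i, g in enumerate(named_matrix.ids)}
        groups = find_orthologs(named_matrix, species_of,
                                config.ortholog_threshold)
        if len(complete) >= 2:
            tree = tree_from_identity(named_matrix)

    # dN/dS over within-family pairs of complete genes
    if cds_by_gene is None:
        cds_by_gene = {m.name: m.cds for m in complete}
    pairs = [
        (a, b) for a, b in itertools.combinations(sorted(family_of), 2)
        if family_of[a] == family_of[b]
        and a in cds_by_gene and b in cds_by_gene
    ]
    records = dnds_for_pairs(cds_by_gene, pairs, config.dnds)
    dnds_fam = family_summary(records, family_of)
    dnds_intra = intra_inter_summary(records, species_of, family_of)

    # conserved motifs on the stacked repertoire alignment
    motifs = []
    if len(complete) >= config.min_motif_sequences:
        aln = stack_alignment([m.protein for m in complete])
        motifs = conserved_motifs(aln, k=config.n_motifs)

    logos = None
    spliced = [m for m in models if m.status == COMPLETE_2EXON]
    if contigs is not None and spliced:
        contig_map = {c.id: c for group in contigs.values() for c in group}
        logos = splice_logo(spliced, contig_map)

    jt, frac = junction_table(models)
    st = status_table(models)
    report = RepertoireReport(
        models=models,
        rejected=[],
        assignments=assignments,
        status_table=st,
        pseudogene_table=pseudogene_table(models),
        junction_table=jt,
        family_table=family_table(models),
        ortholog_groups=groups,
        ortholog_table=ortholog_table(groups, sorted({m.species for m in models})),
        dnds_records=records,
        dnds_family_table=dnds_fam,
        dnds_intra_inter_table=dnds_intra,
        adjacency=adjacency_report(models),
        tree=tree,
        motifs=motifs,
        logos=logos,
        aromatic_basic_fraction=frac,
        manifest={
            "version": __version__,
            **(manifest_extra or {}),
        },
    )
    _check_consistency(report)
    return report


def _check_consistency(report: RepertoireReport) -> None:
    """Cross-table invariants asserted on every run."""
    n_spliced = sum(1 for m in report.models if m.status == COMPLETE_2EXON)
    jt = report.junction_table
    if len(jt):
        census_total = int(jt[jt.species == "all"].drop(columns="species")
                           .sum(axis=1).iloc[0])
        assert census_total == n_spliced, (
            f"junction census total {census_total} != spliced models {n_spliced}"
        )
    assert int(report.status_table["total"].sum()) == len(report.models)


def _hash_config(config: PipelineConfig) -> str:
    text = repr((config.search, config.model, config.dnds,
                 config.family_threshold, config.subfamily_threshold,
                 config.ortholog_threshold))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(contigs: dict[str, list[Contig]],
                 positive_baits: list[Bait], negative_baits: list[Bait],
                 config: PipelineConfig = PipelineConfig(),
                 outdir: str | None = None) -> RepertoireReport:
    """Mine assemblies and produce the full repertoire report."""
    models, rejected = mine_assembly(contigs, positive_baits,
                                     negative_baits, config)
    checksum = hashlib.sha256(
        "".join(c.seq for group in contigs.values() for c in group).encode()
    ).hexdigest()[:16]
    report = _analyze(models, contigs, config,
                      manifest_extra={"config_hash": _hash_config(config),
                                      "input_checksum": checksum})
    report.rejected = rejected
    if outdir is not None:
        write_report(report, outdir)
    return report


def reproduce_mode(proteins: list[ProteinSeq],
                   species_of_gene, cds: dict[str, str] | None = None,
                   config: PipelineConfig = PipelineConfig(),
                   outdir: str | None = None) -> RepertoireReport:
    """Run classification / orthologs / dN/dS / motifs on a gene catalogue.

    ``species_of_gene`` maps a record id to its species label (e.g. the
    3-letter prefix of catalogue names).  CDS sequences are required for
    the dN/dS tables; without them only identity-based tables are produced.
    """
    from .seq_core import GenomicInterval

    models = []
    for i, p in enumerate(proteins):
        if not p.seq:
            raise ValueError(f"catalogue record {p.id} has an empty sequence")
        m = GeneModel(
            species=species_of_gene(p.id),
            exons=[GenomicInterval("catalogue", 3 * i, 3 * i + 3, "+")],
            strand="+",
            cds=cds.get(p.id, "") if cds else "",
            protein=p.seq.rstrip("*"),
            status=COMPLETE_1EXON,
        )
        m.name = p.id
        models.append(m)
    config_hash = _hash_config(config)
    report = _analyze(models, None, config,
                      cds_by_gene={m.name: m.cds for m in models if m.cds},
                      manifest_extra={"config_hash": config_hash,
                                      "mode": "reproduce"},
                      rename=False)
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: RepertoireReport, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    report.status_table.to_csv(p("status_table.tsv"), sep="\t", index=False)
    report.pseudogene_table.to_csv(p("pseudogene_table.tsv"), sep="\t", index=False)
    report.junction_table.to_csv(p("junction_table.tsv"), sep="\t", index=False)
    report.family_table.to_csv(p("family_table.tsv"), sep="\t", index=False)
    report.ortholog_table.to_csv(p("ortholog_table.tsv"), sep="\t", index=False)
    report.dnds_family_table.to_csv(p("dnds_family.tsv"), sep="\t", index=False)
    report.dnds_intra_inter_table.to_csv(p("dnds_intra_inter.tsv"), sep="\t",
                                         index=False)
    pd.DataFrame([{
        "pair": "|".join(r.pair), "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
        "dS": r.dS, "dN": r.dN, "omega": r.omega_text,
    } for r in report.dnds_records]).to_csv(p("dnds_pairs.tsv"), sep="\t",
                                            index=False)
    pd.DataFrame(report.adjacency).to_csv(p("adjacency.tsv"), sep="\t",
                                          index=False)
    complete = [m for m in report.models if m.is_complete]
    if complete:
        write_fasta([(m.name, m.protein) for m in complete],
                    p("complete_proteins.fasta"))
        write_fasta([(m.name, m.cds) for m in complete],
                    p("complete_cds.fasta"))
    real_models = [m for m in report.models
                   if m.exons[0].contig_id != "catalogue"]
    if real_models:
        write_gff3(real_models, p("models.gff3"))
    if report.tree is not None:
        write_newick(report.tree, p("tree.nwk"))
    if report.motifs:
        with open(p("motifs.txt"), "w") as fh:
            for i, m in enumerate(report.motifs, 1):
                fh.write(f"MOTIF {i} width={m.width} start_col={m.start} "
                         f"mean_ic={m.mean_ic:.3f} consensus={m.consensus}\n")
    if report.logos is not None:
        for logo in report.logos:
            df = pd.DataFrame(logo.pfm, columns=list("ACGT"))
            df["ic"] = logo.ic
            df.to_csv(p(f"splice_logo_{logo.side}.tsv"), sep="\t", index=False)
    with open(p("manifest.json"), "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
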