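"""Scoring of recovered gene models against a planted truth table.

Models are matched to truth records by same-contig, same-strand genomic
overlap; the confusion matrix, per-class recall, exactness of recovered
exon boundaries, and partition agreement (Rand index) are the headline
recovery metrics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_models import GeneModel

STATUSES = ["complete_1exon", "complete_2exon", "pseudogene", "edge", "fragment"]


def _truth_spans(row) -> list[tuple[int, int]]:
    return [tuple(map(int, part.split("-"))) for part in row.exons.split(";")]


def match_models(models: list[GeneModel], truth: pd.DataFrame) -> pd.DataFrame:
    """One row per planted gene: truth status vs recovered status/coordinates."""
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        by_key.setdefault((m.contig_id, m.strand), []).append(m)
    rows = []
    used: set[int] = set()
    for row in truth.itertuples():
        spans = _truth_spans(row)
        t0, t1 = spans[0][0], spans[-1][1]
        best = None
        for m in by_key.get((row.contig, row.strand), []):
            ov = min(m.end, t1) - max(m.start, t0)
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, m)
        model = best[1] if best else None
        if model is not None:
            used.add(id(model))
        model_spans = sorted((e.start, e.end) for e in model.exons) if model else []
        rows.append({
            "gene": row.gene,
            "species": row.species,
            "truth_status": row.status,
            "truth_pseudo_type": row.pseudo_type,
            "recovered": model is not None,
            "model_status": model.status if model else "missed",
            "model_pseudo_type": model.pseudo_type if model else "",
            "model_name": model.name if model else "",
            "exons_exact": model_spans == sorted(spans) if model else False,
            # donor/acceptor positions (ignores start-ATG choice, which can
            # be genuinely ambiguous when an in-frame ATG follows the start)
            "intron_exact": (
                [s[1] for s in model_spans[:-1]] == [s[1] for s in sorted(spans)[:-1]]
                and [s[0] for s in model_spans[1:]] == [s[0] for s in sorted(spans)[1:]]
                if model and len(model_spans) == len(spans) == 2 else
                None if row.status != "complete_2exon" else False
            ),
            "intron_index_match": (
                model.intron_codon_index == row.intron_codon_index
                if model and row.status == "complete_2exon" else None
            ),
            "junction_match": (
                (str(model.junction) if model and model.junction else "")
                == row.junction if row.status == "complete_2exon" else None
            ),
        })
    extra = [m for group in by_key.values() for m in group if id(m) not in used]
    df = pd.DataFrame(rows)
    df.attrs["n_unmatched_models"] = len(extra)
    return df


def status_recall(matched: pd.DataFrame) -> dict[str, float]:
    """Per-class recall over plantable statuses (decoys excluded)."""
    out = {}
    for status in STATUSES:
        sub = matched[matched.truth_status == status]
        if len(sub):
            out[status] = float((sub.model_status == status).mean())
    return out


def confusion_matrix(matched: pd.DataFrame) -> pd.DataFrame:
    sub = matched[matched.truth_status.isin(STATUSES)]
    return pd.crosstab(sub.truth_status, sub.model_status)


#: per-omega protein-identity targets for the recovery experiment: the
#: divergence is scaled down as omega falls so that synonymous sites stay
#: clear of Jukes–Cantor saturation (low-omega lineages fix ~3 synonymous
#: changes per nonsynonymous one)
OMEGA_RECOVERY_IDENTITY = {0.1: 95.0, 0.5: 85.0, 1.0: 80.0}


def omega_recovery(omega: float, seed: int, n_codons: int = 300,
                   n_descendants: int = 5,
                   identity: float | None = None) -> float:
    """Mean pairwise NG86 omega of a small repertoire evolved at ``omega``.

    Descendants of one receptor ancestor are evolved under the accept/reject
    mutation process with nonsynonymous acceptance probability ``omega``;
    the mean dN/dS over descendant pairs estimates it.
    """
    import math

    import numpy as np

    from .evolution_dnds import ng86_pair
    from .synthetic_repertoire import evolve_to_identity, receptor_cds

    if identity is None:
        identity = OMEGA_RECOVERY_IDENTITY.get(omega, 85.0)
    rng = np.random.default_rng(seed)
    anc = receptor_cds(rng, n_codons)
    descendants = [evolve_to_identity(anc, identity, omega, 1.0, rng)
                   for _ in range(n_descendants)]
    omegas = []
    for a, b in itertools.combinations(descendants, 2):
        rec = ng86_pair(a, b)
        if not math.isnan(rec.omega):
            omegas.append(rec.omega)
    return float(np.mean(omegas))


def rand_index(labels_a: list, labels_b: list) -> float:
    """Plain Rand index between two partitions of the same items."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label lists must have equal length")
    n = len(labels_a)
    if n < 2:
        return 1.0
    agree = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        agree += same_a == same_b
    return agree / (n * (n - 1) / 2)
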