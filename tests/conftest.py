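import pytest

from taarminer.pipeline import PipelineConfig, run_pipeline
from taarminer.synthetic_repertoire import (
    FamilyPlan,
    SubfamilyPlan,
    SynthConfig,
    generate,
)

#: a small two-species repertoire used across the suite: two families, one
#: ortholog pair, one of each non-complete plant
TINY_CONFIG = SynthConfig(
    seed=11,
    species=("Til", "Bur"),
    families=(
        FamilyPlan("A", 0.4, (SubfamilyPlan(True, 3), SubfamilyPlan(False, 2))),
        FamilyPlan("B", 0.5, (SubfamilyPlan(True, 2),)),
    ),
    n_pseudogene_frameshift=1,
    n_pseudogene_stop=1,
    n_edge=1,
    n_fragment=1,
    n_decoy=2,
    ortholog_pairs=1,
    ortholog_triplets=0,
    n_gene_clusters=1,
    contig_length_median=12000.0,
)


@pytest.fixture(scope="session")
def tiny_repertoire():
    return generate(TINY_CONFIG)


@pytest.fixture(scope="session")
def tiny_report(tiny_repertoire):
    return run_pipeline(
        tiny_repertoire.contigs,
        tiny_repertoire.positive_baits,
        tiny_repertoire.negative_baits,
        PipelineConfig(),
    )
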