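import numpy as np
import pandas as pd
import pytest

from topoclust import pipeline, simulate
from topoclust.io import CountMatrix, GeneModel, GenomeSequence, TranscriptionUnit


@pytest.fixture(scope="session")
def tiny_design():
    """A fast design for unit tests: 200 kb, 180 genes."""
    return simulate.SyntheticDesign(
        seed=7,
        genome_length=200_000,
        n_genes=180,
        planted_clusters=(
            simulate.PlantedCluster(20_000, 50_000, "up", fraction=0.6),
            simulate.PlantedCluster(120_000, 150_000, "down", log2_effect=-3.0,
                                    fraction=0.6),
        ),
        n_induced_promoters=20,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_design):
    return simulate.simulate_genome(tiny_design)


@pytest.fixture(scope="session")
def tiny_annotation(tiny_design, tiny_genome):
    return simulate.simulate_annotation(tiny_design, tiny_genome)


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """The full desk-scale demo dataset, generated once per session."""
    outdir = tmp_path_factory.mktemp("demo")
    paths = pipeline.make_demo(1, outdir)
    return paths


def make_count_matrix(counts: dict, conditions: dict) -> CountMatrix:
    """Hand-build a CountMatrix from {gene: {sample: count}} + {sample: cond}."""
    df = pd.DataFrame(counts).T
    df.index.name = "gene"
    samples = pd.DataFrame(
        [
            {"sample": s, "condition": c, "replicate": i + 1}
            for i, (s, c) in enumerate(conditions.items())
        ]
    ).set_index("sample")
    return CountMatrix(df.astype(np.int64), samples)


def three_gene_annotation():
    """Hand-built 3-gene case used to pin the 1-based inclusive convention."""
    genes = [
        GeneModel("gA", "c", 100, 400, "+"),
        GeneModel("gB", "c", 500, 900, "-"),
        GeneModel("gC", "c", 1000, 4000, "-"),
    ]
    tus = [TranscriptionUnit("tuBC", ("gC", "gB"), "-", 4000)]
    return genes, tus
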