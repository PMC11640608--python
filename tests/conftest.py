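import numpy as np
import pandas as pd
import pytest

from stprofiler import (
    PathwayDefinition,
    STPProfile,
    TargetGene,
    generate_pathway_definitions,
)


def make_profile(scores: dict, index=None, metadata=None) -> STPProfile:
    """Build a profile directly from score values (log2odds set to a linear
    proxy; only the scores matter for clustering/matching tests)."""
    df = pd.DataFrame(scores, index=index)
    if index is None:
        df.index = [f"s{i}" for i in range(len(df))]
    df.index.name = "sample_id"
    return STPProfile(scores=df, log2odds=(df - 50.0) / 10.0, metadata=metadata)


@pytest.fixture
def three_gene_pathway() -> PathwayDefinition:
    return PathwayDefinition(
        name="TEST",
        targets=[
            TargetGene("g1", "up", 0.8),
            TargetGene("g2", "up", 0.4),
            TargetGene("g3", "down", 0.6),
        ],
    )


@pytest.fixture
def definitions():
    return generate_pathway_definitions(n_pathways=7, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
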