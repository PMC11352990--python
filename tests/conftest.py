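import numpy as np
import pytest

from cdonbd import (
    CbowConfig,
    CdonConfig,
    FoldScheme,
    PipelineConfig,
    SyntheticSpec,
    WalkConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group cohort with a strong pairwise effect (cheap)."""
    spec = SyntheticSpec(
        n_nodes=12,
        n_timepoints=120,
        subjects_per_group=4,
        affected_nodes=(0, 1, 2),
        delta=0.6,
        seed=5,
    )
    return spec, *generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_config():
    """Pipeline configuration scaled down to the tiny cohort."""
    return PipelineConfig(
        seed=5,
        cdon=CdonConfig(hidden_units=5, epochs=400),
        walk=WalkConfig(walks_per_node=10, walk_length=20),
        cbow=CbowConfig(dim=8, epochs=3),
        folds=FoldScheme(n_folds=4),
    )
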