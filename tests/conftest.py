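import numpy as np
import pandas as pd
import pytest

from regdiff import (
    ExpressionMatrix,
    SampleAnnotation,
    SimulationConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Small but structured synthetic cohort shared across tests."""
    cfg = SimulationConfig(
        n_genes=500,
        n_samples_per_group=(30, 30),
        n_tfs=8,
        n_active_tfs=2,
        regulon_size_range=(15, 25),
        frac_de_genes=0.1,
        effect_size=1.0,
        noise_sd=0.5,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """All-null cohort: no planted effects anywhere."""
    cfg = SimulationConfig(
        n_genes=400,
        n_samples_per_group=(25, 25),
        n_tfs=5,
        n_active_tfs=0,
        regulon_size_range=(10, 20),
        effect_size=0.0,
        tf_activity_shift=0.0,
        noise_sd=0.5,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def tiny_expr():
    """3-gene x 6-sample matrix with hand-checkable values."""
    data = pd.DataFrame(
        {
            "s1": [2.0, 1.0, 5.0],
            "s2": [4.0, 1.0, 5.0],
            "s3": [6.0, 1.0, 5.0],
            "s4": [1.0, 1.0, 5.0],
            "s5": [3.0, 1.0, 5.0],
            "s6": [5.0, 1.0, 5.0],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_ann():
    return SampleAnnotation(
        pd.DataFrame(
            {"group": ["A", "A", "A", "B", "B", "B"]},
            index=pd.Index([f"s{i}" for i in range(1, 7)], name="sample_id"),
        )
    )
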