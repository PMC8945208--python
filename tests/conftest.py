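import pytest

from graphchart import (
    GraphChartEncoder,
    SweepConfig,
    default_registry,
    generate_dataset,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small mixed benchmark for fast unit tests (short sweeps)."""
    return generate_dataset(
        n_train_normal=8,
        n_test_normal=4,
        n_test_abnormal=4,
        base_seed=11,
        cfg=SweepConfig(n_frames=60),
    )


@pytest.fixture(scope="session")
def tiny_encoder(tiny_dataset):
    """A briefly trained cascade encoder shared across fast tests."""
    return GraphChartEncoder(
        kernel_width=8, epochs=6, train_stride=4, random_state=0
    ).fit(tiny_dataset.train)
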