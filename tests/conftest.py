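import numpy as np
import pytest

from vinechem import (
    ArtifactSpec,
    ConstituentSpec,
    SyntheticConfig,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A fast three-constituent dataset on a short grid."""
    defaults = dict(
        n_samples=40,
        grid=(400.0, 1000.0, 80),
        constituents=(
            ConstituentSpec("TSS", (8.0, 25.0), ((600.0, 30.0, -0.006),)),
            ConstituentSpec("TA", (5.0, 18.0), ((750.0, 25.0, -0.008),)),
            ConstituentSpec("pH", (2.5, 3.8), ((480.0, 20.0, -0.03),)),
        ),
        artifacts=ArtifactSpec(0.05, 0.01, (0.01,), 0.001),
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def small_dataset():
    return generate_dataset(small_config(seed=7))
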