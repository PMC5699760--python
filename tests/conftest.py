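import numpy as np
import pytest

from hepatodimorph import (
    ExpressionMatrix,
    SampleTable,
    SexEffect,
    SimulationConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """120 genes, 40+40 samples, two planted modules and a few sex effects."""
    config = SimulationConfig(
        n_genes=120,
        n_male=40,
        n_female=40,
        module_sizes=[25, 20],
        module_loading=0.7,
        sex_effects=[
            SexEffect(0, 0.30, "F"),
            SexEffect(1, 0.20, "M"),
            SexEffect(50, 0.25, "F"),
        ],
        noise_sd=0.15,
        seed=42,
    )
    return generate_dataset(config)


@pytest.fixture
def toy_matrix():
    """Deterministic 6-gene x 8-sample matrix with non-trivial variance."""
    rng = np.random.default_rng(7)
    values = rng.normal(size=(6, 8))
    return ExpressionMatrix(
        [f"g{i}" for i in range(6)], [f"s{j}" for j in range(8)], values
    )


@pytest.fixture
def toy_samples():
    return SampleTable(
        [f"s{j}" for j in range(8)], ["M", "M", "M", "M", "F", "F", "F", "F"]
    )
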