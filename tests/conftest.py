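import numpy as np
import pytest

from lemopt import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """Three well-separated classes, 45 samples x 60 features, 5 planted
    genes per class — small enough for fast classifier tests."""
    spec = SyntheticSpec(
        class_counts={"A": 15, "B": 15, "C": 15},
        n_features=60,
        n_informative=5,
        effect=2.5,
        dispersion=0.5,
        seed=7,
    )
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
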