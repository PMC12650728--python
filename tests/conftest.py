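import numpy as np
import pytest

from snakeseg.synthetic import generate_dataset, scaled_specs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_samples():
    """Eight 64x64 synthetic angiograms shared across pipeline tests."""
    tree, rend = scaled_specs(64)
    return [s.as_sample(f"s{i}") for i, s in enumerate(generate_dataset(8, seed=11, tree_spec=tree, render_spec=rend))]
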