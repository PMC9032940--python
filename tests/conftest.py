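import numpy as np
import pytest

from mbeeg import BranchConfig, ModelSpec, SynthConfig, generate_synthetic_mi


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    """A small but structurally complete three-branch spec (fast to run)."""
    return ModelSpec(
        channels=6, time_samples=128, n_classes=4,
        branches=(
            BranchConfig(2, 8, 0.0, 2),
            BranchConfig(4, 16, 0.1, 4),
            BranchConfig(4, 32, 0.2, 2),
        ),
    )


@pytest.fixture
def tiny_mi_data():
    """Easily decodable synthetic trials matching ``tiny_spec``'s shape."""
    cfg = SynthConfig(n_trials_per_class=6, channels=6, time_samples=128,
                      n_classes=4, erd_depth=0.8, seed=42)
    return generate_synthetic_mi(cfg)
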