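import numpy as np
import pytest

from phytoscreen.dataset_builder import FingerprintMatrix, build_dataset
from phytoscreen.synthetic_data import (
    FingerprintSimConfig,
    simulate_fingerprint_dataset,
)


def make_dataset(
    n_active=200, n_inactive=200, effect=0.9, noise=0.01, seed=1, **kwargs
):
    """Simulated fingerprint dataset run through the full build pipeline."""
    sim = simulate_fingerprint_dataset(
        FingerprintSimConfig(
            n_active=n_active,
            n_inactive=n_inactive,
            effect=effect,
            noise_flip_rate=noise,
            seed=seed,
        )
    )
    fps = FingerprintMatrix([f"K{i:06d}" for i in range(len(sim.labels))], sim.bits)
    ds = build_dataset(fps, sim.labels, seed=seed, cell_line="SYN", **kwargs)
    return ds, sim


@pytest.fixture(scope="session")
def planted_dataset():
    """200+200 compounds, 5 strongly informative bits, light noise."""
    ds, sim = make_dataset(seed=1)
    return ds, sim


@pytest.fixture(scope="session")
def separable_dataset():
    """Perfectly separable: effect 1, no noise."""
    ds, sim = make_dataset(effect=1.0, noise=0.0, seed=2)
    return ds, sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
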