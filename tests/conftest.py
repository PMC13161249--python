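import numpy as np
import pytest

from ildselect.landmark_io import FactorTable, LandmarkArray
from ildselect.synthetic import (
    SyntheticSpec,
    cranial_landmark_names,
    default_symmetry_map,
    generate_dataset,
    probe_dataset_spec,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def cranial_names():
    return cranial_landmark_names()


@pytest.fixture(scope="session")
def cranial_map():
    return default_symmetry_map()


@pytest.fixture(scope="session")
def small_dataset():
    """Small noisy two-group dataset: 3 midplane + 2 pairs, 12 + 12."""
    spec = SyntheticSpec(m_mid=3, p_pairs=2, n_per_group=12, noise_sd=1.0, seed=5)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def probe_data():
    """Default 31-landmark probe dataset with two planted ILDs at d=2.5."""
    spec, effect = probe_dataset_spec(seed=1, d=2.5)
    data, factor, smap, truth = generate_dataset(spec)
    return data, factor, smap, truth, effect


def random_configuration(rng, n=5, q=8, dim=3, scale=50.0):
    coords = rng.normal(scale=scale, size=(n, q, dim))
    ids = [f"ind{i}" for i in range(n)]
    names = [f"lm{j}" for j in range(q)]
    return LandmarkArray(coords, ids, names)


def rigid_motion(rng, config):
    """Apply a random rotation + translation to one configuration."""
    dim = config.shape[1]
    a = rng.normal(size=(dim, dim))
    qmat, r = np.linalg.qr(a)
    qmat *= np.sign(np.diag(r))
    if np.linalg.det(qmat) < 0:
        qmat[:, 0] *= -1
    return config @ qmat + rng.normal(scale=30.0, size=dim)


@pytest.fixture
def two_group_factor():
    def make(n1, n2, levels=("F", "M")):
        ids = [f"{levels[0]}{i}" for i in range(n1)] + [f"{levels[1]}{i}" for i in range(n2)]
        return FactorTable(ids, factor=[levels[0]] * n1 + [levels[1]] * n2, levels=levels)

    return make
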