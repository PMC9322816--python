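import numpy as np
import pytest

from spingarch import (
    CARSpec,
    ModelParams,
    build_lattice,
    generate_city_lattice,
)


@pytest.fixture
def two_site_lattice():
    return build_lattice([("a", "b")], ["a", "b"])


@pytest.fixture
def path3_lattice():
    return build_lattice([("a", "b"), ("b", "c")], ["a", "b", "c"])


@pytest.fixture
def grid5():
    return generate_city_lattice(5, 5)


@pytest.fixture
def grid6():
    return generate_city_lattice(6, 6)


@pytest.fixture
def car_half():
    return CARSpec(zeta=0.5, sigma2=1.0)


def random_small_lattice(rng, n_max=6):
    """A random connected-or-not lattice with 2..n_max sites."""
    n = rng.integers(2, n_max + 1)
    ids = [f"s{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                edges.append((ids[i], ids[j]))
    return build_lattice(edges, ids)


def random_valid_carspec(rng, lattice):
    """A CARSpec with zeta uniform on the valid interval, away from the edges."""
    chi = lattice.eigvals
    hi = 1.0 / chi.max() if chi.max() > 0 else 5.0
    lo = 1.0 / chi.min() if chi.min() < 0 else -5.0
    zeta = rng.uniform(0.9 * lo, 0.9 * hi)
    return CARSpec(zeta=float(zeta), sigma2=float(rng.uniform(0.2, 3.0)))


@pytest.fixture
def flat_params():
    def make(n, T, **kw):
        defaults = dict(eta=0.2, kappa=0.1, sigma=0.3, sigma_eps=0.5, zeta=0.9,
                        alpha=np.zeros((n, T)))
        defaults.update(kw)
        return ModelParams(**defaults)

    return make
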