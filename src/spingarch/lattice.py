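"""Lattice adjacency algebra and the conditionally autoregressive (CAR) Gaussian field.

The CAR field on a lattice with scaled adjacency matrix ``N_scaled`` has joint
precision ``(I - zeta * N_scaled) / sigma2``.  Scaling the raw 0/1 adjacency by
its spectral radius puts the upper edge of the valid dependence range at
``zeta = 1`` on every lattice, which is what makes values such as 0.99
admissible regardless of lattice geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = [
    "Lattice",
    "CARSpec",
    "build_lattice",
    "car_conditional_mean",
    "log_det_car_precision",
    "car_marginal_variances",
    "sample_car_field",
]


@dataclass(frozen=True)
class Lattice:
    """A finite set of spatial units with a symmetric 0/1 neighborhood structure.

    Attributes
    ----------
    site_ids
        Ordered unit identifiers; positions index rows/columns of the matrices.
    n
        Number of units.
    N_raw
        Binary symmetric adjacency with zero diagonal.
    N_scaled
        ``N_raw`` divided by its largest eigenvalue (identity mapping when the
        lattice has no edges, in which case ``N_raw`` is all zeros).
    eigvals
        Sorted eigenvalues of ``N_scaled``.
    eigvecs
        Orthonormal eigenvectors of ``N_scaled`` (columns), matching ``eigvals``.
    centroids
        Optional (n, 2) coordinates, used only by synthetic-data generation.
    """

    site_ids: tuple
    n: int
    N_raw: np.ndarray
    N_scaled: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray = field(repr=False, default=None)
    centroids: np.ndarray | None = field(repr=False, default=None)

    def index_of(self, site_id: Hashable) -> int:
        try:
            return self.site_ids.index(site_id)
        except ValueError:
            raise KeyError(f"unknown site id: {site_id!r}") from None

    @property
    def n_edges(self) -> int:
        return int(self.N_raw.sum()) // 2


@dataclass(frozen=True)
class CARSpec:
    """CAR dependence coefficient and conditional variance.

    ``zeta`` weights the scaled neighbor deviations in the conditional mean;
    ``sigma2`` is the conditional variance of every site given its neighbors.
    """

    zeta: float
    sigma2: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.zeta):
            raise ValueError("zeta must be finite")
        if not (self.sigma2 > 0 and np.isfinite(self.sigma2)):
            raise ValueError("sigma2 must be positive and finite")

    def validate(self, lattice: Lattice) -> None:
        """Raise if the implied precision is not positive definite on *lattice*."""
        margins = 1.0 - self.zeta * lattice.eigvals
        if np.any(margins <= 0):
            raise ValueError(
                f"CAR precision not positive definite: min(1 - zeta*chi) = {margins.min():.3g}"
            )


def build_lattice(
    edges: Iterable[tuple[Hashable, Hashable]],
    site_ids: Sequence[Hashable],
    centroids: np.ndarray | None = None,
) -> Lattice:
    """Assemble a :class:`Lattice` from an edge list.

    Duplicate edges are idempotent; self-loops and endpoints not present in
    *site_ids* are rejected.
    """
    site_ids = tuple(site_ids)
    if len(set(site_ids)) != len(site_ids):
        raise ValueError("site_ids contains duplicates")
    index = {s: i for i, s in enumerate(site_ids)}
    n = len(site_ids)
    if n == 0:
        raise ValueError("site_ids is empty")
    N = np.zeros((n, n))
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop on site {a!r} is not allowed")
        if a not in index:
            raise ValueError(f"edge endpoint {a!r} not in site_ids")
        if b not in index:
            raise ValueError(f"edge endpoint {b!r} not in site_ids")
        i, j = index[a], index[b]
        N[i, j] = N[j, i] = 1.0
    return _lattice_from_adjacency(N, site_ids, centroids)


def _lattice_from_adjacency(
    N: np.ndarray, site_ids: Sequence[Hashable], centroids: np.ndarray | None = None
) -> Lattice:
    N = np.asarray(N, dtype=float)
    if N.shape != (len(site_ids), len(site_ids)):
        raise ValueError("adjacency shape does not match number of sites")
    if np.any(np.diag(N) != 0):
        raise ValueError("adjacency has nonzero diagonal (self-loops)")
    if not np.array_equal(N, N.T):
        warnings.warn("asymmetric adjacency: symmetrizing with logical OR", stacklevel=3)
        N = np.maximum(N, N.T)
    if not np.isin(N, (0.0, 1.0)).all():
        raise ValueError("adjacency entries must be 0 or 1")
    eigvals_raw, eigvecs = np.linalg.eigh(N)
    chi_max = eigvals_raw[-1]
    if chi_max > 0:
        Ns = N / chi_max
        eigvals = np.sort(eigvals_raw / chi_max)
    else:  # edgeless lattice: sites behave as independent Gaussians
        Ns = N.copy()
        eigvals = np.zeros(len(site_ids))
    if centroids is not None:
        centroids = np.asarray(centroids, dtype=float)
        if centroids.shape != (len(site_ids), 2):
            raise ValueError("centroids must be (n, 2)")
    return Lattice(
        site_ids=tuple(site_ids),
        n=len(site_ids),
        N_raw=N,
        N_scaled=Ns,
        eigvals=eigvals,
        eigvecs=eigvecs,
        centroids=centroids,
    )


def car_conditional_mean(
    X: np.ndarray,
    alpha: np.ndarray,
    car: CARSpec,
    lattice: Lattice,
    site_index: int,
) -> float:
    """Conditional mean of site ``site_index`` given the rest of the field.

    mu_i = alpha_i + zeta * sum_j w_ij (X_j - alpha_j) with weights w_ij the
    entries of the scaled adjacency.
    """
    X = np.asarray(X, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if X.shape != (lattice.n,) or alpha.shape != (lattice.n,):
        raise ValueError("X and alpha must be length-n vectors")
    if not 0 <= site_index < lattice.n:
        raise IndexError(f"site_index {site_index} out of range for n={lattice.n}")
    car.validate(lattice)
    dev = X - alpha
    return float(alpha[site_index] + car.zeta * lattice.N_scaled[site_index] @ dev)


def log_det_car_precision(lattice: Lattice, car: CARSpec, T: int) -> float:
    """Log-determinant of the T-block CAR precision via adjacency eigenvalues.

    Each time block has precision ``(I - zeta*N_scaled)/sigma2``, so the total
    is ``T * (-n log sigma2 + sum_j log(1 - zeta chi_j))``.
    """
    if T < 1:
        raise ValueError("T must be a positive integer")
    margins = 1.0 - car.zeta * lattice.eigvals
    if np.any(margins <= 0):
        raise ValueError("CAR precision not positive definite for this (zeta, lattice)")
    return float(T * (-lattice.n * np.log(car.sigma2) + np.log(margins).sum()))


def car_marginal_variances(lattice: Lattice, car: CARSpec) -> np.ndarray:
    """Sitewise marginal variances diag((I - zeta*N_scaled)^{-1}) * sigma2."""
    car.validate(lattice)
    inv_marg = 1.0 / (1.0 - car.zeta * _eigvals_unsorted(lattice))
    V = lattice.eigvecs
    return car.sigma2 * np.einsum("ij,j,ij->i", V, inv_marg, V)


def _eigvals_unsorted(lattice: Lattice) -> np.ndarray:
    # eigvecs columns match the raw (unsorted-by-us) eigh output order, which is
    # ascending already; eigvals was re-sorted after scaling but scaling is
    # monotone for chi_max > 0, so the orders coincide.
    return lattice.eigvals


def sample_car_field(
    lattice: Lattice,
    alpha: np.ndarray,
    car: CARSpec,
    seed: int | np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw from Gau(alpha, (I - zeta*N_scaled)^{-1} sigma2).

    Returns an (n,) vector, or an (n, size) matrix when *size* is given.
    Identical seeds give identical draws.
    """
    car.validate(lattice)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (lattice.n,):
        raise ValueError("alpha must be a length-n vector")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = 1 if size is None else int(size)
    z = rng.standard_normal((lattice.n, k))
    scale = np.sqrt(car.sigma2 / (1.0 - car.zeta * _eigvals_unsorted(lattice)))
    draws = lattice.eigvecs @ (scale[:, None] * z) + alpha[:, None]
    return draws[:, 0] if size is None else draws
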