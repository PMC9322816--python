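"""The SPINGARCH(1,1) generative process.

Counts are conditionally Poisson with intensity following the stochastic
difference equation

    lambda_t = exp(X_t + eps_t) + eta * Y_{t-1} + kappa * lambda_{t-1},

where X_t is a CAR Gaussian field around the covariate baseline alpha_t and
eps_t is i.i.d. Gaussian noise.  With eta = kappa = 0 and no spatial field the
process reduces to independent lognormal-mixed Poisson counts; with zeta = 0
and sigma = 0 it reduces to the classical INGARCH(1,1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .lattice import CARSpec, Lattice, sample_car_field

__all__ = [
    "ModelParams",
    "CountPanel",
    "IntensityPath",
    "LatentPath",
    "step_intensity",
    "simulate",
    "stationarity_margin",
    "stationary_mean_homogeneous",
]


@dataclass
class ModelParams:
    """Full parameter set theta = (eta, kappa, sigma, sigma_eps, zeta) plus baseline.

    ``alpha`` is the (n, T) log-scale baseline panel; a scalar or (n,) /(T,)
    array is broadcast when the shape is supplied at validation time.
    """

    eta: float
    kappa: float
    sigma: float
    sigma_eps: float
    zeta: float
    alpha: np.ndarray

    def __post_init__(self) -> None:
        for name in ("eta", "kappa", "sigma", "sigma_eps"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.eta + self.kappa >= 1:
            raise ValueError(
                f"stationarity violated: eta + kappa = {self.eta + self.kappa} >= 1"
            )
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("alpha must be finite")

    def alpha_panel(self, n: int, T: int) -> np.ndarray:
        """Broadcast ``alpha`` to an (n, T) panel."""
        a = self.alpha
        if a.ndim == 0:
            return np.full((n, T), float(a))
        if a.shape == (n, T):
            return a
        if a.shape == (n,) or a.shape == (n, 1):
            return np.broadcast_to(a.reshape(n, 1), (n, T)).copy()
        if a.shape == (T,) or a.shape == (1, T):
            return np.broadcast_to(a.reshape(1, T), (n, T)).copy()
        raise ValueError(f"alpha shape {a.shape} not broadcastable to ({n}, {T})")

    def car_spec(self) -> CARSpec:
        if self.sigma <= 0:
            raise ValueError("no CAR spec for sigma = 0 (degenerate latent field)")
        return CARSpec(zeta=self.zeta, sigma2=self.sigma**2)


@dataclass
class CountPanel:
    """Observed counts: (n, T) non-negative integers."""

    Y: np.ndarray
    site_ids: tuple
    time_index: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-D (sites x times)")
        if np.any(self.Y < 0) or not np.issubdtype(self.Y.dtype, np.integer):
            if not np.all(np.mod(self.Y, 1) == 0) or np.any(self.Y < 0):
                raise ValueError("counts must be non-negative integers")
            self.Y = self.Y.astype(np.int64)
        self.site_ids = tuple(self.site_ids)
        if len(self.site_ids) != self.Y.shape[0]:
            raise ValueError("site_ids length does not match Y rows")
        if self.time_index is None:
            self.time_index = np.arange(1, self.Y.shape[1] + 1)
        else:
            self.time_index = np.asarray(self.time_index)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def T(self) -> int:
        return self.Y.shape[1]


@dataclass
class IntensityPath:
    """Intensity panel lambda (n, T) and its initial value lam0 (n,)."""

    lam: np.ndarray
    lam0: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.lam0 = np.asarray(self.lam0, dtype=float)
        if np.any(self.lam <= 0) or not np.all(np.isfinite(self.lam)):
            raise ValueError("intensities must be strictly positive and finite")
        if np.any(self.lam0 <= 0) or not np.all(np.isfinite(self.lam0)):
            raise ValueError("lam0 must be strictly positive and finite")


@dataclass
class LatentPath:
    """Latent CAR field X, i.i.d. noise eps, and their sum U = X + eps."""

    X: np.ndarray
    eps: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if not np.allclose(self.U, self.X + self.eps, atol=1e-12, rtol=0):
            raise ValueError("U must equal X + eps elementwise")


def step_intensity(
    lam_prev: np.ndarray,
    Y_prev: np.ndarray,
    U_t: np.ndarray,
    eta: float,
    kappa: float,
) -> np.ndarray:
    """One step of the intensity recursion: exp(U_t) + eta*Y_prev + kappa*lam_prev."""
    lam_prev = np.asarray(lam_prev, dtype=float)
    Y_prev = np.asarray(Y_prev, dtype=float)
    U_t = np.asarray(U_t, dtype=float)
    if not np.all(np.isfinite(U_t)):
        raise ValueError("U_t must be finite")
    if np.any(lam_prev <= 0):
        raise ValueError("lam_prev must be strictly positive")
    if np.any(Y_prev < 0):
        raise ValueError("Y_prev must be non-negative")
    return np.exp(U_t) + eta * Y_prev + kappa * lam_prev


def stationarity_margin(eta: float, kappa: float) -> float:
    """1 - eta - kappa; positive iff the process has a finite long-run mean."""
    if eta < 0 or kappa < 0:
        raise ValueError("eta and kappa must be >= 0")
    return 1.0 - eta - kappa


def stationary_mean_homogeneous(
    alpha_const: float, sigma_eps: float, eta: float, kappa: float
) -> float:
    """Long-run mean exp(alpha + sigma_eps^2/2) / (1 - eta - kappa).

    Valid for a spatially homogeneous process with no CAR variability
    (sigma = 0) and constant baseline.
    """
    margin = stationarity_margin(eta, kappa)
    if margin <= 0:
        raise ValueError("eta + kappa >= 1: no stationary mean")
    return float(np.exp(alpha_const + sigma_eps**2 / 2.0) / margin)


def default_lam0(alpha_first: np.ndarray, sigma_eps: float, eta: float, kappa: float) -> np.ndarray:
    """Default initial intensity: homogeneous stationary mean at each site's first baseline."""
    margin = stationarity_margin(eta, kappa)
    if margin <= 0:
        raise ValueError("eta + kappa >= 1: cannot initialize at stationarity")
    return np.exp(np.asarray(alpha_first, dtype=float) + sigma_eps**2 / 2.0) / margin


def simulate(
    params: ModelParams,
    lattice: Lattice,
    T: int,
    seed: int | np.random.Generator,
    lam0_policy: Literal["stationary", "constant"] = "stationary",
    lam0_value: float | None = None,
) -> tuple[CountPanel, IntensityPath, LatentPath]:
    """Simulate the full hierarchy for T periods.

    For each t: X_t ~ CAR(alpha_t), eps_t ~ N(0, sigma_eps^2) i.i.d., lambda_t
    from the recursion, Y_t ~ Poisson(lambda_t) sitewise.  The pre-sample state
    is lambda_0 from *lam0_policy* and Y_0 = 0.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    n = lattice.n
    alpha = params.alpha_panel(n, T)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if lam0_policy == "stationary":
        lam0 = default_lam0(alpha[:, 0], params.sigma_eps, params.eta, params.kappa)
    elif lam0_policy == "constant":
        if lam0_value is None or lam0_value <= 0:
            raise ValueError("lam0_policy='constant' requires a positive lam0_value")
        lam0 = np.full(n, float(lam0_value))
    else:
        raise ValueError(f"unknown lam0_policy: {lam0_policy!r}")

    car = params.car_spec() if params.sigma > 0 else None
    X = np.empty((n, T))
    eps = np.empty((n, T))
    lam = np.empty((n, T))
    Y = np.empty((n, T), dtype=np.int64)

    lam_prev = lam0
    Y_prev = np.zeros(n)
    for t in range(T):
        if car is not None:
            X[:, t] = sample_car_field(lattice, alpha[:, t], car, rng)
        else:
            X[:, t] = alpha[:, t]
        eps[:, t] = rng.normal(0.0, params.sigma_eps, size=n) if params.sigma_eps > 0 else 0.0
        lam[:, t] = step_intensity(lam_prev, Y_prev, X[:, t] + eps[:, t], params.eta, params.kappa)
        Y[:, t] = rng.poisson(lam[:, t])
        lam_prev = lam[:, t]
        Y_prev = Y[:, t]

    counts = CountPanel(Y=Y, site_ids=lattice.site_ids)
    return counts, IntensityPath(lam=lam, lam0=lam0), LatentPath(X=X, eps=eps, U=X + eps)
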