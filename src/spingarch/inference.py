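"""Priors, log-densities, and the data-augmented MCMC sampler.

The posterior over theta = (eta, kappa, sigma, sigma_eps) and the latent
fields factorizes as Poisson likelihood x latent Gaussian density x priors.
The sampler is an adaptive random-walk Metropolis-within-Gibbs:

* (eta, kappa) move jointly on additive-logistic coordinates of the open
  triangle {eta > 0, kappa > 0, eta + kappa < 1};
* sigma and sigma_eps move on the log scale;
* the latent state U = X + eps is updated sitewise by time slice - a
  noise-side random walk on eps, a CAR-side random walk on X over graph-color
  classes (sites in one color class share no edge, so simultaneous sitewise
  acceptance is exact), and an exact Gibbs redistribution of X given U that
  decouples the two variance components.

Proposal scales adapt by Robbins-Monro during burn-in only, so the retained
chain targets the exact posterior.  zeta is fixed by default (0.99) and can
optionally be sampled with a uniform prior on its valid interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.linalg import cholesky, solve_triangular
from scipy.signal import lfilter
from scipy.special import betaln, gammaln
from scipy.stats import beta as beta_dist

from .lattice import CARSpec, Lattice, log_det_car_precision
from .model import CountPanel, IntensityPath, LatentPath, ModelParams, default_lam0

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "PosteriorDraws",
    "log_prior",
    "log_latent_density",
    "log_likelihood_counts",
    "log_posterior",
    "reconstruct_intensity",
    "run_mcmc",
]


# --------------------------------------------------------------------------- #
# priors
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class PriorSpec:
    """Beta priors for (eta, kappa) restricted to {eta+kappa<1}, half-Cauchy scales."""

    eta_beta: tuple[float, float] = (2.0, 2.0)
    kappa_beta: tuple[float, float] = (2.0, 2.0)
    sigma_cauchy_scale: float = 2.5
    sigma_eps_cauchy_scale: float = 2.5

    def __post_init__(self) -> None:
        for h in (*self.eta_beta, *self.kappa_beta, self.sigma_cauchy_scale,
                  self.sigma_eps_cauchy_scale):
            if not h > 0:
                raise ValueError("all prior hyperparameters must be > 0")


_TRIANGLE_NORM_CACHE: dict[tuple, float] = {}


def _triangle_log_norm(eta_ab: tuple[float, float], kappa_ab: tuple[float, float]) -> float:
    """log P(B_eta + B_kappa < 1) for independent Beta variables (truncation constant)."""
    key = (eta_ab, kappa_ab)
    if key not in _TRIANGLE_NORM_CACHE:
        a2, b2 = kappa_ab
        z, _ = quad(
            lambda k: beta_dist.pdf(k, a2, b2) * beta_dist.cdf(1.0 - k, *eta_ab),
            0.0, 1.0, limit=200,
        )
        _TRIANGLE_NORM_CACHE[key] = float(np.log(z))
    return _TRIANGLE_NORM_CACHE[key]


def _beta_logpdf(x: float, a: float, b: float) -> float:
    # scipy's beta.logpdf has ~50us of dispatch overhead; this is the hot path
    if not 0.0 < x < 1.0:
        return -np.inf
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)


def _log_half_cauchy(x: float, scale: float) -> float:
    if x < 0:
        return -np.inf
    return float(np.log(2.0 / (np.pi * scale * (1.0 + (x / scale) ** 2))))


def log_prior(theta: ModelParams, priors: PriorSpec) -> float:
    """Joint log-prior of (eta, kappa, sigma, sigma_eps); -inf outside the support."""
    eta, kappa = theta.eta, theta.kappa
    if not (0 <= eta <= 1 and 0 <= kappa <= 1 and eta + kappa < 1):
        return -np.inf
    lp = float(
        beta_dist.logpdf(eta, *priors.eta_beta)
        + beta_dist.logpdf(kappa, *priors.kappa_beta)
        - _triangle_log_norm(priors.eta_beta, priors.kappa_beta)
    )
    lp += _log_half_cauchy(theta.sigma, priors.sigma_cauchy_scale)
    lp += _log_half_cauchy(theta.sigma_eps, priors.sigma_eps_cauchy_scale)
    return lp


# --------------------------------------------------------------------------- #
# log-densities
# --------------------------------------------------------------------------- #

def log_latent_density(
    latent: LatentPath, alpha: np.ndarray, theta: ModelParams, lattice: Lattice
) -> float:
    """Sum over t of the CAR log-density of X_t around alpha_t plus the
    i.i.d. Gaussian log-density of eps_t."""
    X, eps = latent.X, latent.eps
    n, T = X.shape
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (n, T):
        raise ValueError("alpha must match the latent panel shape")

    total = 0.0
    if theta.sigma > 0:
        car = CARSpec(zeta=theta.zeta, sigma2=theta.sigma**2)
        logdet = log_det_car_precision(lattice, car, T)
        dev = X - alpha
        quad_form = (
            np.sum(dev * dev) - theta.zeta * np.sum(dev * (lattice.N_scaled @ dev))
        ) / theta.sigma**2
        total += -0.5 * n * T * np.log(2 * np.pi) + 0.5 * logdet - 0.5 * quad_form
    elif not np.allclose(X, alpha):
        return -np.inf

    if theta.sigma_eps > 0:
        total += float(
            -0.5 * n * T * np.log(2 * np.pi * theta.sigma_eps**2)
            - np.sum(eps**2) / (2 * theta.sigma_eps**2)
        )
    elif np.any(eps != 0):
        return -np.inf
    return float(total)


def log_likelihood_counts(Y: CountPanel | np.ndarray, lam: IntensityPath | np.ndarray) -> float:
    """Poisson log-likelihood summed over all panel cells."""
    Yv = Y.Y if isinstance(Y, CountPanel) else np.asarray(Y)
    lv = lam.lam if isinstance(lam, IntensityPath) else np.asarray(lam, dtype=float)
    if Yv.shape != lv.shape:
        raise ValueError("count and intensity panels must have the same shape")
    if np.any(lv <= 0) or not np.all(np.isfinite(lv)):
        raise ValueError("intensities must be strictly positive and finite")
    return float(np.sum(Yv * np.log(lv) - lv - gammaln(Yv + 1.0)))


def reconstruct_intensity(
    U: np.ndarray, Y: np.ndarray, eta: float, kappa: float, lam0: np.ndarray
) -> np.ndarray:
    """Deterministic intensity panel from the latent field and observed counts.

    Uses the model convention Y_0 = 0, lambda_0 = *lam0*.
    """
    n, T = U.shape
    x = np.exp(U)
    if eta != 0:
        x = x.copy()
        x[:, 1:] += eta * Y[:, :-1]
    if kappa == 0:
        return x if eta != 0 else x.copy()
    # lambda_t = x_t + kappa * lambda_{t-1}: a first-order IIR filter along time
    zi = (kappa * np.asarray(lam0, dtype=float))[:, None]
    lam, _ = lfilter([1.0], [1.0, -kappa], x, axis=1, zi=zi)
    return lam


def log_posterior(
    Y: CountPanel,
    latent: LatentPath,
    alpha: np.ndarray,
    theta: ModelParams,
    lattice: Lattice,
    priors: PriorSpec,
    lam0: np.ndarray | None = None,
) -> float:
    """Assembly identity: log_prior + log_latent_density + log_likelihood_counts."""
    lp = log_prior(theta, priors)
    if not np.isfinite(lp):
        return -np.inf
    ld = log_latent_density(latent, alpha, theta, lattice)
    if not np.isfinite(ld):
        return -np.inf
    if lam0 is None:
        lam0 = default_lam0(alpha[:, 0], theta.sigma_eps, theta.eta, theta.kappa)
    lam = reconstruct_intensity(latent.U, Y.Y, theta.eta, theta.kappa, lam0)
    return lp + ld + log_likelihood_counts(Y.Y, lam)


# --------------------------------------------------------------------------- #
# chain configuration and output container
# --------------------------------------------------------------------------- #

@dataclass
class ChainConfig:
    n_chains: int = 3
    n_iter: int = 70_000
    burn_in: int = 10_000
    thin: int = 100
    seed: int = 0
    zeta_fixed: float = 0.99
    sample_zeta: bool = False
    fix_params: Mapping[str, float] = field(default_factory=dict)
    lam0_policy: str = "stationary"
    lam0_value: float | None = None
    target_accept_scalar: float = 0.3
    target_accept_sitewise: float = 0.44
    progress: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        bad = set(self.fix_params) - {"eta", "kappa", "sigma", "sigma_eps"}
        if bad:
            raise ValueError(f"unknown fixed parameters: {sorted(bad)}")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with chain labels.

    ``draws`` is (R, P) across all chains; tau is the CAR precision 1/sigma^2.
    """

    draws: np.ndarray
    param_names: tuple
    chain_id: np.ndarray
    iteration: np.ndarray
    logpost: np.ndarray
    config: ChainConfig

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    def by_chain(self, name: str) -> list[np.ndarray]:
        col = self.column(name)
        return [col[self.chain_id == c] for c in np.unique(self.chain_id)]

    def posterior_mean(self, name: str) -> float:
        return float(np.mean(self.column(name)))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df.insert(0, "iter", self.iteration)
        df.insert(0, "chain", self.chain_id)
        df["logpost"] = self.logpost
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: ChainConfig | None = None):
        names = tuple(c for c in df.columns if c not in ("chain", "iter", "logpost"))
        return cls(
            draws=df[list(names)].to_numpy(float),
            param_names=names,
            chain_id=df["chain"].to_numpy(int),
            iteration=df["iter"].to_numpy(int),
            logpost=df["logpost"].to_numpy(float)
            if "logpost" in df
            else np.full(len(df), np.nan),
            config=config or ChainConfig(n_iter=2, burn_in=0, thin=1),
        )


# --------------------------------------------------------------------------- #
# sampler internals
# --------------------------------------------------------------------------- #

def _greedy_coloring(N_raw: np.ndarray) -> list[np.ndarray]:
    """Proper vertex coloring (largest-first greedy); rook grids give 2 colors."""
    n = N_raw.shape[0]
    order = np.argsort(-N_raw.sum(axis=1), kind="stable")
    colors = np.full(n, -1, dtype=int)
    for v in order:
        used = {colors[u] for u in np.nonzero(N_raw[v])[0] if colors[u] >= 0}
        c = 0
        while c in used:
            c += 1
        colors[v] = c
    return [np.nonzero(colors == c)[0] for c in range(colors.max() + 1)]


class _ChainState:
    """Mutable per-chain state; all heavy arrays are (n, T)."""

    def __init__(self, Y, alpha, lattice, priors, config, rng):
        self.Y = Y
        self.alpha = alpha
        self.lattice = lattice
        self.priors = priors
        self.cfg = config
        self.rng = rng
        self.n, self.T = Y.shape
        fx = config.fix_params

        self.eta = float(fx.get("eta", rng.uniform(0.05, 0.4)))
        self.kappa = float(fx.get("kappa", rng.uniform(0.05, min(0.4, 0.9 - self.eta))))
        self.sigma = float(fx.get("sigma", rng.uniform(0.3, 1.2)))
        self.sigma_eps = float(fx.get("sigma_eps", rng.uniform(0.3, 1.2)))
        self.zeta = float(config.zeta_fixed)
        self.spatial = self.sigma > 0

        # latent state: start X at the baseline, eps aimed at the observed counts
        target = np.log(Y + 0.5)
        if self.sigma_eps > 0:
            self.X = alpha.copy()
            if self.spatial:
                self.X += 0.1 * rng.standard_normal((self.n, self.T))
            self.eps = np.clip(target - self.X, -3.0, 3.0)
        else:
            # degenerate noise layer: eps pinned at zero
            self.X = (
                alpha + np.clip(target - alpha, -3.0, 3.0)
                if self.spatial
                else alpha.copy()
            )
            self.eps = np.zeros((self.n, self.T))
        self.U = self.X + self.eps
        self.lam = self._recompute_lam()

        self.colors = _greedy_coloring(lattice.N_raw) if self.spatial else []
        self.T_minus = np.arange(self.T, 0, -1)  # T_minus[t] = T - t
        # adaptive proposal scales
        self.s_ek = 0.15
        self.s_sig = 0.3
        self.s_sige = 0.2
        self.s_zeta = 0.5
        self.S_eps = np.full((self.n, self.T), 0.5)
        self.S_x = np.full((self.n, self.T), 0.5)

        if config.sample_zeta:
            chi = lattice.eigvals
            lo = 1.0 / chi.min() if chi.min() < 0 else -1e6
            self.zeta_bounds = (lo + 1e-9, 1.0 - 1e-9)

    # -- bookkeeping ------------------------------------------------------- #

    def _lam0(self, eta=None, kappa=None, sigma_eps=None):
        eta = self.eta if eta is None else eta
        kappa = self.kappa if kappa is None else kappa
        sigma_eps = self.sigma_eps if sigma_eps is None else sigma_eps
        if self.cfg.lam0_policy == "constant":
            return np.full(self.n, float(self.cfg.lam0_value))
        return default_lam0(self.alpha[:, 0], sigma_eps, eta, kappa)

    def _recompute_lam(self, eta=None, kappa=None, sigma_eps=None):
        eta = self.eta if eta is None else eta
        kappa = self.kappa if kappa is None else kappa
        return reconstruct_intensity(
            self.U, self.Y, eta, kappa, self._lam0(eta, kappa, sigma_eps)
        )

    def loglik(self, lam=None) -> float:
        lam = self.lam if lam is None else lam
        return float(np.sum(self.Y * np.log(lam) - lam))

    def quad_terms(self) -> tuple[float, float]:
        dev = self.X - self.alpha
        qI = float(np.sum(dev * dev))
        qN = float(np.sum(dev * (self.lattice.N_scaled @ dev)))
        return qI, qN

    def theta(self) -> ModelParams:
        return ModelParams(
            eta=self.eta, kappa=self.kappa, sigma=self.sigma,
            sigma_eps=self.sigma_eps, zeta=self.zeta, alpha=self.alpha,
        )

    def _log_prior_free(self) -> float:
        """Prior over the *sampled* parameters only; fixed ones are conditioning
        constants and may sit on the boundary of their prior support."""
        fx = self.cfg.fix_params
        pri = self.priors
        lp = 0.0
        eta_free, kappa_free = "eta" not in fx, "kappa" not in fx
        if eta_free and kappa_free:
            lp += float(
                _beta_logpdf(self.eta, *pri.eta_beta)
                + _beta_logpdf(self.kappa, *pri.kappa_beta)
                - _triangle_log_norm(pri.eta_beta, pri.kappa_beta)
            )
        elif eta_free:
            lp += float(_beta_logpdf(self.eta, *pri.eta_beta))
        elif kappa_free:
            lp += float(_beta_logpdf(self.kappa, *pri.kappa_beta))
        if "sigma" not in fx and self.spatial:
            lp += _log_half_cauchy(self.sigma, pri.sigma_cauchy_scale)
        if "sigma_eps" not in fx:
            lp += _log_half_cauchy(self.sigma_eps, pri.sigma_eps_cauchy_scale)
        return lp

    def log_posterior_full(self) -> float:
        latent = LatentPath(X=self.X, eps=self.eps, U=self.U)
        ld = log_latent_density(latent, self.alpha, self.theta(), self.lattice)
        if not np.isfinite(ld):
            return -np.inf
        lam = self._recompute_lam()
        Yp = CountPanel(Y=self.Y, site_ids=self.lattice.site_ids)
        return self._log_prior_free() + ld + log_likelihood_counts(Yp.Y, lam)

    # -- parameter blocks --------------------------------------------------- #

    def update_eta_kappa(self, adapt_gamma):
        fx = self.cfg.fix_params
        eta_free = "eta" not in fx
        kappa_free = "kappa" not in fx
        if not (eta_free or kappa_free):
            return
        pri = self.priors

        if eta_free and kappa_free:
            # joint move on additive-logistic coordinates of the open triangle
            rest = 1.0 - self.eta - self.kappa
            u = np.array([np.log(self.eta / rest), np.log(self.kappa / rest)])
            up = u + self.s_ek * self.rng.standard_normal(2)
            e = np.exp(np.concatenate((up, [0.0])) - max(up.max(), 0.0))
            e /= e.sum()
            eta_p, kappa_p, rest_p = float(e[0]), float(e[1]), float(e[2])
            d_prior = (
                _beta_logpdf(eta_p, *pri.eta_beta)
                - _beta_logpdf(self.eta, *pri.eta_beta)
                + _beta_logpdf(kappa_p, *pri.kappa_beta)
                - _beta_logpdf(self.kappa, *pri.kappa_beta)
                + np.log(eta_p * kappa_p * rest_p)
                - np.log(self.eta * self.kappa * rest)
            )
        else:
            # one coordinate fixed: logit walk on the free one over (0, 1 - fixed)
            if eta_free:
                free, fixed, ab = self.eta, self.kappa, pri.eta_beta
            else:
                free, fixed, ab = self.kappa, self.eta, pri.kappa_beta
            width = 1.0 - fixed
            w = np.log(free / (width - free))
            wp = w + self.s_ek * self.rng.standard_normal()
            free_p = width / (1.0 + np.exp(-wp))
            d_prior = (
                _beta_logpdf(free_p, *ab)
                - _beta_logpdf(free, *ab)
                + np.log(free_p * (width - free_p))
                - np.log(free * (width - free))
            )
            eta_p = free_p if eta_free else self.eta
            kappa_p = self.kappa if eta_free else free_p

        lam_p = self._recompute_lam(eta=eta_p, kappa=kappa_p)
        delta = self.loglik(lam_p) - self.loglik() + d_prior
        acc = min(1.0, float(np.exp(min(delta, 50.0)))) if np.isfinite(delta) else 0.0
        if self.rng.random() < acc:
            self.eta, self.kappa = eta_p, kappa_p
            self.lam = lam_p
        if adapt_gamma is not None:
            self.s_ek *= np.exp(adapt_gamma * (acc - self.cfg.target_accept_scalar))

    def update_sigma(self, adapt_gamma):
        if not self.spatial or "sigma" in self.cfg.fix_params:
            return
        w = np.log(self.sigma)
        wp = w + self.s_sig * self.rng.standard_normal()
        sig_p = float(np.exp(wp))
        qI, qN = self.quad_terms()
        quad_form = qI - self.zeta * qN
        nT = self.n * self.T
        delta = (
            -nT * (wp - w)
            - quad_form / 2.0 * (1.0 / sig_p**2 - 1.0 / self.sigma**2)
            + _log_half_cauchy(sig_p, self.priors.sigma_cauchy_scale)
            - _log_half_cauchy(self.sigma, self.priors.sigma_cauchy_scale)
            + (wp - w)  # log-scale Jacobian
        )
        acc = min(1.0, float(np.exp(min(delta, 50.0)))) if np.isfinite(delta) else 0.0
        if self.rng.random() < acc:
            self.sigma = sig_p
        if adapt_gamma is not None:
            self.s_sig *= np.exp(adapt_gamma * (acc - self.cfg.target_accept_scalar))

    def update_sigma_eps(self, adapt_gamma):
        if "sigma_eps" in self.cfg.fix_params:
            return
        w = np.log(self.sigma_eps)
        wp = w + self.s_sige * self.rng.standard_normal()
        se_p = float(np.exp(wp))
        nT = self.n * self.T
        sum_eps2 = float(np.sum(self.eps**2))
        lam_p = self._recompute_lam(sigma_eps=se_p)
        delta = (
            self.loglik(lam_p) - self.loglik()
            - nT * (wp - w)
            - sum_eps2 / 2.0 * (1.0 / se_p**2 - 1.0 / self.sigma_eps**2)
            + _log_half_cauchy(se_p, self.priors.sigma_eps_cauchy_scale)
            - _log_half_cauchy(self.sigma_eps, self.priors.sigma_eps_cauchy_scale)
            + (wp - w)
        )
        acc = min(1.0, float(np.exp(min(delta, 50.0)))) if np.isfinite(delta) else 0.0
        if self.rng.random() < acc:
            self.sigma_eps = se_p
            self.lam = lam_p
        if adapt_gamma is not None:
            self.s_sige *= np.exp(adapt_gamma * (acc - self.cfg.target_accept_scalar))

    def update_zeta(self, adapt_gamma):
        if not (self.cfg.sample_zeta and self.spatial):
            return
        lo, hi = self.zeta_bounds
        w = np.log((self.zeta - lo) / (hi - self.zeta))
        wp = w + self.s_zeta * self.rng.standard_normal()
        zeta_p = lo + (hi - lo) / (1.0 + np.exp(-wp))
        _, qN = self.quad_terms()
        margins_p = 1.0 - zeta_p * self.lattice.eigvals
        margins = 1.0 - self.zeta * self.lattice.eigvals
        delta = (
            0.5 * self.T * float(np.sum(np.log(margins_p)) - np.sum(np.log(margins)))
            + (zeta_p - self.zeta) * qN / (2.0 * self.sigma**2)
            # uniform prior; logit Jacobian:
            + np.log((zeta_p - lo) * (hi - zeta_p))
            - np.log((self.zeta - lo) * (hi - self.zeta))
        )
        acc = min(1.0, float(np.exp(min(delta, 50.0)))) if np.isfinite(delta) else 0.0
        if self.rng.random() < acc:
            self.zeta = float(zeta_p)
        if adapt_gamma is not None:
            self.s_zeta *= np.exp(adapt_gamma * (acc - self.cfg.target_accept_scalar))

    # -- latent blocks ------------------------------------------------------ #

    def _tail_length(self, t: int) -> int:
        """Effective propagation horizon of a change at time t.

        The shift decays as kappa^(s-t); beyond relative size 1e-14 it is below
        floating-point resolution of the acceptance ratio.
        """
        Tt = self.T - t
        if self.kappa <= 0:
            return 1
        m = int(np.ceil(-14.0 * np.log(10.0) / np.log(self.kappa))) + 1
        return min(Tt, max(m, 1))

    def _tail_loglik_delta(self, t: int, m: int, delta_exp: np.ndarray):
        """Per-site change in Poisson log-likelihood when exp(U_t) changes by delta_exp."""
        kpow = self.kappa ** np.arange(m)  # 0**0 == 1, so kappa=0 is handled
        lam_tail = self.lam[:, t: t + m]
        shift = delta_exp[:, None] * kpow[None, :]
        lam_new = lam_tail + shift
        Yt = self.Y[:, t: t + m]
        with np.errstate(divide="ignore", invalid="ignore"):
            dlog = np.where(Yt > 0, Yt * np.log(lam_new / lam_tail), 0.0)
        out = dlog.sum(axis=1) - delta_exp * ((1.0 - self.kappa**self.T_minus[t]) /
                                              (1.0 - self.kappa)
                                              if 0 < self.kappa < 1 else 1.0)
        bad = lam_new.min(axis=1) <= 0  # exp > 0 makes this impossible; numeric guard
        if bad.any():
            out[bad] = -np.inf
        return out, shift

    def _apply_tail(self, t, m, accept_mask, shift):
        self.lam[accept_mask, t: t + m] += shift[accept_mask]

    def update_latent_slice(self, t: int, adapt_gamma, z_eps, logu_eps, z_x, logu_x):
        n = self.n
        target = self.cfg.target_accept_sitewise
        m = self._tail_length(t)

        # noise-side move: eps changes, X fixed
        if self.sigma_eps > 0:
            delta = self.S_eps[:, t] * z_eps
            eps_t = self.eps[:, t]
            d_prior = -((eps_t + delta) ** 2 - eps_t**2) / (2.0 * self.sigma_eps**2)
            delta_exp = np.exp(self.U[:, t] + delta) - np.exp(self.U[:, t])
            d_lik, shift = self._tail_loglik_delta(t, m, delta_exp)
            log_acc = np.minimum(0.0, d_prior + d_lik)
            accept = logu_eps < log_acc
            if accept.any():
                self.eps[accept, t] += delta[accept]
                self.U[accept, t] += delta[accept]
                self._apply_tail(t, m, accept, shift)
            if adapt_gamma is not None:
                self.S_eps[:, t] *= np.exp(adapt_gamma * (np.exp(log_acc) - target))

        # CAR-side move: X changes (and therefore U), per color class
        if self.spatial:
            dev = self.X[:, t] - self.alpha[:, t]
            for color in self.colors:
                g = (dev - self.zeta * (self.lattice.N_scaled @ dev)) / self.sigma**2
                delta = np.zeros(n)
                delta[color] = self.S_x[color, t] * z_x[color]
                d_prior = -delta * g - delta**2 / (2.0 * self.sigma**2)
                delta_exp = np.zeros(n)
                delta_exp[color] = np.exp(self.U[color, t] + delta[color]) - np.exp(
                    self.U[color, t]
                )
                d_lik, shift = self._tail_loglik_delta(t, m, delta_exp)
                log_acc = np.minimum(0.0, d_prior + d_lik)
                accept = np.zeros(n, dtype=bool)
                accept[color] = logu_x[color] < log_acc[color]
                if accept.any():
                    self.X[accept, t] += delta[accept]
                    self.U[accept, t] += delta[accept]
                    dev[accept] += delta[accept]
                    self._apply_tail(t, m, accept, shift)
                if adapt_gamma is not None:
                    self.S_x[color, t] *= np.exp(
                        adapt_gamma * (np.exp(log_acc[color]) - target)
                    )

    def update_latent_panel(self, adapt_gamma, Z_eps, LU_eps, Z_x, LU_x):
        """Whole-panel latent update, valid only when kappa == 0 (then lambda_t
        depends on U_t alone and all cells decouple across time)."""
        target = self.cfg.target_accept_sitewise
        Y = self.Y
        if self.sigma_eps > 0:
            delta = self.S_eps * Z_eps
            d_prior = -((self.eps + delta) ** 2 - self.eps**2) / (2.0 * self.sigma_eps**2)
            lam_new = self.lam + np.exp(self.U + delta) - np.exp(self.U)
            with np.errstate(divide="ignore", invalid="ignore"):
                d_lik = np.where(Y > 0, Y * np.log(lam_new / self.lam), 0.0) - (
                    lam_new - self.lam
                )
            log_acc = np.minimum(0.0, d_prior + d_lik)
            accept = LU_eps < log_acc
            self.eps[accept] += delta[accept]
            self.U[accept] += delta[accept]
            self.lam[accept] = lam_new[accept]
            if adapt_gamma is not None:
                self.S_eps *= np.exp(adapt_gamma * (np.exp(log_acc) - target))
        if self.spatial:
            for color in self.colors:
                dev = self.X - self.alpha
                g = (dev - self.zeta * (self.lattice.N_scaled @ dev)) / self.sigma**2
                delta = self.S_x[color] * Z_x[color]
                d_prior = -delta * g[color] - delta**2 / (2.0 * self.sigma**2)
                lam_new = self.lam[color] + np.exp(self.U[color] + delta) - np.exp(
                    self.U[color]
                )
                Yc = Y[color]
                with np.errstate(divide="ignore", invalid="ignore"):
                    d_lik = np.where(Yc > 0, Yc * np.log(lam_new / self.lam[color]), 0.0
                                     ) - (lam_new - self.lam[color])
                log_acc = np.minimum(0.0, d_prior + d_lik)
                accept = LU_x[color] < log_acc
                rows = np.repeat(color, self.T).reshape(len(color), self.T)[accept]
                cols = np.tile(np.arange(self.T), (len(color), 1))[accept]
                self.X[rows, cols] += delta[accept]
                self.U[rows, cols] += delta[accept]
                self.lam[rows, cols] = lam_new[accept]
                if adapt_gamma is not None:
                    self.S_x[color] *= np.exp(adapt_gamma * (np.exp(log_acc) - target))

    def gibbs_split(self):
        """Exact draw of X | U (and eps = U - X): redistributes the two variance
        components without touching U or the likelihood."""
        if not (self.spatial and self.sigma_eps > 0):
            return
        Q = (np.eye(self.n) - self.zeta * self.lattice.N_scaled) / self.sigma**2
        P = Q + np.eye(self.n) / self.sigma_eps**2
        L = cholesky(P, lower=True)
        rhs = Q @ self.alpha + self.U / self.sigma_eps**2
        mean = solve_triangular(
            L.T, solve_triangular(L, rhs, lower=True), lower=False
        )
        z = self.rng.standard_normal((self.n, self.T))
        self.X = mean + solve_triangular(L.T, z, lower=False)
        self.eps = self.U - self.X


def _run_single_chain(Y, alpha, lattice, priors, config, chain_idx):
    rng = np.random.default_rng([config.seed, chain_idx, 0x5147])
    st = _ChainState(Y, alpha, lattice, priors, config, rng)

    lp0 = st.log_posterior_full()
    if not np.isfinite(lp0):
        raise RuntimeError(
            f"non-finite log-posterior at initialization (chain {chain_idx}): {lp0}"
        )

    R = config.retained_per_chain
    out = np.empty((R, 4))
    logposts = np.empty(R)
    iters = np.empty(R, dtype=int)
    r = 0
    for it in range(1, config.n_iter + 1):
        adapting = it <= config.burn_in
        gamma = 2.0 / max(it, 10) ** 0.6 if adapting else None

        st.update_eta_kappa(gamma)
        st.update_sigma(gamma)
        st.update_sigma_eps(gamma)
        st.update_zeta(gamma)
        # one batched draw per sweep: per-slice rng calls dominate otherwise
        Z_eps = rng.standard_normal((st.n, st.T))
        LU_eps = np.log(rng.random((st.n, st.T)))
        Z_x = rng.standard_normal((st.n, st.T)) if st.spatial else Z_eps
        LU_x = np.log(rng.random((st.n, st.T))) if st.spatial else LU_eps
        if st.kappa == 0.0 and "kappa" in config.fix_params:
            st.update_latent_panel(gamma, Z_eps, LU_eps, Z_x, LU_x)
        else:
            for t in range(st.T):
                st.update_latent_slice(
                    t, gamma, Z_eps[:, t], LU_eps[:, t], Z_x[:, t], LU_x[:, t]
                )
        st.gibbs_split()

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            tau = 1.0 / st.sigma**2 if st.sigma > 0 else np.inf
            out[r] = (st.eta, st.kappa, tau, st.sigma_eps)
            logposts[r] = st.log_posterior_full()
            iters[r] = it
            r += 1
    return out[:r], logposts[:r], iters[:r]


def run_mcmc(
    Y: CountPanel | np.ndarray,
    alpha: np.ndarray,
    lattice: Lattice,
    priors: PriorSpec | None = None,
    config: ChainConfig | None = None,
) -> PosteriorDraws:
    """Run the data-augmented sampler and return thinned post-burn-in draws.

    *alpha* is the precomputed (n, T) log-scale baseline (two-stage pipeline).
    A fixed seed in *config* gives bitwise-identical output.
    """
    priors = priors or PriorSpec()
    config = config or ChainConfig()
    Yv = Y.Y if isinstance(Y, CountPanel) else np.asarray(Y)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != Yv.shape:
        raise ValueError("alpha panel must match the count panel shape")
    if config.lam0_policy == "constant" and (
        config.lam0_value is None or config.lam0_value <= 0
    ):
        raise ValueError("lam0_policy='constant' requires a positive lam0_value")

    chunks, lps, its, cids = [], [], [], []
    for c in range(config.n_chains):
        draws, logposts, iters = _run_single_chain(Yv, alpha, lattice, priors, config, c)
        chunks.append(draws)
        lps.append(logposts)
        its.append(iters)
        cids.append(np.full(len(iters), c))
    return PosteriorDraws(
        draws=np.vstack(chunks),
        param_names=("eta", "kappa", "tau", "sigma_eps"),
        chain_id=np.concatenate(cids),
        iteration=np.concatenate(its),
        logpost=np.concatenate(lps),
        config=config,
    )
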