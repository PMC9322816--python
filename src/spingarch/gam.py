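"""Penalized B-spline additive models turning covariate panels into the baseline alpha_t.

The response panel is fit with a log link as

    g(E[y]) = beta0 + sum_i f_i(x_i),

each smooth f_i built from a B-spline basis (cubic by default, knots at
covariate quantiles) with a second-order difference penalty on the
coefficients; smoothing parameters are chosen by generalized cross-validation
over a log-spaced grid.  The fitted linear predictor is returned on the log
scale as the (n, T) baseline panel.

Row-wise Kronecker tensor-product surfaces over two covariates are provided as
a building block; the default pipeline uses univariate terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import solve
from scipy.stats import chi2

__all__ = [
    "SplineBasis",
    "CovariatePanel",
    "GAMConfig",
    "GAMFit",
    "bspline_basis",
    "tensor_row_kronecker",
    "gcv_score",
    "fit_alpha_gam",
    "predict_alpha",
]


@dataclass
class SplineBasis:
    """A B-spline basis evaluated on a set of points.

    ``knots`` is the full (padded) knot vector; ``B`` has one row per
    evaluation point and one column per basis function.
    """

    knots: np.ndarray
    degree: int
    B: np.ndarray

    @property
    def num_basis(self) -> int:
        return self.B.shape[1]

    @property
    def xmin(self) -> float:
        return float(self.knots[self.degree])

    @property
    def xmax(self) -> float:
        return float(self.knots[len(self.knots) - self.degree - 1])

    def evaluate(self, x: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Evaluate the basis at new points, clamping to the boundary knots."""
        x = np.asarray(x, dtype=float).ravel()
        if clamp:
            lo, hi = self.xmin, self.xmax
            if np.any(x < lo) or np.any(x > hi):
                warnings.warn(
                    "covariate values outside the training range; clamping to boundary knots",
                    stacklevel=2,
                )
            x = np.clip(x, lo, hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()


def bspline_basis(x: np.ndarray, num_basis: int, degree: int = 3) -> SplineBasis:
    """Build a B-spline basis with interior knots at quantiles of *x*.

    ``num_basis`` must be at least ``degree + 1``; the number of interior knots
    is ``num_basis - degree - 1``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if num_basis < degree + 1:
        raise ValueError(f"num_basis must be >= degree+1 = {degree + 1}")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("constant covariate: degenerate knot placement")
    n_interior = num_basis - degree - 1
    if n_interior > 0:
        qs = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
        # quantile ties break the knot sequence; fall back to even spacing
        if np.any(np.diff(np.concatenate(([lo], qs, [hi]))) <= 0):
            qs = np.linspace(lo, hi, n_interior + 2)[1:-1]
        interior = qs
    else:
        interior = np.empty(0)
    knots = np.concatenate((np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)))
    B = BSpline.design_matrix(x, knots, degree).toarray()
    return SplineBasis(knots=knots, degree=degree, B=B)


def tensor_row_kronecker(B1: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product: row i of the result is row_i(B1) kron row_i(B2)."""
    B1 = np.asarray(B1, dtype=float)
    B2 = np.asarray(B2, dtype=float)
    if B1.ndim != 2 or B2.ndim != 2:
        raise ValueError("B1 and B2 must be matrices")
    if B1.shape[0] != B2.shape[0]:
        raise ValueError(f"row-count mismatch: {B1.shape[0]} vs {B2.shape[0]}")
    out = np.einsum("ij,ik->ijk", B1, B2)
    return out.reshape(B1.shape[0], B1.shape[1] * B2.shape[1])


def gcv_score(rss: float, n_obs: int, edf: float) -> float:
    """Generalized cross-validation: n * rss / (n - edf)^2."""
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if edf < 0:
        raise ValueError("edf must be >= 0")
    if edf >= n_obs:
        raise ValueError("edf must be smaller than n_obs")
    return float(n_obs * rss / (n_obs - edf) ** 2)


@dataclass
class CovariatePanel:
    """A named covariate that is spatial-only (n,), temporal-only (T,), or full (n, T)."""

    name: str
    values: np.ndarray
    kind: Literal["spatial", "temporal", "spatiotemporal"]

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"covariate {self.name!r} has non-finite values")
        if self.kind not in ("spatial", "temporal", "spatiotemporal"):
            raise ValueError(f"unknown covariate kind: {self.kind!r}")

    def to_panel(self, n: int, T: int) -> np.ndarray:
        """Broadcast the stored values to a full (n, T) panel."""
        v = self.values
        if self.kind == "spatial":
            v = v.ravel()
            if v.shape != (n,):
                raise ValueError(f"spatial covariate {self.name!r} must have length n={n}")
            return np.broadcast_to(v[:, None], (n, T)).copy()
        if self.kind == "temporal":
            v = v.ravel()
            if v.shape != (T,):
                raise ValueError(f"temporal covariate {self.name!r} must have length T={T}")
            return np.broadcast_to(v[None, :], (n, T)).copy()
        if v.shape != (n, T):
            raise ValueError(f"spatiotemporal covariate {self.name!r} must be ({n}, {T})")
        return v.copy()


@dataclass
class GAMConfig:
    num_basis: int = 10
    degree: int = 3
    penalty_order: int = 2
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-6, 6, 13)
    )
    grid_passes: int = 2
    max_iter: int = 50
    tol: float = 1e-9
    term_mode: Literal["spline", "linear"] = "spline"
    select_terms: bool = False
    signif_threshold: float = 0.05


@dataclass
class _TermFit:
    name: str
    mode: str
    basis: SplineBasis | None  # None for linear terms
    col_means: np.ndarray
    coef: np.ndarray
    lam: float
    edf: float
    x_center: float = 0.0
    # orthonormal basis of the sum-to-zero coefficient subspace; removes the
    # constant gauge direction shared by the centered basis and the penalty
    Z: np.ndarray | None = None


@dataclass
class GAMFit:
    beta0: float
    terms: list
    fitted_alpha: np.ndarray
    gcv: float
    edf: dict
    link: str = "log"
    gcv_candidates: np.ndarray | None = None

    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]


def _difference_penalty(k: int, order: int) -> np.ndarray:
    if k <= order:
        return np.zeros((k, k))
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _constraint_basis(k: int) -> np.ndarray:
    """Orthonormal (k, k-1) basis of the subspace {beta : sum(beta) = 0}."""
    from scipy.linalg import null_space

    return null_space(np.ones((1, k)))


def _term_design(term: _TermFit, x: np.ndarray) -> np.ndarray:
    if term.mode == "linear":
        return (np.asarray(x, dtype=float).ravel() - term.x_center)[:, None] - term.col_means
    return (term.basis.evaluate(x) - term.col_means) @ term.Z


def _build_terms(
    covariates: Sequence[CovariatePanel], panels: list[np.ndarray], config: GAMConfig
) -> list[_TermFit]:
    terms = []
    for cov, panel in zip(covariates, panels):
        x = panel.ravel()
        if config.term_mode == "linear":
            xc = float(x.mean())
            cols = (x - xc)[:, None]
            terms.append(
                _TermFit(
                    name=cov.name, mode="linear", basis=None,
                    col_means=cols.mean(axis=0), coef=np.zeros(1), lam=0.0, edf=1.0,
                    x_center=xc,
                )
            )
        else:
            basis = bspline_basis(x, config.num_basis, config.degree)
            Z = _constraint_basis(basis.num_basis)
            terms.append(
                _TermFit(
                    name=cov.name, mode="spline", basis=basis,
                    col_means=basis.B.mean(axis=0), coef=np.zeros(basis.num_basis - 1),
                    lam=1.0, edf=float(basis.num_basis - 1), Z=Z,
                )
            )
    return terms


def _assemble(terms: list[_TermFit], panels: list[np.ndarray]) -> tuple[np.ndarray, list]:
    """Design matrix [1 | centered term blocks] and per-term column slices."""
    N = panels[0].size
    blocks = [np.ones((N, 1))]
    slices = []
    start = 1
    for term, panel in zip(terms, panels):
        if term.mode == "linear":
            block = (panel.ravel() - term.x_center)[:, None] - term.col_means
        else:
            block = (term.basis.B - term.col_means) @ term.Z
        blocks.append(block)
        slices.append(slice(start, start + block.shape[1]))
        start += block.shape[1]
    return np.hstack(blocks), slices


def _penalty_matrix(terms: list[_TermFit], slices: list, p: int, order: int) -> np.ndarray:
    S = np.zeros((p, p))
    for term, sl in zip(terms, slices):
        if term.mode == "spline":
            P = _difference_penalty(term.basis.num_basis, order)
            S[sl, sl] = term.lam * (term.Z.T @ P @ term.Z)
    return S


def _pirls(
    y: np.ndarray, X: np.ndarray, S: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Penalized IRLS for a log-link Poisson-type fit.

    Returns (beta, eta_lin, deviance, F_diag) where F_diag holds the diagonal
    of the influence matrix (X'WX + S)^{-1} X'WX.
    """
    y = np.asarray(y, dtype=float).ravel()
    mu = np.maximum(y, 0.0) + np.mean(y) * 0.1 + 1e-3
    eta = np.log(mu)
    dev_old = np.inf
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w = mu
        z = eta + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X
        try:
            beta = solve(A + S, XtW @ z, assume_a="pos")
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "rank-deficient penalized design; increase penalties or drop terms"
            )
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        dev = _poisson_deviance(y, mu)
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            break
        dev_old = dev
    w = mu
    A = (X.T * w) @ X
    F = solve(A + S, A, assume_a="pos")
    return beta, eta, _poisson_deviance(y, mu), np.diag(F)


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    # a Bregman divergence, so >= 0; clamp the numerically tiny negatives
    return max(float(2.0 * np.sum(term - (y - mu))), 0.0)


def fit_alpha_gam(
    response: np.ndarray,
    covariates: Sequence[CovariatePanel],
    config: GAMConfig | None = None,
) -> GAMFit:
    """Fit the additive log-link model and return the fitted log-scale baseline.

    Smoothing parameters are selected per term by minimizing GCV (deviance
    based) over ``config.lambda_grid``, cycling through terms for
    ``config.grid_passes`` passes.
    """
    config = config or GAMConfig()
    response = np.asarray(response, dtype=float)
    if response.ndim != 2:
        raise ValueError("response must be an (n, T) panel")
    if len(covariates) < 1:
        raise ValueError("at least one covariate is required")
    n, T = response.shape
    panels = [c.to_panel(n, T) for c in covariates]
    for c, p in zip(covariates, panels):
        if not np.all(np.isfinite(p)):
            raise ValueError(f"covariate {c.name!r} has non-finite values")

    terms = _build_terms(covariates, panels, config)
    fit = _fit_given_terms(response, terms, panels, config)

    if config.select_terms and len(terms) > 1:
        terms, panels = _prune_terms(response, fit, terms, panels, config)
        fit = _fit_given_terms(response, terms, panels, config)
    return fit


def _fit_given_terms(
    response: np.ndarray, terms: list[_TermFit], panels: list[np.ndarray], config: GAMConfig
) -> GAMFit:
    n, T = response.shape
    y = response.ravel()
    N = y.size
    X, slices = _assemble(terms, panels)
    p = X.shape[1]

    any_spline = any(t.mode == "spline" for t in terms)
    gcv_seen = []

    def fit_once() -> tuple:
        S = _penalty_matrix(terms, slices, p, config.penalty_order)
        beta, eta, dev, Fd = _pirls(y, X, S, config.max_iter, config.tol)
        edf = float(Fd.sum())
        g = gcv_score(dev, N, min(edf, N - 1))
        gcv_seen.append(g)
        return beta, eta, dev, Fd, edf, g

    beta, eta, dev, Fd, edf, g = fit_once()
    if any_spline:
        for _ in range(config.grid_passes):
            for term in terms:
                if term.mode != "spline":
                    continue
                best = (g, term.lam)
                for lam in config.lambda_grid:
                    term.lam = float(lam)
                    _, _, _, _, _, g_cand = fit_once()
                    if g_cand < best[0]:
                        best = (g_cand, float(lam))
                term.lam = best[1]
                beta, eta, dev, Fd, edf, g = fit_once()

    for term, sl in zip(terms, slices):
        term.coef = beta[sl].copy()
        term.edf = float(Fd[sl].sum())
    edf_map = {t.name: t.edf for t in terms}
    return GAMFit(
        beta0=float(beta[0]),
        terms=terms,
        fitted_alpha=eta.reshape(n, T),
        gcv=g,
        edf=edf_map,
        gcv_candidates=np.array(gcv_seen),
    )


def _prune_terms(response, fit, terms, panels, config):
    """Drop terms whose approximate Wald p-value exceeds the threshold, then refit."""
    y = response.ravel()
    X, slices = _assemble(terms, panels)
    S = _penalty_matrix(terms, slices, X.shape[1], config.penalty_order)
    beta, eta, dev, Fd = _pirls(y, X, S, config.max_iter, config.tol)
    mu = np.exp(np.clip(eta, -30, 30))
    A = (X.T * mu) @ X
    Vb = solve(A + S, np.eye(X.shape[1]), assume_a="pos")
    keep_terms, keep_panels = [], []
    for term, panel, sl in zip(terms, panels, slices):
        psi = beta[sl]
        V = Vb[sl, sl]
        stat = float(psi @ np.linalg.pinv(V) @ psi)
        dof = max(term.edf, 1.0)
        pval = float(chi2.sf(stat, dof))
        if pval <= config.signif_threshold:
            keep_terms.append(term)
            keep_panels.append(panel)
    if not keep_terms:  # keep the strongest term rather than an empty model
        keep_terms, keep_panels = [terms[0]], [panels[0]]
    return keep_terms, keep_panels


def predict_alpha(fit: GAMFit, covariates: Sequence[CovariatePanel]) -> np.ndarray:
    """Evaluate beta0 + sum_i f_i on new covariate panels, returning (n, T)."""
    by_name = {c.name: c for c in covariates}
    missing = [t.name for t in fit.terms if t.name not in by_name]
    if missing:
        raise KeyError(f"missing covariates for terms: {missing}")
    # infer (n, T) from the covariate kinds present
    full = [c for c in covariates if c.kind == "spatiotemporal"]
    if full:
        n, T = full[0].values.shape
    else:
        n_guess = [c.values.size for c in covariates if c.kind == "spatial"]
        T_guess = [c.values.size for c in covariates if c.kind == "temporal"]
        n = n_guess[0] if n_guess else 1
        T = T_guess[0] if T_guess else 1
    eta = np.full(n * T, fit.beta0)
    for term in fit.terms:
        x = by_name[term.name].to_panel(n, T).ravel()
        eta += _term_design(term, x) @ term.coef
    return eta.reshape(n, T)
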