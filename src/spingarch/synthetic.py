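"""Synthetic city lattices, landmark-distance covariates, and model-generated counts.

Emulates the structure of monthly crime panels on an administrative-zone
lattice: a rook-adjacency grid of zones (default 12x12 = 144, close to a
141-zone city), per-zone nearest-landmark distance covariates with small
monthly jitter, a static lognormal population-density covariate, and count
panels generated by the SPINGARCH process itself with a covariate-driven
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .gam import CovariatePanel
from .lattice import Lattice, build_lattice
from .model import CountPanel, IntensityPath, LatentPath, ModelParams, simulate

__all__ = [
    "SyntheticScenario",
    "generate_city_lattice",
    "generate_landmark_covariates",
    "generate_scenario",
]

DEFAULT_LANDMARKS = {"upc": 6, "cam": 10, "cc": 4, "par": 5, "hos": 3}


def generate_city_lattice(rows: int, cols: int) -> Lattice:
    """Rook-adjacency grid of rows x cols zones with unit-spaced centroids."""
    if rows * cols < 2:
        raise ValueError("need at least 2 zones")
    ids = [f"z{r * cols + c + 1:03d}" for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((ids[r * cols + c], ids[r * cols + c + 1]))
            if r + 1 < rows:
                edges.append((ids[r * cols + c], ids[(r + 1) * cols + c]))
    centroids = np.array(
        [[c + 0.5, r + 0.5] for r in range(rows) for c in range(cols)], dtype=float
    )
    return build_lattice(edges, ids, centroids=centroids)


def generate_landmark_covariates(
    lattice: Lattice,
    landmark_counts: Mapping[str, int] | None = None,
    T: int = 60,
    seed: int | np.random.Generator = 0,
    jitter_scale: float = 0.05,
    seasonal_amplitude: float = 0.0,
    include_density: bool = True,
) -> list[CovariatePanel]:
    """Per-zone per-month distance-to-nearest-landmark covariates.

    Landmarks are placed uniformly in the centroid bounding box; the monthly
    jitter makes the panels genuinely (n, T), and *seasonal_amplitude* adds a
    shared 12-month cycle (random phase per landmark type) on top.  A static
    lognormal density covariate ``pob`` is appended when *include_density* is
    set.
    """
    if lattice.centroids is None:
        raise ValueError("lattice has no centroids; build it with generate_city_lattice")
    landmark_counts = dict(landmark_counts or DEFAULT_LANDMARKS)
    for name, k in landmark_counts.items():
        if k < 1:
            raise ValueError(f"landmark count for {name!r} must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cent = lattice.centroids
    lo = cent.min(axis=0)
    hi = cent.max(axis=0)
    diag = float(np.linalg.norm(hi - lo)) or 1.0
    n = lattice.n

    panels = []
    months = np.arange(T)
    for name, k in landmark_counts.items():
        pts = rng.uniform(lo, hi, size=(k, 2))
        d = np.min(np.linalg.norm(cent[:, None, :] - pts[None, :, :], axis=2), axis=1)
        phase = rng.uniform(0, 2 * np.pi)
        season = seasonal_amplitude * np.sin(2 * np.pi * months / 12.0 + phase)
        jitter = jitter_scale * rng.standard_normal((n, T))
        values = np.clip(d[:, None] + season[None, :] + jitter, 0.0, diag)
        panels.append(CovariatePanel(name=name, values=values, kind="spatiotemporal"))
    if include_density:
        pob = rng.lognormal(mean=0.0, sigma=0.5, size=n)
        panels.append(CovariatePanel(name="pob", values=pob, kind="spatial"))
    return panels


@dataclass
class SyntheticScenario:
    """Everything needed to generate a reproducible model-drawn dataset."""

    grid_rows: int = 12
    grid_cols: int = 12
    T: int = 60
    landmark_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LANDMARKS)
    )
    beta0: float = 0.0
    effect_functions: Mapping[str, Callable[[np.ndarray], np.ndarray]] = field(
        default_factory=dict
    )
    eta: float = 0.2
    kappa: float = 0.1
    sigma: float = 0.3
    sigma_eps: float = 0.5
    zeta: float = 0.99
    jitter_scale: float = 0.05
    seasonal_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta + self.kappa >= 1:
            raise ValueError("scenario violates eta + kappa < 1")


def generate_scenario(
    scenario: SyntheticScenario,
) -> tuple[CountPanel, list[CovariatePanel], dict]:
    """Build lattice + covariates, form alpha_t from the effect functions, simulate counts.

    Returns the counts, the covariate panels, and a truth record holding the
    lattice, parameters, baseline panel, and latent/intensity paths.
    """
    lattice = generate_city_lattice(scenario.grid_rows, scenario.grid_cols)
    rng = np.random.default_rng([scenario.seed, 0xC0FFEE])
    covariates = generate_landmark_covariates(
        lattice,
        scenario.landmark_counts,
        T=scenario.T,
        seed=rng,
        jitter_scale=scenario.jitter_scale,
        seasonal_amplitude=scenario.seasonal_amplitude,
    )
    n, T = lattice.n, scenario.T
    alpha = np.full((n, T), float(scenario.beta0))
    by_name = {c.name: c for c in covariates}
    for name, f in scenario.effect_functions.items():
        if name not in by_name:
            raise KeyError(f"effect function for unknown covariate {name!r}")
        contrib = f(by_name[name].to_panel(n, T))
        if not np.all(np.isfinite(contrib)):
            raise ValueError(f"effect function for {name!r} produced non-finite values")
        alpha += contrib

    params = ModelParams(
        eta=scenario.eta,
        kappa=scenario.kappa,
        sigma=scenario.sigma,
        sigma_eps=scenario.sigma_eps,
        zeta=scenario.zeta,
        alpha=alpha,
    )
    counts, intensity, latent = simulate(params, lattice, T, seed=rng)
    truth = {
        "lattice": lattice,
        "params": params,
        "alpha": alpha,
        "intensity": intensity,
        "latent": latent,
        "scenario": scenario,
    }
    return counts, covariates, truth
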