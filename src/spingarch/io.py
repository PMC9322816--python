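"""Plain-text I/O for count panels, adjacency structures, and covariate panels.

Counts travel in long format (``site_id,time,count``); adjacency as an
edge-list CSV (``site_a,site_b``) or a dense 0/1 matrix with a site-id header
row; covariates in long format (``site_id,time,name,value``) where spatial-only
rows leave ``time`` blank and temporal-only rows leave ``site_id`` blank.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gam import CovariatePanel
from .lattice import Lattice, _lattice_from_adjacency, build_lattice
from .model import CountPanel

__all__ = [
    "write_counts_csv", "read_counts_csv",
    "write_adjacency_csv", "read_adjacency_csv",
    "write_covariates_csv", "read_covariates_csv",
    "write_truth_json", "read_truth_json",
]


def write_counts_csv(path, counts: CountPanel) -> None:
    n, T = counts.Y.shape
    df = pd.DataFrame(
        {
            "site_id": np.repeat(counts.site_ids, T),
            "time": np.tile(counts.time_index, n),
            "count": counts.Y.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_counts_csv(path) -> CountPanel:
    df = pd.read_csv(path, dtype={"site_id": str})
    required = {"site_id", "time", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts CSV must have columns {sorted(required)}")
    wide = df.pivot(index="site_id", columns="time", values="count")
    if wide.isna().any().any():
        raise ValueError("counts panel has missing (site, time) cells")
    # preserve first-appearance site order rather than pivot's lexicographic sort
    order = list(dict.fromkeys(df["site_id"]))
    wide = wide.loc[order]
    return CountPanel(
        Y=wide.to_numpy().astype(np.int64),
        site_ids=tuple(wide.index),
        time_index=wide.columns.to_numpy(),
    )


def write_adjacency_csv(path, lattice: Lattice) -> None:
    rows_i, cols_j = np.nonzero(np.triu(lattice.N_raw))
    df = pd.DataFrame(
        {
            "site_a": [lattice.site_ids[i] for i in rows_i],
            "site_b": [lattice.site_ids[j] for j in cols_j],
        }
    )
    df.to_csv(path, index=False)


def read_adjacency_csv(path, site_ids: Sequence | None = None) -> Lattice:
    """Read an edge-list CSV (header ``site_a,site_b``) or a dense 0/1 matrix.

    A dense matrix file has the site ids as its header row.  Asymmetric dense
    input is symmetrized with a warning.
    """
    head = pd.read_csv(path, nrows=0)
    cols = list(head.columns)
    if cols[:2] == ["site_a", "site_b"]:
        df = pd.read_csv(path, dtype=str)
        if site_ids is None:
            site_ids = list(dict.fromkeys(pd.concat([df["site_a"], df["site_b"]])))
        return build_lattice(list(zip(df["site_a"], df["site_b"])), site_ids)
    # dense form: header row holds the site ids
    df = pd.read_csv(path)
    ids = [str(c) for c in df.columns]
    M = df.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError("dense adjacency must be square")
    if not np.array_equal(M, M.T):
        warnings.warn("asymmetric adjacency matrix: symmetrizing with logical OR")
        M = np.maximum(M, M.T)
    return _lattice_from_adjacency(M, ids)


def write_covariates_csv(path, covariates: Sequence[CovariatePanel],
                         site_ids: Sequence, time_index: Sequence) -> None:
    frames = []
    n, T = len(site_ids), len(time_index)
    for cov in covariates:
        if cov.kind == "spatial":
            frames.append(
                pd.DataFrame(
                    {"site_id": list(site_ids), "time": "", "name": cov.name,
                     "value": cov.values.ravel()}
                )
            )
        elif cov.kind == "temporal":
            frames.append(
                pd.DataFrame(
                    {"site_id": "", "time": list(time_index), "name": cov.name,
                     "value": cov.values.ravel()}
                )
            )
        else:
            panel = cov.to_panel(n, T)
            frames.append(
                pd.DataFrame(
                    {
                        "site_id": np.repeat(list(site_ids), T),
                        "time": np.tile(list(time_index), n),
                        "name": cov.name,
                        "value": panel.ravel(),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_covariates_csv(path, site_ids: Sequence, time_index: Sequence
                        ) -> list[CovariatePanel]:
    df = pd.read_csv(path, dtype={"site_id": str, "name": str})
    required = {"site_id", "time", "name", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"covariates CSV must have columns {sorted(required)}")
    site_pos = {str(s): i for i, s in enumerate(site_ids)}
    time_pos = {t: j for j, t in enumerate(pd.Series(time_index))}
    n, T = len(site_ids), len(time_index)
    out = []
    for name, grp in df.groupby("name", sort=False):
        has_site = grp["site_id"].notna() & (grp["site_id"].astype(str) != "")
        has_time = grp["time"].notna()
        if has_site.all() and has_time.all():
            panel = np.full((n, T), np.nan)
            i = grp["site_id"].map(site_pos).to_numpy()
            j = grp["time"].map(time_pos).to_numpy()
            if np.any(pd.isna(i)) or np.any(pd.isna(j)):
                raise ValueError(f"covariate {name!r} references unknown sites/times")
            panel[i.astype(int), j.astype(int)] = grp["value"].to_numpy(float)
            if np.isnan(panel).any():
                raise ValueError(f"covariate {name!r} panel has missing cells")
            out.append(CovariatePanel(name=name, values=panel, kind="spatiotemporal"))
        elif has_site.all():
            v = np.full(n, np.nan)
            i = grp["site_id"].map(site_pos).to_numpy()
            v[i.astype(int)] = grp["value"].to_numpy(float)
            if np.isnan(v).any():
                raise ValueError(f"spatial covariate {name!r} is incomplete")
            out.append(CovariatePanel(name=name, values=v, kind="spatial"))
        elif has_time.all():
            v = np.full(T, np.nan)
            j = grp["time"].map(time_pos).to_numpy()
            v[j.astype(int)] = grp["value"].to_numpy(float)
            if np.isnan(v).any():
                raise ValueError(f"temporal covariate {name!r} is incomplete")
            out.append(CovariatePanel(name=name, values=v, kind="temporal"))
        else:
            raise ValueError(f"covariate {name!r} mixes blank and filled dimensions")
    return out


def write_truth_json(path, truth: dict) -> None:
    """Serialize the scenario ground truth (parameters + baseline) to JSON."""
    params = truth["params"]
    payload = {
        "eta": params.eta,
        "kappa": params.kappa,
        "sigma": params.sigma,
        "sigma_eps": params.sigma_eps,
        "zeta": params.zeta,
        "beta0": getattr(truth.get("scenario"), "beta0", None),
        "seed": getattr(truth.get("scenario"), "seed", None),
        "alpha": np.asarray(truth["alpha"]).tolist(),
        "site_ids": list(truth["lattice"].site_ids),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
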