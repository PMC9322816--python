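"""Posterior summaries and convergence diagnostics.

Summary tables carry the columns Mean, Sd, 2.5%, 25.0%, 50.0%, 75.0%, 97.5%,
n_eff, Rhat, and the Shannon entropy H of the pooled sample computed on
equal-width histogram bins numbering round(sqrt(sample size)), in nats.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .inference import PosteriorDraws

__all__ = [
    "split_rhat",
    "effective_sample_size",
    "shannon_entropy_sqrt_bins",
    "acf",
    "posterior_summary",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "Mean", "Sd", "2.5%", "25.0%", "50.0%", "75.0%", "97.5%", "n_eff", "Rhat", "H",
]


def _as_chain_matrix(chains) -> np.ndarray:
    arr = np.asarray([np.asarray(c, dtype=float) for c in chains])
    if arr.ndim != 2:
        raise ValueError("chains must be equal-length 1-D sequences")
    return arr


def split_rhat(chains) -> float:
    """Split-chain potential scale reduction factor.

    Each chain is split in half; Rhat compares between- and within-half-chain
    variance.  Returns 1.0 by convention when every half-chain is constant.
    """
    arr = _as_chain_matrix(chains)
    m, length = arr.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if length < 4:
        raise ValueError("chains must have length >= 4")
    half = length // 2
    halves = np.vstack([arr[:, :half], arr[:, half: 2 * half]])
    W = float(np.mean(np.var(halves, axis=1, ddof=1)))
    if W == 0.0:
        return 1.0
    B = half * float(np.var(np.mean(halves, axis=1), ddof=1))
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def effective_sample_size(chains) -> float:
    """Autocorrelation-based ESS with initial-positive-sequence truncation.

    Antithetic chains can give a raw estimate above the number of draws; the
    value is then capped at the total draw count and a warning is issued.
    Constant chains return the total draw count, with a warning.
    """
    arr = _as_chain_matrix(chains)
    m, length = arr.shape
    total = m * length
    chain_vars = np.var(arr, axis=1, ddof=1)
    if np.all(chain_vars == 0):
        warnings.warn("constant chains: ESS defined as total draws by convention")
        return float(total)

    W = float(np.mean(chain_vars))
    B_over_n = float(np.var(np.mean(arr, axis=1), ddof=1)) if m > 1 else 0.0
    var_plus = (length - 1) / length * W + B_over_n

    # mean autocovariance across chains at each lag (FFT-based, biased norm)
    max_lag = length - 1
    acov = np.zeros((m, length))
    for c in range(m):
        acov[c] = _autocovariance(arr[c])
    mean_acov = acov.mean(axis=0)

    rho = 1.0 - (W - mean_acov) / var_plus
    # Geyer initial positive sequence on paired sums rho[2k] + rho[2k+1],
    # starting at lag 0; tau = 2 * sum(pairs) - 1
    paired = 0.0
    k = 0
    while k + 1 <= max_lag:
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        paired += pair
        k += 2
    tau = 2.0 * paired - 1.0
    if tau <= 0 or total / tau > total:
        warnings.warn("negative autocorrelation: ESS capped at total draw count")
        return float(total)
    return float(total / tau)


def _autocovariance(x: np.ndarray) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    return acov


def shannon_entropy_sqrt_bins(sample: np.ndarray) -> float:
    """Histogram Shannon entropy (nats) with round(sqrt(len(sample))) equal-width bins."""
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size < 4:
        raise ValueError("sample size must be >= 4")
    lo, hi = sample.min(), sample.max()
    if hi <= lo:
        return 0.0
    n_bins = int(np.rint(np.sqrt(sample.size)))
    counts, _ = np.histogram(sample, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / sample.size
    return float(-np.sum(p * np.log(p)))


def acf(sample: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized autocorrelation at lags 0..max_lag (lag 0 is 1)."""
    sample = np.asarray(sample, dtype=float).ravel()
    if len(sample) <= max_lag:
        raise ValueError("sample length must exceed max_lag")
    acov = _autocovariance(sample)
    if acov[0] == 0:
        warnings.warn("constant sample: autocorrelation undefined beyond lag 0")
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    return acov[: max_lag + 1] / acov[0]


def posterior_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """One summary row per parameter, columns ordered as in the reference tables."""
    rows = {}
    for name in draws.param_names:
        chains = draws.by_chain(name)
        pooled = np.concatenate(chains)
        finite = np.isfinite(pooled)
        if not finite.all():  # e.g. tau = inf when the spatial field is disabled
            rows[name] = dict.fromkeys(SUMMARY_COLUMNS, np.nan)
            continue
        qs = np.percentile(pooled, [2.5, 25, 50, 75, 97.5])
        if len(chains) >= 2 and len(chains[0]) >= 4:
            rhat = split_rhat(chains)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                neff = effective_sample_size(chains)
        else:
            rhat, neff = np.nan, np.nan
        H = shannon_entropy_sqrt_bins(pooled) if pooled.size >= 4 else np.nan
        rows[name] = dict(
            zip(
                SUMMARY_COLUMNS,
                [pooled.mean(), pooled.std(ddof=1) if pooled.size > 1 else 0.0,
                 *qs, neff, rhat, H],
            )
        )
    return pd.DataFrame.from_dict(rows, orient="index")[SUMMARY_COLUMNS]
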