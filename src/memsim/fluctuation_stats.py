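"""Fluctuation statistics for single-cell expression traces and snapshots.

The two workhorse quantities are the normalized variance NV = sigma^2/mu^2
(squared coefficient of variation, the standard noise measure for expression
distributions) and the autocorrelation function of the volume-normalized
protein level, summarized by tau_half — the first lag at which the ACF drops
to 0.5, an operational "cellular memory" timescale.

Conventions: NV uses the population variance (a distribution functional, not
an inferential estimate); the ACF is the biased single-global-mean estimator,
which keeps |r| <= 1 and the sequence positive semidefinite; tau_half is
linearly interpolated at the first downward crossing and right-censored at
``max_lag`` when the ACF never reaches 0.5 in the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.tsa.stattools import acf as _sm_acf

from .errors import InsufficientDataError, UndefinedStatisticError

__all__ = [
    "ACFResult",
    "StatSummary",
    "normalized_variance",
    "autocorrelation",
    "tau_half",
    "fraction_positive",
    "quadrant_fractions",
    "fit_half_life",
    "reporter_correlation",
    "summarize",
    "analyze_tracks",
]


@dataclass(frozen=True)
class ACFResult:
    """Autocorrelation of a regular-grid trace.

    ``tau_half`` is in the units of ``lags`` (minutes); ``censored`` is True
    when the ACF never crossed 0.5 within the window, in which case
    ``tau_half`` equals the maximum lag (a right-censored lower bound).
    """

    lags: np.ndarray
    acf: np.ndarray
    tau_half: float
    censored: bool
    n_points: int


@dataclass(frozen=True)
class StatSummary:
    mean: float
    variance: float
    nv: float  # NaN when the mean is 0
    median: float
    n: int


def normalized_variance(values) -> float:
    """Normalized variance NV = sigma^2 / mu^2 (population variance).

    NaN signals an undefined NV (zero mean); fewer than two observations
    raise :class:`InsufficientDataError`.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"NV needs >= 2 values, got {x.size}")
    mu = x.mean()
    if mu == 0:
        return math.nan
    return float(x.var() / mu**2)


def summarize(values) -> StatSummary:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"summary needs >= 2 values, got {x.size}")
    mu = float(x.mean())
    var = float(x.var())
    nv = math.nan if mu == 0 else var / mu**2
    return StatSummary(mean=mu, variance=var, nv=nv, median=float(np.median(x)), n=x.size)


def autocorrelation(values, max_lag: float, dt: float = 1.0) -> ACFResult:
    """Biased-estimator ACF of a regular-grid series, with tau_half.

    r(k) = sum_{t}(x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2 with
    the global mean xbar; r(0) = 1.  ``max_lag`` and the returned lags are in
    time units (``dt`` per grid step); ``max_lag`` must be smaller than the
    trace span.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        raise InsufficientDataError(f"ACF needs >= 10 grid points, got {n}")
    k_max = int(math.floor(max_lag / dt + 1e-9))
    if k_max >= n:
        raise InsufficientDataError(
            f"max_lag {max_lag} not below the trace span {(n - 1) * dt}"
        )
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("ACF undefined for a constant series")
    r = _sm_acf(x, nlags=k_max, adjusted=False, fft=n > 512)
    lags = np.arange(k_max + 1) * dt
    th, censored = _tau_half_from_curve(lags, r)
    return ACFResult(lags=lags, acf=r, tau_half=th, censored=censored, n_points=n)


def _tau_half_from_curve(lags: np.ndarray, r: np.ndarray) -> tuple[float, bool]:
    below = np.nonzero(r < 0.5)[0]
    if below.size == 0:
        return float(lags[-1]), True
    j = below[0]
    if j == 0:  # cannot happen for a proper ACF (r(0)=1) but stay defensive
        return float(lags[0]), False
    r0, r1 = r[j - 1], r[j]
    frac = (r0 - 0.5) / (r0 - r1)
    return float(lags[j - 1] + frac * (lags[j] - lags[j - 1])), False


def tau_half(acf: ACFResult) -> float:
    """First 0.5-crossing lag of an ACF (linear interpolation; censored
    results return the maximum lag — check ``acf.censored``)."""
    return acf.tau_half


def fraction_positive(values, threshold: float) -> float:
    """Proportion of values strictly above the positivity threshold."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("fraction_positive needs >= 1 value")
    return float((x > threshold).mean())


def quadrant_fractions(a, b, threshold_a: float, threshold_b: float) -> dict[str, float]:
    """Two-channel quadrant classification (strictly above = positive).

    Returns fractions for the four quadrants keyed ``"A+B+"``, ``"A+B-"``,
    ``"A-B+"``, ``"A-B-"``; they sum to 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise InsufficientDataError("quadrant_fractions needs matched non-empty channels")
    pa = a > threshold_a
    pb = b > threshold_b
    n = a.size
    return {
        "A+B+": float((pa & pb).sum() / n),
        "A+B-": float((pa & ~pb).sum() / n),
        "A-B+": float((~pa & pb).sum() / n),
        "A-B-": float((~pa & ~pb).sum() / n),
    }


def fit_half_life(times, values) -> float:
    """Half-life (min) from a decay trace by log-linear least squares.

    Fits log(values) against time; t_half = -ln2/slope.  Values must be
    positive; a non-negative fitted slope means no decay and raises
    :class:`UndefinedStatisticError`.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(values, dtype=float)
    if t.size < 3 or t.size != x.size:
        raise InsufficientDataError("fit_half_life needs >= 3 matched points")
    if np.any(x <= 0):
        raise ValueError("fit_half_life requires strictly positive values")
    slope = sps.linregress(t, np.log(x)).slope
    if slope >= 0:
        raise UndefinedStatisticError("no decay: fitted slope is non-negative")
    return float(-math.log(2.0) / slope)


def reporter_correlation(pairs_a, pairs_b) -> float:
    """Pearson correlation between per-cell statistics of two reporters."""
    a = np.asarray(pairs_a, dtype=float)
    b = np.asarray(pairs_b, dtype=float)
    if a.size < 3 or a.shape != b.shape:
        raise InsufficientDataError("reporter_correlation needs >= 3 matched pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError("correlation undefined: a margin has zero variance")
    return float(sps.pearsonr(a, b).statistic)


def analyze_tracks(
    table: pd.DataFrame,
    value_columns=None,
    cell_col: str = "cell_id",
    time_col: str = "time_min",
    max_lag: float | None = None,
) -> pd.DataFrame:
    """Per-cell fluctuation statistics from a tracking or trace table.

    ``value_columns`` default to every column starting with ``total_``,
    ``fluor_`` or ``norm_level``.  For each cell and channel the mean, NV
    and tau_half (with censored flag) are reported; tau_half is NaN for
    records too short for an ACF (fewer than 10 frames).  ``max_lag``
    defaults to half the cell's record span.
    """
    if value_columns is None:
        value_columns = [c for c in table.columns
                         if c.startswith(("total_", "fluor_", "norm_level"))]
    if not value_columns:
        raise InsufficientDataError("no value columns found to analyze")
    rows = []
    for cid, group in table.groupby(cell_col, sort=True):
        group = group.sort_values(time_col)
        t = group[time_col].to_numpy(dtype=float)
        row: dict = {cell_col: cid, "n_frames": len(group)}
        for col in value_columns:
            x = group[col].to_numpy(dtype=float)
            row[f"mean_{col}"] = float(x.mean())
            row[f"nv_{col}"] = (math.nan if x.size < 2 or x.mean() == 0
                                else float(x.var() / x.mean() ** 2))
            th, cens = math.nan, False
            if x.size >= 10 and np.ptp(x) > 0:
                dt = float(t[1] - t[0])
                lag = max_lag if max_lag is not None else (t[-1] - t[0]) / 2.0
                lag = min(lag, t[-1] - t[0] - dt)
                res = autocorrelation(x, max_lag=lag, dt=dt)
                th, cens = res.tau_half, res.censored
            row[f"tau_half_{col}"] = th
            row[f"censored_{col}"] = bool(cens)
        rows.append(row)
    return pd.DataFrame(rows)
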