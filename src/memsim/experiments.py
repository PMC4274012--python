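"""Canned in-silico reproductions of the study's headline analyses.

Each function runs one published protocol end to end with the package's
default parameter regimes and returns the summary numbers a reader would
compare against the study's figures: clamped-open and whole-model normalized
variances, per-cell memory-time cohorts, subclone relaxation, and FRAP
inhibitor controls.  They are deliberately small wrappers over the library so
the protocol of every reported number is explicit and reproducible from one
seed.
"""

from __future__ import annotations

import math

import numpy as np

from . import presets
from .fluctuation_stats import autocorrelation, normalized_variance
from .gene_model import ChromatinState
from .population import (
    frap_experiment,
    subclone_experiment,
    tau_half_cohort,
)
from .ssa_engine import simulate_cell, stationary_guess
from .synthetic_data import positivity_threshold

__all__ = [
    "clamped_open_trace",
    "clamped_open_nv",
    "whole_model_nv",
    "memory_cohorts",
    "matched_tau_half",
    "subclone_convergence",
    "frap_control_labels",
    "default_threshold",
]


def default_threshold(seed=0) -> float:
    """Positivity threshold from the default measurement noise floor."""
    meas = presets.default_measurement()
    floor = meas.floor_sample(100_000, np.random.default_rng(seed))
    return positivity_threshold(floor) / meas.gain


def clamped_open_trace(regime: str, seed, n_divisions: int = 130,
                       dt: float = 10.0, channel: str = "yfp"):
    """One long single-cell line with chromatin pinned OPEN.

    This is the active-period protocol: the promoter never closes, divisions
    halve the molecules every cycle, and the observable is the
    volume-normalized protein level.
    """
    genes = (presets.gene_preset(regime, channel),)
    cycle = presets.CYCLE
    rng = np.random.default_rng(seed)
    init = stationary_guess(genes, cycle, rng, open_only=True)
    init.clamp = [ChromatinState.OPEN]
    init.chromatin = [ChromatinState.OPEN]
    return simulate_cell(genes, cycle, n_divisions * cycle.T_div, dt=dt,
                         seed=rng, init=init)


def clamped_open_nv(regime: str, seed, n_divisions: int = 130,
                    burn_divisions: int = 5) -> dict:
    """Normalized variance of the clamped-OPEN normalized protein level."""
    dt = 10.0
    trace = clamped_open_trace(regime, seed, n_divisions=n_divisions, dt=dt)
    burn = int(burn_divisions * presets.CYCLE.T_div / dt)
    x = trace.norm_level[0][burn:]
    return {"nv": normalized_variance(x), "mean": float(x.mean()),
            "n_divisions": len(trace.division_times), "n_samples": len(x)}


def whole_model_nv(regime: str, seed, n_lineages: int = 20,
                   days: float = 90.0, burn_days: float = 10.0,
                   dt: float = 30.0) -> dict:
    """Normalized variance of the full model (chromatin switching on).

    Pools ``n_lineages`` independent single-cell lines, each simulated for
    ``days`` days (after discarding ``burn_days`` of warm-up), so slow
    chromatin dwells of the order of a week are averaged over.
    """
    genes = (presets.gene_preset(regime, "yfp"),)
    cycle = presets.CYCLE
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    burn = int(burn_days * 1440.0 / dt)
    chunks = []
    for ss in root.spawn(n_lineages):
        tr = simulate_cell(genes, cycle, days * 1440.0, dt=dt,
                           seed=np.random.default_rng(ss))
        chunks.append(tr.norm_level[0][burn:])
    x = np.concatenate(chunks)
    return {"nv": normalized_variance(x), "mean": float(x.mean()),
            "span_days": days, "n_lineages": n_lineages}


def memory_cohorts(seed, n_cells: int = 80) -> dict:
    """Per-cell autocorrelation memory times under each clone's own imaging
    design.

    Stable clone: movies of 120 h at 10-min frames (cells are identifiable
    across divisions).  Unstable clone: per-cell records span one cell cycle
    at 20-min frames (cells change appearance too fast to stitch across
    divisions).  Medians are over expressing, uncensored cells; censored
    counts are reported alongside.
    """
    cycle = presets.CYCLE
    thr = default_threshold(seed)
    out = {}
    stable = tau_half_cohort(
        (presets.gene_preset("stable", "yfp"),), cycle, n_cells=n_cells,
        movie_min=120 * 60.0, dt=10.0, max_lag=60 * 60.0, level_min=thr,
        seed=np.random.SeedSequence([1, int(seed) % 2**31]))
    unstable = tau_half_cohort(
        (presets.gene_preset("unstable", "yfp"),), cycle, n_cells=n_cells,
        movie_min=cycle.T_div, dt=20.0, max_lag=cycle.T_div / 2.0,
        level_min=thr,
        seed=np.random.SeedSequence([2, int(seed) % 2**31]))
    for name, df in (("stable", stable), ("unstable", unstable)):
        ok = df["expressing_yfp"] & ~df["censored_yfp"]
        taus = df.loc[ok, "tau_half_yfp"]
        out[name] = {
            "median_tau_half_min": float(taus.median()),
            "n_expressing": int(df["expressing_yfp"].sum()),
            "n_censored": int(df["censored_yfp"].sum()),
            "fraction_below_2h": float((taus < 120.0).mean()),
        }
    return out


def matched_tau_half(seed, n_divisions: int = 120) -> dict:
    """tau_half of the long clamped-OPEN trace for both regimes, same seed.

    The two regimes share the random stream, division schedule and analysis
    window, isolating the effect of product stability on the loss of
    autocorrelation.
    """
    out = {}
    for regime in ("stable", "unstable"):
        tr = clamped_open_trace(regime, seed, n_divisions=n_divisions)
        res = autocorrelation(tr.norm_level[0], max_lag=4320.0, dt=10.0)
        out[regime] = {"tau_half_min": res.tau_half,
                       "censored": bool(res.censored)}
    return out


def subclone_convergence(seed, n_replicates: int = 20,
                         max_cells: int = 96) -> dict:
    """Relaxation of sorted HIGH vs LOW subclones toward the parental mean.

    Grows ``n_replicates`` single-reporter subclones per class for 55 days
    with snapshots at day 14 and day 55, and reports the gap between the
    class-average medians (mean over HIGH subclones of the median level
    minus the LOW counterpart) at both times.  Memory keeps the early gap
    large; week-scale chromatin mixing erodes it over the culture.
    """
    genes = (presets.gene_preset("stable", "yfp"),)
    cycle = presets.CYCLE
    thr = default_threshold(seed)
    snaps = [14 * 1440.0, 55 * 1440.0]
    courses = subclone_experiment(
        genes, cycle, n_subclones=n_replicates, duration=55 * 1440.0,
        snapshot_times=snaps, seed=seed, threshold=thr,
        classes=("HIGH", "LOW"), max_cells=max_cells, parental_n=300)
    med = {cls: np.array([tc.median for tc in courses
                          if tc.founder_class == cls])
           for cls in ("HIGH", "LOW")}
    gap = med["HIGH"].mean(axis=0) - med["LOW"].mean(axis=0)  # per snapshot
    nv = np.array([tc.nv for tc in courses])
    return {
        "gap_day14": float(gap[0]),
        "gap_day55": float(gap[1]),
        "mean_nv_day55": float(np.nanmean(nv[:, 1])),
        "n_replicates": n_replicates,
    }


def frap_control_labels(seed, n_cells: int = 20) -> dict:
    """FRAP inhibitor controls: RECOVERING label counts (expected 0).

    Bleach to 20 %, observe 5 h, with transcription (DRB-like) or
    translation (cycloheximide-like) blocked at the bleach.
    """
    genes = presets.stable_pair()
    cycle = presets.CYCLE
    out = {}
    for i, control in enumerate(("NO_TRANSCRIPTION", "NO_TRANSLATION")):
        df = frap_experiment(genes, cycle, n_cells=n_cells, seed=int(seed) + i,
                             control=control)
        labels = df.groupby("cell_id")["label"].first()
        out[control] = {"n_recovering": int((labels == "RECOVERING").sum()),
                        "n_cells": int(labels.size)}
    return out
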