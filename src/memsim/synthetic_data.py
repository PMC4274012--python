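"""Synthetic measurement tables: time-lapse tracking and cytometry snapshots.

The simulator produces molecule counts; real instruments report fluorescence.
The measurement model applied here is a gain (fluorescence units per protein
molecule), multiplicative lognormal noise of a given CV, and an additive
Gaussian autofluorescence floor — the simplest response that produces a
non-expressing "black" population and the positive skew seen in cytometry.

Two output modalities are emulated:

* tracking tables, one row per cell per frame (CellProfiler-like output of a
  time-lapse movie at a fixed frame interval, default 10 min);
* snapshot tables, one row per cell with the two channels, as a cytometer
  would record an asynchronous population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError
from .gene_model import CellCycleParams, GeneParams
from .population import _as_int_seed, grow_clone, sample_population

__all__ = [
    "MeasurementModel",
    "generate_timelapse_table",
    "generate_cytometry_snapshot",
    "positivity_threshold",
]


@dataclass(frozen=True)
class MeasurementModel:
    """Optical response: measured = gain * count * LogNormal(cv) + floor.

    ``noise_cv`` is the CV of the multiplicative lognormal term (0 disables
    it); the floor is Gaussian with mean ``floor_mean`` and SD ``floor_sd``
    (both 0 disable it); ``gain`` is fluorescence units per molecule.
    """

    noise_cv: float = 0.05
    floor_mean: float = 2.0
    floor_sd: float = 0.7
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not (self.noise_cv >= 0):
            raise InvalidParameterError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if not (self.gain > 0):
            raise InvalidParameterError(f"gain must be > 0, got {self.gain}")
        if self.floor_mean < 0 or self.floor_sd < 0:
            raise InvalidParameterError("floor parameters must be >= 0")

    def measure(self, counts, rng: np.random.Generator) -> np.ndarray:
        """Apply the response to an array of molecule counts."""
        x = np.asarray(counts, dtype=float) * self.gain
        if self.noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + self.noise_cv**2))
            x = x * rng.lognormal(-0.5 * sigma**2, sigma, size=x.shape)
        if self.floor_mean > 0 or self.floor_sd > 0:
            x = x + rng.normal(self.floor_mean, self.floor_sd, size=x.shape)
        return x

    def floor_sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw from the zero-expression (autofluorescence-only) response."""
        return self.measure(np.zeros(n), rng)


def positivity_threshold(floor_sample) -> float:
    """99th percentile of a zero-expression noise-floor sample: measured
    values above it are called expressing."""
    x = np.asarray(floor_sample, dtype=float)
    if x.size < 100:
        raise InsufficientDataError(
            f"positivity threshold needs >= 100 floor values, got {x.size}"
        )
    return float(np.quantile(x, 0.99))


def generate_timelapse_table(
    genes,
    cycle: CellCycleParams,
    n_founders: int,
    duration: float,
    frame_interval: float = 10.0,
    meas: MeasurementModel | None = None,
    seed=0,
    max_cells: int = 256,
) -> pd.DataFrame:
    """Tracking table of ``n_founders`` independent lineage trees.

    One row per live cell per frame: cell_id, parent_id, frame, time_min,
    total fluorescence per channel (measured total protein), and an
    area proxy (the linear-growth volume with the same multiplicative
    noise).  Cell ids are made unique across founders.
    """
    if duration < frame_interval:
        raise InvalidParameterError(
            f"duration {duration} shorter than one frame ({frame_interval})"
        )
    genes = (genes,) if isinstance(genes, GeneParams) else tuple(genes)
    meas = meas if meas is not None else MeasurementModel()
    frames = np.arange(0.0, duration + 0.5 * frame_interval, frame_interval)
    root = np.random.SeedSequence(_as_int_seed(seed))
    ss_cells, ss_grow, ss_meas = root.spawn(3)
    meas_rng = np.random.default_rng(ss_meas)
    founders = sample_population(genes, cycle, n_founders, seed=ss_cells)
    grow_seeds = ss_grow.spawn(n_founders)
    tables = []
    offset = 0
    for founder, gseed in zip(founders, grow_seeds):
        tab = grow_clone(founder, genes, cycle, float(frames[-1]),
                         max_cells=max_cells, snapshot_times=frames,
                         seed=gseed)
        tab["cell_id"] = tab["cell_id"] + offset
        tab["parent_id"] = tab["parent_id"].where(tab["parent_id"] < 0,
                                                  tab["parent_id"] + offset)
        offset = int(tab["cell_id"].max()) + 1
        tables.append(tab)
    sim = pd.concat(tables, ignore_index=True)
    out = pd.DataFrame({
        "cell_id": sim["cell_id"],
        "parent_id": sim["parent_id"],
        "frame": np.rint(sim["sample_time"] / frame_interval).astype(int),
        "time_min": sim["sample_time"],
    })
    for gp in genes:
        out[f"total_{gp.name}"] = meas.measure(
            sim[f"protein_{gp.name}"].to_numpy(), meas_rng)
    vol = sim["volume"].to_numpy().copy()
    if meas.noise_cv > 0:  # segmentation jitter; no autofluorescence on area
        sigma = math.sqrt(math.log(1.0 + meas.noise_cv**2))
        vol = vol * meas_rng.lognormal(-0.5 * sigma**2, sigma, size=vol.shape)
    out["area_proxy"] = vol
    out = out.sort_values(["frame", "cell_id"]).reset_index(drop=True)
    return out


def generate_cytometry_snapshot(
    genes,
    cycle: CellCycleParams,
    n_cells: int,
    meas: MeasurementModel | None = None,
    seed=0,
    relax_min: float = 4320.0,
) -> pd.DataFrame:
    """Two-channel snapshot of ``n_cells`` independent asynchronous cells.

    Cells are drawn from the model's long-run regime (warm start plus a
    relaxation burn-in; cycle ages end up spread over the cycle) and measured
    with the measurement model.  Columns: ``fluor_<channel>`` per gene plus
    the underlying ``protein_<channel>`` counts and ``volume`` for
    sensitivity checks.
    """
    if n_cells < 1:
        raise InvalidParameterError(f"n_cells must be >= 1, got {n_cells}")
    genes = (genes,) if isinstance(genes, GeneParams) else tuple(genes)
    meas = meas if meas is not None else MeasurementModel()
    root = np.random.SeedSequence(_as_int_seed(seed))
    ss_cells, ss_meas = root.spawn(2)
    meas_rng = np.random.default_rng(ss_meas)
    cells = sample_population(genes, cycle, n_cells, seed=ss_cells,
                              relax_min=relax_min)
    out = pd.DataFrame({"cell_id": [c.cell_id for c in cells],
                        "volume": [c.volume for c in cells]})
    for g, gp in enumerate(genes):
        counts = np.array([c.p[g] for c in cells], dtype=float)
        out[f"protein_{gp.name}"] = counts.astype(int)
        out[f"fluor_{gp.name}"] = meas.measure(counts, meas_rng)
    return out
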