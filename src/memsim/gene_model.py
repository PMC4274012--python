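"""Kinetic model of one reporter gene in a growing, dividing cell.

The promoter is a random telegraph: chromatin switches between a
transcription-permissive OPEN state and a silent CLOSED state at first-order
rates ``k_open``/``k_close``.  While OPEN, transcriptional bursts fire at rate
``k_burst``, each depositing a geometrically distributed number of mRNAs
(mean ``burst_size_mean``; mean 1 degenerates to the classic one-mRNA-per-event
telegraph model).  mRNAs are translated and both species decay with first-order
kinetics.  All rates are per minute; half-lives given in hours in config files
are converted at parse time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError, InvalidStateError

__all__ = [
    "ChromatinState",
    "GeneParams",
    "CellCycleParams",
    "half_life_to_rate",
    "rate_to_half_life",
    "propensities",
    "sample_burst_size",
    "apply_shared_degradation",
]

_LN2 = math.log(2.0)


class ChromatinState(enum.Enum):
    """Two-state promoter/chromatin configuration."""

    OPEN = "open"
    CLOSED = "closed"


def half_life_to_rate(t_half: float) -> float:
    """First-order rate constant (1/min) for a half-life in minutes.

    Strictly decreasing in ``t_half``; raises for non-positive input.
    """
    if not (t_half > 0):
        raise InvalidParameterError(f"half-life must be > 0, got {t_half!r}")
    return _LN2 / t_half


def rate_to_half_life(rate: float) -> float:
    """Half-life in minutes for a first-order rate constant (1/min)."""
    if not (rate > 0):
        raise InvalidParameterError(f"rate must be > 0, got {rate!r}")
    return _LN2 / rate


@dataclass(frozen=True)
class GeneParams:
    """Kinetic rates of one reporter gene.

    Parameters
    ----------
    k_open, k_close : float
        Chromatin opening/closing rates (1/min).  Their ratio sets the
        long-run fraction of time the promoter spends OPEN.
    k_burst : float
        Burst initiation rate while chromatin is OPEN (1/min).
    burst_size_mean : float
        Mean mRNAs per burst; >= 1.  Bursts are shifted-geometric on
        {1, 2, ...}; mean 1 means exactly one mRNA per burst.
    k_tl : float
        Translation rate per mRNA (proteins/mRNA/min).
    delta_m, delta_p : float
        mRNA / protein first-order degradation rates (1/min).
    name : str
        Channel label (e.g. ``"yfp"``); used in output tables.
    """

    k_open: float
    k_close: float
    k_burst: float
    burst_size_mean: float
    k_tl: float
    delta_m: float
    delta_p: float
    name: str = "gene"

    def __post_init__(self) -> None:
        for field in ("k_open", "k_close", "k_burst", "k_tl", "delta_m", "delta_p"):
            v = getattr(self, field)
            if not (v >= 0) or not math.isfinite(v):
                raise InvalidParameterError(f"{field} must be finite and >= 0, got {v!r}")
        if not (self.burst_size_mean >= 1):
            raise InvalidParameterError(
                f"burst_size_mean must be >= 1, got {self.burst_size_mean!r}"
            )

    @property
    def open_fraction(self) -> float:
        """Stationary probability of the OPEN chromatin state."""
        tot = self.k_open + self.k_close
        if tot == 0:
            raise InvalidParameterError("open_fraction undefined: both switch rates are 0")
        return self.k_open / tot

    def with_(self, **changes) -> "GeneParams":
        """Copy with selected fields replaced (e.g. ``with_(delta_p=0.0)``)."""
        return replace(self, **changes)

    @classmethod
    def from_half_lives(
        cls,
        *,
        mrna_half_life_min: float,
        protein_half_life_min: float,
        k_open: float,
        k_close: float,
        k_burst: float,
        burst_size_mean: float = 1.0,
        k_tl: float = 0.0,
        name: str = "gene",
    ) -> "GeneParams":
        """Construct with degradation given as half-lives in minutes."""
        return cls(
            k_open=k_open,
            k_close=k_close,
            k_burst=k_burst,
            burst_size_mean=burst_size_mean,
            k_tl=k_tl,
            delta_m=half_life_to_rate(mrna_half_life_min),
            delta_p=half_life_to_rate(protein_half_life_min),
            name=name,
        )


@dataclass(frozen=True)
class CellCycleParams:
    """Cell-cycle clock.

    ``T_div`` is the mean cycle length in minutes; ``cv_div`` the coefficient
    of variation of sampled cycle lengths (0 gives strictly periodic
    divisions).  Sampled lengths are normal, truncated below at
    ``0.5 * T_div`` so a pathological draw can never produce an instant or
    negative cycle.  Volume grows linearly from 1 at birth to 2 at division.
    """

    T_div: float
    cv_div: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T_div > 0):
            raise InvalidParameterError(f"T_div must be > 0, got {self.T_div!r}")
        if not (self.cv_div >= 0):
            raise InvalidParameterError(f"cv_div must be >= 0, got {self.cv_div!r}")

    def sample_cycle_length(self, rng: np.random.Generator) -> float:
        if self.cv_div == 0:
            return self.T_div
        draw = rng.normal(self.T_div, self.cv_div * self.T_div)
        return max(draw, 0.5 * self.T_div)


#: Reaction channel labels, in the order `propensities` reports them.
REACTIONS = ("switch", "burst", "mrna_decay", "translation", "protein_decay")


def propensities(
    chromatin: ChromatinState,
    m: int,
    p: int,
    params: GeneParams,
    clamp: ChromatinState | None = None,
) -> dict[str, float]:
    """Instantaneous reaction rates for one gene.

    Five channels: chromatin switch (``k_open`` if CLOSED, ``k_close`` if
    OPEN; 0 while clamped), burst initiation (``k_burst`` only while OPEN),
    mRNA decay ``m*delta_m``, translation ``m*k_tl``, protein decay
    ``p*delta_p``.
    """
    if m < 0 or p < 0:
        raise InvalidStateError(f"molecule counts must be >= 0, got m={m}, p={p}")
    if clamp is not None:
        switch = 0.0
    else:
        switch = params.k_open if chromatin is ChromatinState.CLOSED else params.k_close
    burst = params.k_burst if chromatin is ChromatinState.OPEN else 0.0
    return {
        "switch": switch,
        "burst": burst,
        "mrna_decay": m * params.delta_m,
        "translation": m * params.k_tl,
        "protein_decay": p * params.delta_p,
    }


def sample_burst_size(burst_size_mean: float, rng: np.random.Generator) -> int:
    """Number of mRNAs produced by one burst.

    Shifted geometric on {1, 2, ...} with the given mean: 1 + Geometric
    failures with success probability 1/mean.  Mean 1 is deterministic.
    """
    if not (burst_size_mean >= 1):
        raise InvalidParameterError(
            f"burst_size_mean must be >= 1, got {burst_size_mean!r}"
        )
    if burst_size_mean == 1:
        return 1
    # numpy's geometric is on {1, 2, ...} with mean 1/p.
    return int(rng.geometric(1.0 / burst_size_mean))


def apply_shared_degradation(
    genes,
    cv: float,
    rng: np.random.Generator,
):
    """Scale both genes' protein decay by one per-cell lognormal factor.

    Models a cell-wide degradation capacity shared by the two reporters
    (mean-1 lognormal with coefficient of variation ``cv``); ``cv = 0``
    returns the genes unchanged.  The same factor multiplies ``delta_p`` of
    every gene, correlating their effective protein half-lives within a cell
    while leaving the genes otherwise independent.
    """
    if cv < 0:
        raise InvalidParameterError(f"shared degradation cv must be >= 0, got {cv}")
    genes = (genes,) if isinstance(genes, GeneParams) else tuple(genes)
    if cv == 0:
        return genes
    sigma = math.sqrt(math.log(1.0 + cv**2))
    factor = float(rng.lognormal(-0.5 * sigma**2, sigma))
    return tuple(g.with_(delta_p=g.delta_p * factor) for g in genes)
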