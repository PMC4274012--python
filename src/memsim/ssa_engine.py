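"""Exact stochastic simulation of one cell line through growth and division.

The reaction network of each gene (chromatin switch, burst, mRNA decay,
translation, protein decay) is simulated with the Gillespie direct method.
Cell divisions are *scheduled* events, not reaction channels: each cycle has a
sampled length, molecules are partitioned between the daughters when it ends,
and for a followed line one daughter is chosen by a fair coin.  Interventions
(chromatin clamps, photobleaching) interrupt the simulation exactly at their
onset times.  Trajectories are piecewise constant, so traces are sampled onto
a regular grid by last-value-carried-forward; a grid point coinciding with a
scheduled event records the pre-event state.

Randomness: every public entry point takes a seed, a ``numpy`` ``Generator``
or a ``SeedSequence``.  Population-level code derives per-cell child streams
with ``SeedSequence.spawn`` in cell-creation order, so runs are reproducible
regardless of scheduling details.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    InvalidParameterError,
    InvalidStateError,
    SimulationError,
)
from .gene_model import CellCycleParams, ChromatinState, GeneParams, sample_burst_size

__all__ = [
    "CellState",
    "Trace",
    "Intervention",
    "as_generator",
    "volume_at",
    "divide",
    "apply_intervention",
    "simulate_cell",
    "stationary_guess",
]


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def volume_at(age: float, cycle_length: float) -> float:
    """Cell volume, growing linearly from 1 at birth to 2 at division."""
    if not (0 <= age <= cycle_length):
        raise InvalidStateError(
            f"age {age} outside cycle [0, {cycle_length}]"
        )
    return 1.0 + age / cycle_length


@dataclass
class CellState:
    """Instantaneous state of one cell.

    ``chromatin``, ``m``, ``p`` and ``clamp`` are per-gene lists indexed like
    the ``genes`` sequence the simulator was given.  ``clamp[g]`` is ``None``
    when chromatin switches freely, or the ``ChromatinState`` it is pinned to.
    """

    chromatin: list
    m: list
    p: list
    age: float = 0.0
    cycle_length: float = 1080.0
    cell_id: int = 0
    parent_id: int = -1
    generation: int = 0
    clamp: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.chromatin)
        if not (len(self.m) == len(self.p) == n):
            raise InvalidStateError("chromatin/m/p must have one entry per gene")
        if any(int(x) != x or x < 0 for x in self.m + self.p):
            raise InvalidStateError("molecule counts must be non-negative integers")
        if not self.clamp:
            self.clamp = [None] * n
        if not (0 <= self.age <= self.cycle_length):
            raise InvalidStateError("age must lie within [0, cycle_length]")

    @property
    def n_genes(self) -> int:
        return len(self.m)

    @property
    def volume(self) -> float:
        return volume_at(self.age, self.cycle_length)

    def copy(self) -> "CellState":
        return CellState(
            chromatin=list(self.chromatin),
            m=list(self.m),
            p=list(self.p),
            age=self.age,
            cycle_length=self.cycle_length,
            cell_id=self.cell_id,
            parent_id=self.parent_id,
            generation=self.generation,
            clamp=list(self.clamp),
        )

    @classmethod
    def fresh(cls, n_genes: int, cycle_length: float, open_chromatin: bool = False,
              cell_id: int = 0) -> "CellState":
        state = ChromatinState.OPEN if open_chromatin else ChromatinState.CLOSED
        return cls(
            chromatin=[state] * n_genes,
            m=[0] * n_genes,
            p=[0] * n_genes,
            age=0.0,
            cycle_length=cycle_length,
            cell_id=cell_id,
        )


@dataclass(frozen=True)
class Intervention:
    """A scheduled perturbation of a followed cell.

    kinds: ``CLAMP_OPEN`` / ``CLAMP_CLOSED`` pin chromatin of ``gene`` (an
    index, or ``None`` for all genes) from ``time`` on; ``RELEASE`` lifts a
    clamp; ``BLEACH`` instantaneously reduces the protein count of ``gene``
    to ``round(p * bleach_fraction)``.
    """

    kind: str
    time: float
    gene: int | None = None
    bleach_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("CLAMP_OPEN", "CLAMP_CLOSED", "RELEASE", "BLEACH"):
            raise ConfigError(f"unknown intervention kind {self.kind!r}")
        if self.kind == "BLEACH":
            if not (0 < self.bleach_fraction <= 1):
                raise ConfigError(
                    f"bleach_fraction must be in (0, 1], got {self.bleach_fraction!r}"
                )
            if self.gene is None:
                raise ConfigError("BLEACH requires a target gene index")


def apply_intervention(state: CellState, iv: Intervention,
                       rng: np.random.Generator | None = None) -> CellState:
    """Return a copy of ``state`` with the intervention applied."""
    out = state.copy()
    targets = range(out.n_genes) if iv.gene is None else (iv.gene,)
    if iv.kind == "BLEACH":
        g = iv.gene
        out.p[g] = int(round(out.p[g] * iv.bleach_fraction))
    elif iv.kind == "RELEASE":
        for g in targets:
            out.clamp[g] = None
    else:
        target_state = (
            ChromatinState.OPEN if iv.kind == "CLAMP_OPEN" else ChromatinState.CLOSED
        )
        for g in targets:
            out.clamp[g] = target_state
            out.chromatin[g] = target_state
    return out


def divide(
    state: CellState,
    rng: np.random.Generator,
    cycle: CellCycleParams | None = None,
    mode: str = "EQUAL",
    next_ids: tuple[int, int] = (1, 2),
) -> tuple[CellState, CellState]:
    """Split a cell at the end of its cycle into two daughters.

    Counts are conserved per species and gene.  ``EQUAL``: each daughter gets
    half, the odd molecule by fair coin.  ``BINOMIAL``: daughter 1 gets
    Binomial(n, 1/2).  Chromatin state and clamps are inherited identically;
    daughters restart at age 0 (volume 1) with freshly sampled cycle lengths.
    """
    if mode not in ("EQUAL", "BINOMIAL"):
        raise InvalidParameterError(f"unknown partition mode {mode!r}")
    if not math.isclose(state.age, state.cycle_length, rel_tol=1e-9, abs_tol=1e-6):
        raise InvalidStateError(
            f"divide() before end of cycle: age={state.age}, "
            f"cycle_length={state.cycle_length}"
        )

    def split(n: int) -> tuple[int, int]:
        if mode == "BINOMIAL":
            a = int(rng.binomial(n, 0.5))
        else:
            a = n // 2
            if n % 2 and rng.random() < 0.5:
                a += 1
        return a, n - a

    def new_length() -> float:
        if cycle is None:
            return state.cycle_length
        return cycle.sample_cycle_length(rng)

    d = []
    halves = [split(n) for n in state.m], [split(n) for n in state.p]
    for i in range(2):
        d.append(
            CellState(
                chromatin=list(state.chromatin),
                m=[h[i] for h in halves[0]],
                p=[h[i] for h in halves[1]],
                age=0.0,
                cycle_length=new_length(),
                cell_id=next_ids[i],
                parent_id=state.cell_id,
                generation=state.generation + 1,
                clamp=list(state.clamp),
            )
        )
    return d[0], d[1]


# ---------------------------------------------------------------------------
# Gillespie core


def _gene_tuple(g: GeneParams):
    return (g.k_open, g.k_close, g.k_burst, g.burst_size_mean, g.k_tl,
            g.delta_m, g.delta_p)


def _ssa_segment(params, open_, m, p, clamped, rng, t, t_stop,
                 sample_times, si, record):
    """Advance the reaction network from ``t`` to ``t_stop`` (no scheduled
    events inside), recording LVCF samples.  Mutates ``open_``, ``m``, ``p``.

    ``sample_times`` is the full grid; ``si`` the index of the next pending
    sample; ``record(time_index)`` snapshots the current state.  Returns the
    updated sample index.
    """
    G = len(params)
    n_samples = len(sample_times)
    rand = rng.random
    rexp = rng.standard_exponential
    while True:
        total = 0.0
        props = []
        for g in range(G):
            k_open, k_close, k_burst, bmean, k_tl, dm, dp = params[g]
            og = open_[g]
            sw = 0.0 if clamped[g] else (k_close if og else k_open)
            bu = k_burst if og else 0.0
            md = m[g] * dm
            tl = m[g] * k_tl
            pd_ = p[g] * dp
            props.append((sw, bu, md, tl, pd_))
            total += sw + bu + md + tl + pd_
        if total <= 0.0:
            t_next = math.inf
        else:
            if not math.isfinite(total):
                raise SimulationError(f"propensity overflow at t={t}")
            t_next = t + rexp() / total
        # flush samples passed by this waiting time
        while si < n_samples and sample_times[si] < t_next:
            if sample_times[si] > t_stop:
                break
            record(si)
            si += 1
        if t_next >= t_stop:
            return si
        t = t_next
        # pick reaction
        u = rand() * total
        acc = 0.0
        hit = None
        for g in range(G):
            for r in range(5):
                acc += props[g][r]
                if u < acc:
                    hit = (g, r)
                    break
            if hit is not None:
                break
        if hit is None:  # float round-off: take the last non-zero channel
            for g in reversed(range(G)):
                for r in reversed(range(5)):
                    if props[g][r] > 0:
                        hit = (g, r)
                        break
                if hit is not None:
                    break
        g, r = hit
        if r == 0:
            open_[g] = not open_[g]
        elif r == 1:
            m[g] += sample_burst_size(params[g][3], rng)
        elif r == 2:
            m[g] -= 1
        elif r == 3:
            p[g] += 1
        else:
            p[g] -= 1


# ---------------------------------------------------------------------------
# Trace container


@dataclass
class Trace:
    """Regular-grid record of one followed cell line.

    Arrays are indexed ``[gene, time]`` except ``times``, ``volume`` and
    ``generation``.  ``norm_level`` is the protein count divided by the
    linearly growing cell volume — the analogue of mean fluorescence.
    """

    times: np.ndarray
    m: np.ndarray
    p: np.ndarray
    chromatin_open: np.ndarray
    volume: np.ndarray
    generation: np.ndarray
    cell_ids: np.ndarray
    division_times: list
    gene_names: tuple
    cell_id: int = 0

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def norm_level(self) -> np.ndarray:
        return self.p / self.volume[None, :]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per gene per grid point."""
        frames = []
        for g, name in enumerate(self.gene_names):
            frames.append(
                pd.DataFrame(
                    {
                        "time_min": self.times,
                        "gene": name,
                        "chromatin": np.where(self.chromatin_open[g], "open", "closed"),
                        "mrna": self.m[g],
                        "protein": self.p[g],
                        "volume": self.volume,
                        "norm_level": self.norm_level[g],
                        "cell_id": self.cell_ids,
                        "generation": self.generation,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def stationary_guess(
    genes: tuple[GeneParams, ...],
    cycle: CellCycleParams | None,
    rng: np.random.Generator,
    open_only: bool = False,
) -> CellState:
    """Approximate draw from the model's long-run state.

    Chromatin is Bernoulli(open fraction); molecule counts are Poisson at the
    conditional quasi-stationary mean, with dilution by growth/division folded
    in as an extra first-order decay ln2/T_div.  Cells found CLOSED carry
    residual product decayed over an exponential elapsed-closed time.  This is
    a warm start, not an exact sample: follow it with a burn-in of a few
    protein lifetimes before measuring.
    """
    dil = math.log(2.0) / cycle.T_div if cycle is not None else 0.0
    chromatin, ms, ps = [], [], []
    for gp in genes:
        dm_eff = gp.delta_m + dil
        dp_eff = gp.delta_p + dil
        m_open = gp.k_burst * gp.burst_size_mean / dm_eff if dm_eff > 0 else 0.0
        p_open = m_open * gp.k_tl / dp_eff if dp_eff > 0 else 0.0
        if open_only or (gp.k_open + gp.k_close) == 0:
            is_open = True
        else:
            is_open = rng.random() < gp.open_fraction
        if is_open:
            m_mean, p_mean = m_open, p_open
        else:
            elapsed = rng.exponential(1.0 / gp.k_open) if gp.k_open > 0 else math.inf
            m_mean = m_open * math.exp(-dm_eff * elapsed)
            p_mean = p_open * math.exp(-dp_eff * elapsed)
        chromatin.append(ChromatinState.OPEN if is_open else ChromatinState.CLOSED)
        ms.append(int(rng.poisson(m_mean)))
        ps.append(int(rng.poisson(p_mean)))
    if cycle is not None:
        length = cycle.sample_cycle_length(rng)
        age = rng.uniform(0.0, length)
    else:
        length, age = math.inf, 0.0
    return CellState(chromatin=chromatin, m=ms, p=ps, age=age,
                     cycle_length=length if math.isfinite(length) else 1e18)


def simulate_cell(
    genes,
    cycle: CellCycleParams | None,
    t_end: float,
    dt: float = 10.0,
    interventions=(),
    seed=0,
    init: CellState | str = "stationary-guess",
    partition_mode: str = "EQUAL",
) -> Trace:
    """Simulate one followed cell line and sample it on a regular grid.

    Between scheduled events the dynamics are exact Gillespie.  At each
    division the cell is split with :func:`divide` and one daughter is
    followed, chosen by fair coin.  ``cycle=None`` disables division and
    freezes the volume at 1.  ``init`` may be a :class:`CellState`, the
    string ``"stationary-guess"`` (see :func:`stationary_guess`) or
    ``"zero"`` (fresh closed cell with no molecules).

    Identical seeds give bit-identical traces.
    """
    if isinstance(genes, GeneParams):
        genes = (genes,)
    genes = tuple(genes)
    if t_end <= 0 or dt <= 0:
        raise SimulationError(f"t_end and dt must be > 0 (got {t_end}, {dt})")
    if t_end < dt:
        raise SimulationError(f"t_end={t_end} shorter than sampling interval dt={dt}")
    rng = as_generator(seed)

    if isinstance(init, CellState):
        state = init.copy()
    elif init == "stationary-guess":
        state = stationary_guess(genes, cycle, rng)
    elif init == "zero":
        length = cycle.sample_cycle_length(rng) if cycle is not None else 1e18
        state = CellState.fresh(len(genes), cycle_length=length)
    else:
        raise InvalidParameterError(f"unknown init {init!r}")

    params = [_gene_tuple(g) for g in genes]
    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    n = len(times)
    G = len(genes)
    m_out = np.empty((G, n), dtype=np.int64)
    p_out = np.empty((G, n), dtype=np.int64)
    open_out = np.empty((G, n), dtype=bool)
    vol_out = np.empty(n)
    gen_out = np.empty(n, dtype=np.int64)
    id_out = np.empty(n, dtype=np.int64)
    division_times: list[float] = []

    open_ = [c is ChromatinState.OPEN for c in state.chromatin]
    m = list(state.m)
    p = list(state.p)
    clamped = [c is not None for c in state.clamp]

    t_now = 0.0
    # cell-local clock: state.age at t=0
    birth_t = -state.age

    def record(i: int) -> None:
        ts = times[i]
        age = min(ts - birth_t, state.cycle_length)
        for g in range(G):
            m_out[g, i] = m[g]
            p_out[g, i] = p[g]
            open_out[g, i] = open_[g]
        vol_out[i] = volume_at(age, state.cycle_length) if cycle is not None else 1.0
        gen_out[i] = state.generation
        id_out[i] = state.cell_id

    ivs = sorted(interventions, key=lambda iv: iv.time)
    iv_idx = 0
    si = 0
    next_id = state.cell_id + 1
    while t_now < t_end:
        next_div = birth_t + state.cycle_length if cycle is not None else math.inf
        next_iv = ivs[iv_idx].time if iv_idx < len(ivs) else math.inf
        t_stop = min(next_div, next_iv, t_end)
        si = _ssa_segment(params, open_, m, p, clamped, rng, t_now, t_stop,
                          times, si, record)
        t_now = t_stop
        # apply scheduled events due now (samples at t_stop already recorded
        # pre-event by _ssa_segment)
        while si < n and times[si] <= t_now:
            record(si)
            si += 1
        if t_now >= t_end:
            break
        if next_iv <= t_now:
            state.chromatin = [ChromatinState.OPEN if o else ChromatinState.CLOSED
                               for o in open_]
            state.m, state.p = list(m), list(p)
            state.age = min(t_now - birth_t, state.cycle_length)
            state = apply_intervention(state, ivs[iv_idx], rng)
            iv_idx += 1
            open_ = [c is ChromatinState.OPEN for c in state.chromatin]
            m, p = list(state.m), list(state.p)
            clamped = [c is not None for c in state.clamp]
            continue
        # division
        state.chromatin = [ChromatinState.OPEN if o else ChromatinState.CLOSED
                           for o in open_]
        state.m, state.p = list(m), list(p)
        state.age = state.cycle_length
        d1, d2 = divide(state, rng, cycle, mode=partition_mode,
                        next_ids=(next_id, next_id + 1))
        next_id += 2
        state = d1 if rng.random() < 0.5 else d2
        division_times.append(t_now)
        birth_t = t_now
        open_ = [c is ChromatinState.OPEN for c in state.chromatin]
        m, p = list(state.m), list(state.p)
        clamped = [c is not None for c in state.clamp]
    # trailing samples (grid point exactly at t_end)
    while si < n:
        record(si)
        si += 1

    return Trace(
        times=times,
        m=m_out,
        p=p_out,
        chromatin_open=open_out,
        volume=vol_out,
        generation=gen_out,
        cell_ids=id_out,
        division_times=division_times,
        gene_names=tuple(g.name for g in genes),
        cell_id=state.cell_id,
    )
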