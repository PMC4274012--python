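"""Population-level in-silico experiments.

Reproduces the study designs around the single-cell simulator: growth of a
clone from one founder with full lineage records and passaging, relaxation of
sorted subclones (high / low / non-expressing founders) toward the parental
distribution, whole-cell photobleaching (FRAP) cohorts with inhibitor
controls, transcriptional-silencing lineages, and per-cell autocorrelation
cohorts.

All experiments draw per-cell random streams by ``SeedSequence.spawn`` in
cell-creation order, so results are reproducible for a fixed root seed.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, SelectionError, UndefinedStatisticError
from .fluctuation_stats import autocorrelation, fraction_positive, normalized_variance
from .gene_model import (
    CellCycleParams,
    ChromatinState,
    GeneParams,
    apply_shared_degradation,
)
from .ssa_engine import (
    CellState,
    Intervention,
    _gene_tuple,
    _ssa_segment,
    apply_intervention,
    as_generator,
    divide,
    simulate_cell,
    stationary_guess,
    volume_at,
)

__all__ = [
    "SubcloneTimecourse",
    "grow_clone",
    "validate_lineage",
    "select_founders",
    "subclone_experiment",
    "frap_experiment",
    "silencing_scenario",
    "tau_half_cohort",
    "mother_daughter_levels",
    "sample_population",
]

FOUNDER_CLASSES = ("HIGH", "LOW", "NEGATIVE")


# ---------------------------------------------------------------------------
# clone growth with lineage records


def _run_cell_segment(state, params, rng, t_birth, t_stop, snap_times, rows,
                     genes):
    """Advance one cell from ``t_birth`` to ``t_stop`` (<= its division time),
    appending one row per snapshot time falling in the cell's lifetime."""
    open_ = [c is ChromatinState.OPEN for c in state.chromatin]
    m, p = list(state.m), list(state.p)
    clamped = [c is not None for c in state.clamp]
    birth_age = state.age
    local_birth = t_birth - birth_age  # absolute time the cycle started

    def record(i):
        ts = snap_times[i]
        age = min(ts - local_birth, state.cycle_length)
        vol = volume_at(age, state.cycle_length)
        row = {
            "cell_id": state.cell_id,
            "parent_id": state.parent_id,
            "generation": state.generation,
            "birth_time": t_birth,
            "sample_time": ts,
            "volume": vol,
        }
        for g, gp in enumerate(genes):
            row[f"mrna_{gp.name}"] = m[g]
            row[f"protein_{gp.name}"] = p[g]
            row[f"norm_level_{gp.name}"] = p[g] / vol
            row[f"chromatin_{gp.name}"] = "open" if open_[g] else "closed"
        rows.append(row)

    _ssa_segment(params, open_, m, p, clamped, rng, t_birth, t_stop,
                 snap_times, 0, record)
    state.chromatin = [ChromatinState.OPEN if o else ChromatinState.CLOSED
                       for o in open_]
    state.m, state.p = m, p
    state.age = min(birth_age + (t_stop - t_birth), state.cycle_length)
    return state


def grow_clone(
    founder: CellState,
    genes,
    cycle: CellCycleParams,
    t_end: float,
    max_cells: int = 512,
    snapshot_times=(),
    seed=0,
    partition_mode: str = "EQUAL",
) -> pd.DataFrame:
    """Grow the full binary lineage from one founder.

    Every live cell is simulated from birth to division (or ``t_end``); one
    table row is emitted per live cell per snapshot time.  When the pending
    population exceeds ``max_cells`` a uniform random subsample of
    ``max_cells`` cells is retained, emulating passaging.  Founder time is 0;
    a founder with ``age > 0`` continues its current cycle.
    """
    if isinstance(genes, GeneParams):
        genes = (genes,)
    genes = tuple(genes)
    if max_cells < 1:
        raise ConfigError(f"max_cells must be >= 1, got {max_cells}")
    snap_times = np.asarray(sorted(snapshot_times), dtype=float)
    if snap_times.size and snap_times[-1] > t_end:
        raise ConfigError(
            f"snapshot time {snap_times[-1]} exceeds t_end={t_end}"
        )
    params = [_gene_tuple(g) for g in genes]
    root = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    passage_rng = np.random.default_rng(root.spawn(1)[0])

    rows: list[dict] = []
    founder = founder.copy()
    founder.cell_id = 0
    founder.parent_id = -1
    next_id = 1
    seq = 0
    # heap entries: (birth_time, seq, state, seed_sequence)
    heap = [(0.0, seq, founder, root.spawn(1)[0])]
    while heap:
        t_birth, _, state, ss = heapq.heappop(heap)
        rng = np.random.default_rng(ss)
        t_div = t_birth + (state.cycle_length - state.age)
        t_stop = min(t_div, t_end)
        # snapshots during [birth, min(div, t_end)); cells alive at the
        # horizon are recorded at t_end itself.  A division at exactly t_end
        # happens: the daughters are the cells observed there.
        if t_div > t_end:
            mask = (snap_times >= t_birth) & (snap_times <= t_end)
        else:
            mask = (snap_times >= t_birth) & (snap_times < t_div)
        _run_cell_segment(state, params, rng, t_birth, t_stop,
                          snap_times[mask], rows, genes)
        if t_div > t_end:
            continue
        d1, d2 = divide(state, rng, cycle, mode=partition_mode,
                        next_ids=(next_id, next_id + 1))
        next_id += 2
        for d in (d1, d2):
            seq += 1
            heapq.heappush(heap, (t_div, seq, d, root.spawn(1)[0]))
        if len(heap) > max_cells:
            keep = passage_rng.choice(len(heap), size=max_cells, replace=False)
            heap = [heap[i] for i in sorted(keep)]
            heapq.heapify(heap)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["sample_time", "cell_id"]).reset_index(drop=True)
    return df


def validate_lineage(table: pd.DataFrame) -> None:
    """Check lineage integrity: every non-founder parent exists in the table
    and child generation = parent generation + 1.  Raises AssertionError."""
    if table.empty:
        return
    gen = dict(zip(table["cell_id"], table["generation"]))
    for cid, pid, g in zip(table["cell_id"], table["parent_id"],
                           table["generation"]):
        if pid == -1:
            continue
        assert pid in gen, f"parent {pid} of cell {cid} missing from table"
        assert g == gen[pid] + 1, (
            f"generation of cell {cid} is {g}, parent {pid} has {gen[pid]}"
        )


# ---------------------------------------------------------------------------
# founder sorting and subclone relaxation


def sample_population(
    genes,
    cycle: CellCycleParams,
    n_cells: int,
    seed=0,
    relax_min: float = 4320.0,
) -> list[CellState]:
    """Draw ``n_cells`` independent cells from the model's long-run regime.

    Each cell is warm-started from :func:`stationary_guess` and relaxed by
    ``relax_min`` minutes (default 3 days) of full simulation, divisions
    included, to settle the warm start's conditional approximations.
    """
    if isinstance(genes, GeneParams):
        genes = (genes,)
    genes = tuple(genes)
    root = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    params = [_gene_tuple(g) for g in genes]
    cells = []
    for i, ss in enumerate(root.spawn(n_cells)):
        rng = np.random.default_rng(ss)
        state = stationary_guess(genes, cycle, rng)
        t = 0.0
        t_end = relax_min
        birth = -state.age
        while t < t_end:
            t_div = birth + state.cycle_length
            t_stop = min(t_div, t_end)
            state = _run_cell_segment(state, params, rng, t, t_stop,
                                      np.empty(0), [], genes)
            t = t_stop
            if t_div <= t_end:
                d1, d2 = divide(state, rng, cycle)
                state = d1 if rng.random() < 0.5 else d2
                birth = t
        state.cell_id = i
        cells.append(state)
    return cells


def select_founders(
    snapshot: list[CellState],
    cls: str,
    threshold: float,
    rng=None,
    n: int = 1,
    gene: int = 0,
):
    """Pick founder cell(s) of a sorting class from a population snapshot.

    ``NEGATIVE``: normalized level of ``gene`` at or below the positivity
    ``threshold``.  ``LOW`` / ``HIGH``: uniform draws from the bottom
    quartile / top decile of *positive* cells.  Returns a single
    :class:`CellState` when ``n == 1``, else a list.
    """
    if cls not in FOUNDER_CLASSES:
        raise SelectionError(f"unknown founder class {cls!r}")
    if not snapshot:
        raise SelectionError("empty population snapshot")
    rng = as_generator(rng if rng is not None else 0)
    levels = np.array([c.p[gene] / c.volume for c in snapshot])
    if cls == "NEGATIVE":
        pool = [c for c, lv in zip(snapshot, levels) if lv <= threshold]
    else:
        pos = [(c, lv) for c, lv in zip(snapshot, levels) if lv > threshold]
        if not pos:
            raise SelectionError(f"no cells available for class {cls}")
        pos_levels = np.array([lv for _, lv in pos])
        if cls == "LOW":
            cut = np.quantile(pos_levels, 0.25)
            pool = [c for c, lv in pos if lv <= cut]
        else:  # HIGH
            cut = np.quantile(pos_levels, 0.90)
            pool = [c for c, lv in pos if lv >= cut]
    if not pool:
        raise SelectionError(f"no cells available for class {cls}")
    picks = [pool[int(i)].copy() for i in rng.integers(0, len(pool), size=n)]
    return picks[0] if n == 1 else picks


@dataclass
class SubcloneTimecourse:
    """Snapshot statistics of one subclone population over its culture."""

    founder_class: str
    times: np.ndarray
    median: np.ndarray
    nv: np.ndarray
    fraction_positive: np.ndarray
    n_cells: np.ndarray


def subclone_experiment(
    genes,
    cycle: CellCycleParams,
    n_subclones: int,
    duration: float,
    snapshot_times,
    seed=0,
    threshold: float | None = None,
    classes=FOUNDER_CLASSES,
    max_cells: int = 64,
    parental_pool: list[CellState] | None = None,
    parental_n: int = 400,
    gene: int = 0,
) -> list[SubcloneTimecourse]:
    """Sort founders from a parental population and culture subclones.

    For each class in ``classes``, ``n_subclones`` founders are drawn from a
    long-run parental snapshot; each founder is grown with
    :func:`grow_clone` (passaged at ``max_cells``) and the normalized level
    of channel ``gene`` is summarized (median, NV, fraction positive) at
    every snapshot.
    """
    snapshot_times = sorted(snapshot_times)
    if snapshot_times and snapshot_times[-1] > duration:
        raise ConfigError("snapshot schedule extends beyond the culture duration")
    if threshold is None:
        from .presets import default_measurement
        from .synthetic_data import positivity_threshold

        meas = default_measurement()
        rng0 = np.random.default_rng(np.random.SeedSequence(
            [0x5eed, _as_int_seed(seed)]))
        floor = meas.floor_sample(10_000, rng0)
        threshold = positivity_threshold(floor) / meas.gain
    root = np.random.SeedSequence(_as_int_seed(seed))
    ss_pool, ss_pick, ss_grow = root.spawn(3)
    if parental_pool is None:
        parental_pool = sample_population(genes, cycle, parental_n, seed=ss_pool)
    pick_rng = np.random.default_rng(ss_pick)
    grow_seeds = ss_grow.spawn(len(classes) * n_subclones)
    name = genes[gene].name if not isinstance(genes, GeneParams) else genes.name
    out = []
    k = 0
    for cls in classes:
        for _ in range(n_subclones):
            founder = select_founders(parental_pool, cls, threshold,
                                      rng=pick_rng, gene=gene)
            table = grow_clone(founder, genes, cycle, duration,
                               max_cells=max_cells,
                               snapshot_times=snapshot_times,
                               seed=grow_seeds[k])
            k += 1
            med, nv, fp, nc = [], [], [], []
            col = f"norm_level_{name}"
            for t in snapshot_times:
                vals = table.loc[table["sample_time"] == t, col].to_numpy()
                nc.append(vals.size)
                med.append(float(np.median(vals)))
                nv.append(normalized_variance(vals) if vals.size >= 2
                          else math.nan)
                fp.append(fraction_positive(vals, threshold))
            out.append(SubcloneTimecourse(
                founder_class=cls,
                times=np.asarray(snapshot_times, dtype=float),
                median=np.array(med),
                nv=np.array(nv),
                fraction_positive=np.array(fp),
                n_cells=np.array(nc),
            ))
    return out


def _as_int_seed(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0])
    return int(np.random.default_rng(seed).integers(2**31))


# ---------------------------------------------------------------------------
# FRAP


def frap_experiment(
    genes,
    cycle: CellCycleParams,
    n_cells: int,
    bleach_fraction: float = 0.2,
    observe: float = 300.0,
    seed=0,
    control: str = "NONE",
    dt: float = 10.0,
    gene: int = 0,
    n_envelope: int = 30,
) -> pd.DataFrame:
    """Whole-cell photobleaching cohort.

    Each cell is drawn from the model's long-run regime, the protein count of
    channel ``gene`` is instantaneously reduced to ``bleach_fraction`` of its
    value at t=0, and the cell is followed for ``observe`` minutes.
    ``control="NO_TRANSCRIPTION"`` sets the burst rate to 0 at t=0 (DRB-like),
    ``"NO_TRANSLATION"`` the translation rate (cycloheximide-like).

    A cell is labelled ``RECOVERING`` when its terminal/initial normalized
    fluorescence ratio exceeds ``1 + 3 * s``, where ``s`` is half the spread
    of the same ratio in an internal transcription-inhibited envelope
    cohort; otherwise ``FLAT``.  Returns a long table with columns
    cell_id, time_min, norm_level_target, norm_level_control, label.
    """
    if not (0 < bleach_fraction < 1):
        raise ConfigError(
            f"bleach_fraction must be in (0, 1), got {bleach_fraction}"
        )
    if control not in ("NONE", "NO_TRANSCRIPTION", "NO_TRANSLATION"):
        raise ConfigError(f"unknown FRAP control {control!r}")
    genes = (genes,) if isinstance(genes, GeneParams) else tuple(genes)
    root = np.random.SeedSequence(_as_int_seed(seed))
    ss_env, ss_main = root.spawn(2)

    def run_cohort(n, mode, seedseq):
        mod = list(genes)
        if mode == "NO_TRANSCRIPTION":
            mod[gene] = mod[gene].with_(k_burst=0.0)
        elif mode == "NO_TRANSLATION":
            mod[gene] = mod[gene].with_(k_tl=0.0)
        bleach = Intervention(kind="BLEACH", time=0.0, gene=gene,
                              bleach_fraction=bleach_fraction)
        ratios, traces = [], []
        for i, ss in enumerate(seedseq.spawn(n)):
            rng = np.random.default_rng(ss)
            init = stationary_guess(genes, cycle, rng)
            init = apply_intervention(init, bleach, rng)
            tr = simulate_cell(tuple(mod), cycle, observe, dt=dt, seed=rng,
                               init=init)
            x = tr.norm_level[gene]
            x0 = max(x[0], 0.5)  # guard a fully bleached zero-count start
            ratios.append(x[-1] / x0)
            traces.append((i, tr))
        return np.array(ratios), traces

    env_ratios, _ = run_cohort(n_envelope, "NO_TRANSCRIPTION", ss_env)
    envelope_halfwidth = float(np.ptp(env_ratios) / 2.0)
    cutoff = 1.0 + 3.0 * envelope_halfwidth

    ratios, traces = run_cohort(n_cells, control, ss_main)
    other = 1 - gene if len(genes) > 1 else gene
    rows = []
    for (i, tr), ratio in zip(traces, ratios):
        label = "RECOVERING" if ratio > cutoff else "FLAT"
        for j, t in enumerate(tr.times):
            rows.append({
                "cell_id": i,
                "time_min": t,
                "norm_level_target": tr.norm_level[gene][j],
                "norm_level_control": tr.norm_level[other][j],
                "recovery_ratio": ratio,
                "label": label,
            })
    df = pd.DataFrame(rows)
    df.attrs["cutoff"] = cutoff
    df.attrs["envelope_halfwidth"] = envelope_halfwidth
    return df


# ---------------------------------------------------------------------------
# silencing and per-cell memory cohorts


def silencing_scenario(
    genes,
    cycle: CellCycleParams,
    t_clamp: float,
    t_end: float,
    seed=0,
    dt: float = 10.0,
    gene: int = 0,
):
    """Follow one expressing cell line whose channel ``gene`` is
    transcriptionally silenced (chromatin clamped CLOSED) at ``t_clamp``.

    The already synthesized molecules are then diluted by division and
    degraded, while any other channel is untouched.
    """
    if not (t_clamp < t_end):
        raise ConfigError(f"t_clamp={t_clamp} must precede t_end={t_end}")
    genes = (genes,) if isinstance(genes, GeneParams) else tuple(genes)
    rng = as_generator(seed)
    init = stationary_guess(genes, cycle, rng, open_only=True)
    iv = Intervention(kind="CLAMP_CLOSED", time=t_clamp, gene=gene)
    return simulate_cell(genes, cycle, t_end, dt=dt, interventions=[iv],
                         seed=rng, init=init)


def tau_half_cohort(
    genes,
    cycle: CellCycleParams,
    n_cells: int,
    movie_min: float,
    dt: float,
    max_lag: float,
    level_min: float,
    seed=0,
    clamp_open: bool = False,
    shared_degradation_cv: float = 0.0,
) -> pd.DataFrame:
    """Per-cell autocorrelation memory times from simulated movies.

    Each cell line is followed for ``movie_min`` minutes at frame interval
    ``dt`` and every channel's normalized level is autocorrelated with the
    global per-cell mean; tau_half is right-censored at ``max_lag``.
    Channels whose median normalized level stays below ``level_min`` are
    non-expressing (no signal to correlate): ``expressing_<name>`` is False
    and the tau is NaN.  ``clamp_open=True`` pins chromatin OPEN (an
    active-period cohort); ``shared_degradation_cv`` draws one degradation
    factor per cell applied to every channel's protein decay.
    """
    genes = (genes,) if isinstance(genes, GeneParams) else tuple(genes)
    root = np.random.SeedSequence(_as_int_seed(seed))
    rows = []
    for i, ss in enumerate(root.spawn(n_cells)):
        rng = np.random.default_rng(ss)
        cell_genes = apply_shared_degradation(genes, shared_degradation_cv, rng)
        if clamp_open:
            init = stationary_guess(cell_genes, cycle, rng, open_only=True)
            init.clamp = [ChromatinState.OPEN] * len(cell_genes)
            init.chromatin = [ChromatinState.OPEN] * len(cell_genes)
        else:
            init = "stationary-guess"
        tr = simulate_cell(cell_genes, cycle, movie_min, dt=dt, seed=rng,
                           init=init)
        row: dict = {"cell_id": i}
        for g, gp in enumerate(genes):
            x = tr.norm_level[g]
            med = float(np.median(x))
            row[f"median_level_{gp.name}"] = med
            if med < level_min:
                row[f"expressing_{gp.name}"] = False
                row[f"tau_half_{gp.name}"] = math.nan
                row[f"censored_{gp.name}"] = False
                continue
            try:
                res = autocorrelation(x, max_lag=max_lag, dt=dt)
                th, cens = res.tau_half, res.censored
            except UndefinedStatisticError:
                th, cens = max_lag, True
            row[f"expressing_{gp.name}"] = True
            row[f"tau_half_{gp.name}"] = th
            row[f"censored_{gp.name}"] = bool(cens)
        rows.append(row)
    return pd.DataFrame(rows)


def mother_daughter_levels(
    genes,
    cycle: CellCycleParams,
    n_pairs: int,
    seed=0,
    gene: int = 0,
) -> pd.DataFrame:
    """Normalized levels of mothers and daughters around a division.

    Chromatin is clamped OPEN (active-period analysis), so the comparison
    isolates product inheritance from promoter-state inheritance.  Columns:
    ``mother_pre`` (just before division), ``daughter_post`` (just after),
    ``daughter_pre`` (one full daughter cycle later, pre-division).
    """
    genes = (genes,) if isinstance(genes, GeneParams) else tuple(genes)
    params = [_gene_tuple(g) for g in genes]
    root = np.random.SeedSequence(_as_int_seed(seed))
    rows = []
    for ss in root.spawn(n_pairs):
        rng = np.random.default_rng(ss)
        state = stationary_guess(genes, cycle, rng, open_only=True)
        state.clamp = [ChromatinState.OPEN] * len(genes)
        state.chromatin = [ChromatinState.OPEN] * len(genes)
        # finish the mother's current cycle
        remaining = state.cycle_length - state.age
        state = _run_cell_segment(state, params, rng, 0.0, remaining,
                                  np.empty(0), [], genes)
        mother_pre = state.p[gene] / 2.0
        d1, d2 = divide(state, rng, cycle)
        daughter = d1 if rng.random() < 0.5 else d2
        daughter_post = daughter.p[gene] / 1.0
        daughter = _run_cell_segment(daughter, params, rng, 0.0,
                                     daughter.cycle_length, np.empty(0), [],
                                     genes)
        daughter_pre = daughter.p[gene] / 2.0
        rows.append({"mother_pre": mother_pre,
                     "daughter_post": daughter_post,
                     "daughter_pre": daughter_pre})
    return pd.DataFrame(rows)
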