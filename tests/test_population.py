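import math

import numpy as np
import pandas as pd
import pytest

from memsim import presets
from memsim.errors import ConfigError, SelectionError
from memsim.fluctuation_stats import reporter_correlation
from memsim.gene_model import CellCycleParams, ChromatinState
from memsim.population import (
    frap_experiment,
    grow_clone,
    mother_daughter_levels,
    sample_population,
    select_founders,
    silencing_scenario,
    subclone_experiment,
    tau_half_cohort,
    validate_lineage,
)
from memsim.ssa_engine import CellState, simulate_cell

from .conftest import make_gene


def founder(n_genes=2, open_=True, m=0, p=0, cycle_length=1080.0):
    state = ChromatinState.OPEN if open_ else ChromatinState.CLOSED
    return CellState(chromatin=[state] * n_genes, m=[m] * n_genes,
                     p=[p] * n_genes, age=0.0, cycle_length=cycle_length)


class TestGrowClone:
    def test_three_cycles_give_eight_cells(self, stable_pair, cycle):
        tab = grow_clone(founder(), stable_pair, cycle, 3 * cycle.T_div,
                         max_cells=10**6, snapshot_times=[3 * cycle.T_div],
                         seed=1)
        assert (tab.sample_time == 3 * cycle.T_div).sum() == 8

    def test_max_cells_one_is_single_line(self, stable_pair, cycle):
        tab = grow_clone(founder(), stable_pair, cycle, 4 * cycle.T_div,
                         max_cells=1,
                         snapshot_times=np.arange(0, 4 * cycle.T_div + 1, 540.0),
                         seed=2)
        per_snap = tab.groupby("sample_time").size()
        assert per_snap.max() == 1

    def test_passaging_caps_population(self, stable_pair, cycle):
        tab = grow_clone(founder(), stable_pair, cycle, 7 * cycle.T_div,
                         max_cells=16, snapshot_times=[7 * cycle.T_div],
                         seed=3)
        assert 1 <= (tab.sample_time == 7 * cycle.T_div).sum() <= 16

    def test_silent_founder_stays_dark(self, cycle):
        g = make_gene(k_open=0.0, k_close=0.0, k_burst=5.0, k_tl=1.0,
                      delta_m=0.01, delta_p=0.001)
        tab = grow_clone(founder(n_genes=1, open_=False), (g,), cycle,
                         3 * cycle.T_div, max_cells=64,
                         snapshot_times=[cycle.T_div, 3 * cycle.T_div], seed=4)
        assert (tab["protein_g"] == 0).all()
        assert (tab["norm_level_g"] == 0).all()

    def test_snapshot_beyond_horizon_rejected(self, stable_pair, cycle):
        with pytest.raises(ConfigError):
            grow_clone(founder(), stable_pair, cycle, 1000.0,
                       snapshot_times=[2000.0], seed=5)

    def test_lineage_integrity_dense_frames(self, stable_pair, cycle):
        frames = np.arange(0, 2.5 * cycle.T_div + 1, 120.0)
        tab = grow_clone(founder(), stable_pair, cycle, 2.5 * cycle.T_div,
                         max_cells=64, snapshot_times=frames, seed=6)
        validate_lineage(tab)

    def test_validate_catches_corruption(self, stable_pair, cycle):
        frames = np.arange(0, 2 * cycle.T_div + 1, 120.0)
        tab = grow_clone(founder(), stable_pair, cycle, 2 * cycle.T_div,
                         max_cells=64, snapshot_times=frames, seed=7)
        bad = tab.copy()
        bad.loc[bad.index[-1], "generation"] += 1
        with pytest.raises(AssertionError):
            validate_lineage(bad)


def synthetic_snapshot(levels):
    """CellStates at volume 1 with the given gene-0 normalized levels."""
    return [CellState(chromatin=[ChromatinState.OPEN], m=[0], p=[int(lv)],
                      age=0.0, cycle_length=1080.0, cell_id=i)
            for i, lv in enumerate(levels)]


class TestSelectFounders:
    def test_negative_class_empty_raises(self):
        snap = synthetic_snapshot([50, 60, 70])
        with pytest.raises(SelectionError):
            select_founders(snap, "NEGATIVE", threshold=5.0, rng=0)

    def test_singleton_positive_high(self):
        snap = synthetic_snapshot([40])
        cell = select_founders(snap, "HIGH", threshold=5.0, rng=0)
        assert cell.p[0] == 40

    def test_bimodal_ordering(self):
        levels = list(range(10, 20)) + list(range(200, 260, 6))
        snap = synthetic_snapshot(levels)
        hi = select_founders(snap, "HIGH", threshold=5.0, rng=1)
        lo = select_founders(snap, "LOW", threshold=5.0, rng=1)
        assert hi.p[0] > lo.p[0]

    def test_negative_below_threshold(self):
        snap = synthetic_snapshot([1, 2, 3, 80, 90])
        cell = select_founders(snap, "NEGATIVE", threshold=5.0, rng=2)
        assert cell.p[0] <= 5

    def test_unknown_class(self):
        with pytest.raises(SelectionError):
            select_founders(synthetic_snapshot([1]), "MEDIUM", 5.0)


class TestSubclones:
    def test_silenced_gene_never_reactivates(self, cycle):
        # no opening channel: NEGATIVE-founder subclones stay dark forever
        g = make_gene(k_open=0.0, k_close=1e-3, k_burst=5.0, k_tl=0.5,
                      delta_m=0.01, delta_p=1e-3)
        snaps = [5 * cycle.T_div, 10 * cycle.T_div]
        courses = subclone_experiment(
            (g,), cycle, n_subclones=3, duration=10 * cycle.T_div,
            snapshot_times=snaps, seed=8, threshold=3.6,
            classes=("NEGATIVE",), max_cells=24, parental_n=40)
        assert len(courses) == 3
        for tc in courses:
            assert tc.founder_class == "NEGATIVE"
            assert np.all(tc.fraction_positive == 0.0)
            assert np.all(tc.n_cells > 0)

    def test_timecourse_structure(self, stable_pair, cycle):
        snaps = [2 * cycle.T_div, 4 * cycle.T_div]
        courses = subclone_experiment(
            stable_pair, cycle, n_subclones=2, duration=4 * cycle.T_div,
            snapshot_times=snaps, seed=9, threshold=3.6,
            classes=("HIGH", "LOW"), max_cells=16, parental_n=60)
        assert [tc.founder_class for tc in courses] == ["HIGH", "HIGH",
                                                        "LOW", "LOW"]
        for tc in courses:
            assert np.all((0 <= tc.fraction_positive)
                          & (tc.fraction_positive <= 1))
            assert np.all(np.diff(tc.times) > 0)

    def test_positive_founder_nv_stays_in_band(self, cycle):
        # the population noise of expressing-founder subclones neither
        # collapses nor explodes over the 55-day culture
        g = (presets.gene_preset("stable", "yfp"),)
        from memsim.experiments import default_threshold

        snaps = [14 * 1440.0, 35 * 1440.0, 55 * 1440.0]
        courses = subclone_experiment(
            g, cycle, n_subclones=5, duration=55 * 1440.0,
            snapshot_times=snaps, seed=33,
            threshold=default_threshold(0), classes=("HIGH", "LOW"),
            max_cells=48, parental_n=150)
        means = np.nanmean(np.array([tc.nv for tc in courses]), axis=0)
        assert np.all((0.3 < means) & (means < 4.0))
        assert means.max() / means.min() < 4.0

    def test_schedule_beyond_duration_rejected(self, stable_pair, cycle):
        with pytest.raises(ConfigError):
            subclone_experiment(stable_pair, cycle, 1, 1000.0,
                                snapshot_times=[2000.0], seed=0,
                                threshold=3.6, parental_n=10)


SHARP = make_gene(k_open=1.0, k_close=0.0, k_burst=0.5, k_tl=5.0,
                  delta_m=0.5, delta_p=0.01, name="yfp")
DARK = make_gene(k_open=0.0, k_close=1.0, k_burst=0.5, k_tl=5.0,
                 delta_m=0.5, delta_p=0.01, name="yfp")


class TestFrap:
    def test_active_cells_recover(self, cycle):
        # fast mRNA turnover: the transcription-inhibited envelope is flat
        # and ongoing synthesis is unmistakable
        df = frap_experiment((SHARP,), cycle, n_cells=12, seed=10,
                             n_envelope=12)
        labels = df.groupby("cell_id")["label"].first()
        assert (labels == "RECOVERING").mean() > 0.8

    def test_dark_cells_stay_flat(self, cycle):
        df = frap_experiment((DARK,), cycle, n_cells=10, seed=11,
                             n_envelope=10)
        labels = df.groupby("cell_id")["label"].first()
        assert (labels == "FLAT").all()

    @pytest.mark.parametrize("control", ["NO_TRANSCRIPTION", "NO_TRANSLATION"])
    def test_inhibitor_controls_all_flat_sharp(self, cycle, control):
        df = frap_experiment((SHARP,), cycle, n_cells=10, seed=12,
                             control=control, n_envelope=10)
        assert (df.groupby("cell_id")["label"].first() == "FLAT").all()

    def test_translation_control_flat_default_regime(self, stable_pair, cycle):
        df = frap_experiment(stable_pair, cycle, n_cells=10, seed=13,
                             control="NO_TRANSLATION", n_envelope=10)
        assert (df.groupby("cell_id")["label"].first() == "FLAT").all()

    def test_invalid_bleach_fraction(self, stable_pair, cycle):
        with pytest.raises(ConfigError):
            frap_experiment(stable_pair, cycle, 5, bleach_fraction=1.5, seed=0)


class TestSilencing:
    def test_pure_dilution_halving(self, cycle):
        # no reactions at all: k post-clamp divisions leave p0/2^k +- k
        g = make_gene()
        init = CellState(chromatin=[ChromatinState.CLOSED], m=[0], p=[809],
                         age=0.0, cycle_length=cycle.T_div)
        tr = simulate_cell(g, cycle, 5.5 * cycle.T_div, dt=10.0, seed=14,
                           init=init)
        assert len(tr.division_times) == 5
        assert abs(tr.p[0][-1] - 809 / 2**5) <= 5

    def test_clamped_gene_dilutes_over_generations(self, stable_pair, cycle):
        tr = silencing_scenario(stable_pair, cycle, t_clamp=cycle.T_div,
                                t_end=6 * cycle.T_div, seed=15)
        i_clamp = int(cycle.T_div / 10.0)
        p_at_clamp = tr.p[0][i_clamp]
        assert p_at_clamp > 0
        # 43 h half-life: decline is dominated by dilution, visible over
        # >= 3 generations but not instantaneous
        assert tr.p[0][-1] < p_at_clamp / 4
        i_one_gen = int(2 * cycle.T_div / 10.0)
        assert tr.p[0][i_one_gen] > p_at_clamp / 4

    def test_untouched_gene_unaffected_in_distribution(self, stable_pair,
                                                       cycle):
        finals_clamped, finals_free = [], []
        for s in range(30):
            trc = silencing_scenario(stable_pair, cycle,
                                     t_clamp=cycle.T_div,
                                     t_end=4 * cycle.T_div, seed=100 + s)
            finals_clamped.append(trc.norm_level[1][-1])
            rng = np.random.default_rng(200 + s)
            from memsim.ssa_engine import stationary_guess

            init = stationary_guess(stable_pair, cycle, rng, open_only=True)
            trf = simulate_cell(stable_pair, cycle, 4 * cycle.T_div, dt=10.0,
                                seed=rng, init=init)
            finals_free.append(trf.norm_level[1][-1])
        a, b = np.array(finals_clamped), np.array(finals_free)
        se = math.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_clamp_must_precede_end(self, stable_pair, cycle):
        with pytest.raises(ConfigError):
            silencing_scenario(stable_pair, cycle, t_clamp=500.0, t_end=400.0)


class TestMotherDaughterMemory:
    def test_stable_regime_inherits_level(self, stable_pair, cycle):
        df = mother_daughter_levels(stable_pair, cycle, n_pairs=60, seed=16)
        r = np.corrcoef(df.mother_pre, df.daughter_post)[0, 1]
        assert r > 0.9

    def test_unstable_regime_forgets_in_one_cycle(self, unstable_pair, cycle):
        df = mother_daughter_levels(unstable_pair, cycle, n_pairs=100, seed=17)
        r = np.corrcoef(df.mother_pre, df.daughter_pre)[0, 1]
        assert abs(r) < 3.0 / math.sqrt(len(df))


class TestTauHalfCohort:
    def test_non_expressing_cells_flagged(self, cycle):
        g = make_gene(k_open=0.0, k_close=1.0, name="yfp")
        df = tau_half_cohort((g,), cycle, n_cells=5, movie_min=1440.0,
                             dt=20.0, max_lag=720.0, level_min=3.6, seed=18)
        assert (~df.expressing_yfp).all()
        assert df.tau_half_yfp.isna().all()

    def test_shared_degradation_couples_reporters(self, unstable_pair, cycle):
        # long movies keep the per-cell tau estimate tight; a wide shared
        # factor makes the coupling unmistakable against that noise floor
        common = dict(cycle=cycle, n_cells=60, movie_min=17280.0, dt=20.0,
                      max_lag=8640.0, level_min=2.0, clamp_open=True)
        off = tau_half_cohort(unstable_pair, seed=19,
                              shared_degradation_cv=0.0, **common)
        on = tau_half_cohort(unstable_pair, seed=19,
                             shared_degradation_cv=1.2, **common)

        def corr(df):
            ok = df.expressing_yfp & df.expressing_cfp
            return reporter_correlation(df.tau_half_yfp[ok],
                                        df.tau_half_cfp[ok])

        n = len(off)
        assert abs(corr(off)) < 3.0 / math.sqrt(n)
        assert corr(on) > 3.0 / math.sqrt(n)
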