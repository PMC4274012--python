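"""Default parameter regimes for the two-reporter cell lines.

Two half-life regimes are modelled, mirroring the engineered reporter pairs:

* **stable** — long-lived products: mRNA half-life 3.5 h (YFP-like) / 4 h
  (CFP-like); protein half-life 43 h / 29.5 h.  Products outlive the cell
  cycle, so the level in a cell is set by dilution at division and the slow
  chromatin state, not by turnover.
* **unstable** — destabilized products (ARE-tagged mRNA, PEST-tagged
  protein): mRNA half-life 1.5 h / 1.9 h; protein half-life 6 h 30 / 5 h 40.
  Turnover outpaces the cycle and the level tracks the bursty synthesis.

Promoter kinetics are shared by the two regimes (the constructs use the same
promoter).  The burst rate, burst size, translation rate and chromatin dwell
times are not directly measured; the defaults below were fixed once by
moment-matching the model's stationary noise decomposition to the normalized
variances the two regimes exhibit (see docs/methods.md for the derivation).
Chromatin dwells are of the order of a week — switching is rare on the scale
of both the cell cycle and a time-lapse movie.
"""

from __future__ import annotations

from .gene_model import CellCycleParams, GeneParams

__all__ = [
    "CYCLE",
    "CHROMATIN_K_OPEN",
    "CHROMATIN_K_CLOSE",
    "stable_pair",
    "unstable_pair",
    "gene_preset",
    "default_measurement",
]

#: Mean cell-cycle length (min): 18 h, a realistic mammalian doubling time
#: consistent with protein half-lives spanning roughly two cycles.
CYCLE = CellCycleParams(T_div=1080.0, cv_div=0.0)

#: Chromatin switch rates (1/min): mean closed dwell 27600 min (~19 d),
#: mean open dwell 20000 min (~14 d); open fraction ~0.42.  The dwell scale
#: is set by the observed week-scale relaxation of sorted subclones (still
#: recognizable after three weeks) together with the whole-model noise level.
CHROMATIN_K_OPEN = 1.0 / 27600.0
CHROMATIN_K_CLOSE = 1.0 / 20000.0

# Shared promoter/translation kinetics (see module docstring).
_K_BURST = 0.087          # bursts per min while OPEN (one per ~11.5 min)
_BURST_SIZE_MEAN = 3.0    # mRNAs per burst
_K_TL = 0.0016            # proteins per mRNA per min (effective fluorescence quanta)

# Half-lives in minutes.
_HALF_LIVES = {
    # regime: (mrna_yfp, protein_yfp, mrna_cfp, protein_cfp)
    "stable": (210.0, 2580.0, 240.0, 1770.0),      # 3.5 h / 43 h ; 4 h / 29.5 h
    "unstable": (90.0, 390.0, 114.0, 340.0),       # 1.5 h / 6 h30 ; 1.9 h / 5 h40
}


def gene_preset(regime: str, channel: str = "yfp") -> GeneParams:
    """One reporter gene in the named regime (``"stable"``/``"unstable"``),
    channel ``"yfp"`` or ``"cfp"``."""
    try:
        m_y, p_y, m_c, p_c = _HALF_LIVES[regime]
    except KeyError:
        raise ValueError(f"unknown regime {regime!r}; expected 'stable' or 'unstable'")
    if channel == "yfp":
        t_m, t_p = m_y, p_y
    elif channel == "cfp":
        t_m, t_p = m_c, p_c
    else:
        raise ValueError(f"unknown channel {channel!r}; expected 'yfp' or 'cfp'")
    return GeneParams.from_half_lives(
        mrna_half_life_min=t_m,
        protein_half_life_min=t_p,
        k_open=CHROMATIN_K_OPEN,
        k_close=CHROMATIN_K_CLOSE,
        k_burst=_K_BURST,
        burst_size_mean=_BURST_SIZE_MEAN,
        k_tl=_K_TL,
        name=channel,
    )


def stable_pair() -> tuple[GeneParams, GeneParams]:
    """(YFP-like, CFP-like) with long half-lives."""
    return gene_preset("stable", "yfp"), gene_preset("stable", "cfp")


def unstable_pair() -> tuple[GeneParams, GeneParams]:
    """(YFP-like, CFP-like) with destabilized products."""
    return gene_preset("unstable", "yfp"), gene_preset("unstable", "cfp")


def default_measurement():
    """Default optical measurement model (import here to avoid a cycle)."""
    from .synthetic_data import MeasurementModel

    return MeasurementModel(noise_cv=0.05, floor_mean=2.0, floor_sd=0.7, gain=1.0)
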