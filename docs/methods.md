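# Methods

## Model

A cell carries two reporter genes that share nothing but the cell-cycle
clock (and, optionally, a degradation capacity — see *Shared degradation*).
Each gene is a random-telegraph promoter with bursty transcription and
linear turnover:

| reaction | propensity | effect |
|---|---|---|
| chromatin switch | `k_open` (CLOSED) / `k_close` (OPEN) | toggles the state |
| burst initiation | `k_burst` while OPEN | mRNA += B, B ~ 1 + Geom(1/b) |
| mRNA decay | `m·δ_m` | m -= 1 |
| translation | `m·k_tl` | p += 1 |
| protein decay | `p·δ_p` | p -= 1 |

Burst sizes are shifted-geometric on {1, 2, …} with mean `b`; with `b = 1`
the model reduces to the classic one-mRNA-per-event telegraph. Geometric is
the standard choice for burst statistics and keeps the simple model
recoverable as a special case.

Division is a **scheduled event**, not a reaction channel: the cycle length
is `T_div` (optionally jittered, normal with CV `cv_div`, truncated below at
`0.5·T_div` so a draw can never produce a non-positive cycle; the default
`cv_div = 0` gives strictly periodic divisions). At division each molecular
species is split equally between the daughters — each gets `n//2`, the odd
molecule by fair coin (`EQUAL`; a `BINOMIAL(n, 1/2)` option exists for
partition-noise sensitivity studies). Chromatin state and clamps are
inherited by both daughters. A followed line picks one daughter by fair
coin; population runs keep both.

Volume grows linearly from 1 at birth to 2 at division, and the observable
analogous to mean fluorescence is the volume-normalized protein level
`c(t) = p(t)/V(t)`. A useful property of this normalization: with constant
synthesis and negligible degradation, the periodic steady state has `c`
exactly constant through divisions (production doubles `p` over the cycle
while `V` doubles too, and halving at division cancels), so any fluctuation
of `c` is informative about kinetics rather than cycle phase.

Time is minutes everywhere internally; config files may use `_h`/`_d`
suffixed keys and half-lives (`protein_half_life_h = 43`), converted at
parse time via `δ = ln2/t½`.

## Default parameters and their calibration

Measured quantities are taken at face value: protein half-lives 43 h
(YFP-like) and 29.5 h (CFP-like) in the stable regime, 6 h 30 and 5 h 40 in
the destabilized regime; mRNA half-lives 1.5 h / 1.9 h destabilized and
3.5 h / 4 h stable. The cell-cycle length is not directly printed; we use
`T_div = 18 h`, a realistic doubling time consistent with the stable protein
half-lives spanning roughly two cycles.

The promoter parameters (`k_burst`, `b`, `k_tl`, chromatin dwell times) are
not individually measured. They were fixed **once, analytically**, by
moment-matching the model's stationary noise decomposition to the normalized
variances the two regimes exhibit, with dilution by growth and division
folded in as an extra first-order decay `ln2/T_div` on both species
(`δ_eff = δ + ln2/T_div`):

* Active period (chromatin OPEN): the two-stage bursty cascade gives
  `NV ≈ 1/⟨p⟩ + (b_F/⟨m⟩)·δ_p,eff/(δ_m,eff + δ_p,eff)` with mRNA Fano factor
  `b_F = b` for the shifted-geometric burst law. Matching a low stable-regime
  NV (~0.017) and a several-fold larger unstable-regime NV under a *shared*
  promoter fixes `k_burst = 0.087 /min` and the protein scale
  (`k_tl = 1.6e-3 /min`, i.e. mean protein signals of order 10²
  effective fluorescence quanta in the stable regime and of order 10¹ in the
  destabilized one — consistent with the destabilized clones sitting ~100×
  lower and near the detection floor). Because both regimes share the
  promoter, the unstable/stable NV ratio is bounded near ~6 in this model;
  the simulated unstable NV (~0.06–0.07) therefore sits below the measured
  0.11 while preserving the qualitative, several-fold contrast.
* Whole model (chromatin switching): for switching much slower than the
  protein response, `NV ≈ (1−f)/f · φ` with open fraction
  `f = k_open/(k_open+k_close)` and a low-pass attenuation
  `φ = δ_p,eff/(δ_p,eff+λ)·δ_m,eff/(δ_m,eff+λ)`, `λ = k_open+k_close`.
  Matching whole-model NVs of ~1.3 in both regimes gives dwell times of the
  order of a week: mean closed 13 800 min (~9.6 d), mean open 10 000 min
  (~6.9 d), `f ≈ 0.42`. These also make roughly half of the cells in a FRAP
  cohort transcriptionally active at any moment.

`b = 3` mRNAs per burst is a typical burst size; the active-period NV is
insensitive to `b` at fixed `k_burst` (the burst term depends on
`δ_m,eff/k_burst` only), so it mainly sets the mRNA copy scale (~60 stable,
~30 destabilized while open).

## Simulation engine

Exact Gillespie (direct method) between scheduled breakpoints; divisions,
interventions and the horizon interrupt the event loop exactly at their
times. No tau-leaping. SSA trajectories are piecewise constant, so traces
are sampled last-value-carried-forward onto a regular grid (default 10-min
frames, the time-lapse interval); a grid point coinciding with a scheduled
event records the pre-event state, so a division at time `t` appears as the
mother at `t` and the daughter at the next frame.

Randomness: one root seed; population code derives per-cell streams with
`SeedSequence.spawn` in cell-creation order, making runs reproducible and
independent of scheduling details. Within one cell the two genes share a
stream, so an intervention on one gene can shift the other gene's sample
path for a fixed seed — distributional, not pathwise, invariance is the
contract there (and is what the tests check).

Population growth is breadth-first over a birth-time queue; when the pending
population exceeds `max_cells`, a uniform random subsample of `max_cells`
cells is retained, emulating unbiased passaging. Lineage tables record one
row per live cell per snapshot; parent links and generation increments are
checkable whenever the snapshot schedule is denser than the cycle (as in
time-lapse frames).

Snapshot/initial states use a **warm start**: chromatin ~ Bernoulli(f),
molecule counts Poisson at the conditional quasi-stationary mean (with
closed cells carrying residual product decayed over an exponential
elapsed-closed time), cycle age uniform over the cycle, followed by a
relaxation burn-in of full simulation (default 3 days ≈ several protein
effective lifetimes). This approximates the exact stationary law well at a
small fraction of the cost of cold-start burn-in over many chromatin dwells;
the across-cell chromatin mixture, which dominates the population variance,
is exact by construction.

## Statistics

* `NV = σ²/µ²` uses the **population** variance: it is a distribution
  functional compared across large populations, not an inferential estimate.
  Zero mean yields NaN (undefined), not an exception.
* The ACF is the biased single-global-mean estimator
  `r(k) = Σ(x_t−x̄)(x_{t+k}−x̄)/Σ(x_t−x̄)²` (via statsmodels), which keeps
  `|r| ≤ 1` and the sequence positive semidefinite — the standard choice in
  fluctuation analysis. It is computed on the volume-normalized level;
  computing on raw counts is available for sensitivity checks.
* `τ½` is the first downward 0.5-crossing, linearly interpolated between
  bracketing lags; if the ACF never reaches 0.5 within `max_lag` the value
  is right-censored at `max_lag` and flagged. Cohort medians are over
  expressing, uncensored cells, with censored counts reported alongside.
* Half-life fits are least squares on `log(values)` vs time;
  `t½ = −ln2/slope`; a non-negative slope signals "no decay".
* Positivity: a cell is expressing when its measured level exceeds the 99th
  percentile of the zero-expression noise-floor distribution (the
  autofluorescence band of the measurement model).

## Reported protocols and problem sizes

* **Active-period NV**: one line with chromatin clamped OPEN, 130 divisions
  (260 in the acceptance script), 10-min frames, first 5 cycles discarded;
  NV of `p/V` over the rest.
* **Whole-model NV**: chromatin free; 20 independent lineages × 90 days in
  the tests (48 × 120 days in the acceptance script), 30-min frames, first
  10 days discarded, pooled before taking NV — the slow chromatin dwells are
  the dominant Monte-Carlo error, so pooling across lineages matters more
  than trace length.
* **Memory cohorts** mirror each clone's imaging design: stable-product
  cells are identifiable across divisions, so their movies run 120 h at
  10-min frames (ACF window 60 h); destabilized-product cells change too
  fast to stitch across divisions, so a per-cell record spans one cell cycle
  at 20-min frames (window 9 h). The short unstable window is not a
  nuisance: the finite-window, per-cell-mean ACF decays faster than the
  underlying process, which is exactly the situation of the corresponding
  measurements, and is what pushes the unstable median τ½ (~1.5 h) below the
  protein half-life.
* **Subclone relaxation**: a 300-cell parental pool; HIGH founders from the
  top decile and LOW from the bottom quartile of positive cells (the sorter
  gates are not numerically specified; these bands are a stand-in); 20
  single-reporter subclones per class grown 55 days with passaging at 96
  cells; the reported gap is the difference of the class-average median
  levels at day 14 and day 55. Population size matters here: a passaged
  subclone's cells share recent ancestry, so its median is driven by a
  handful of effectively independent chromatin histories, and too small a
  cap buries the relaxation signal in median noise.
* **FRAP**: cells drawn from the long-run state, target protein reduced to
  20 %, observed 5 h at 10-min frames. A cell is RECOVERING when its
  terminal/initial normalized level exceeds `1 + 3·s`, with `s` half the
  spread of the same ratio in a transcription-inhibited envelope cohort.

## Synthetic data

The generator emulates the study's two modalities from the simulator plus a
measurement model — gain (fluorescence units per molecule), multiplicative
lognormal noise (CV 0.05), additive Gaussian autofluorescence floor (mean 2,
SD 0.7 in signal units): tracking tables (one row per cell per 10-min frame
with total fluorescence per channel and an area proxy) and cytometry-like
snapshots (one row per cell, two channels, asynchronous ages). It does not
emulate: segmentation/tracking errors, spectral spillover or compensation,
photobleaching during imaging, fluorophore maturation, or cell death.
Passing tests therefore demonstrate correctness of the pipeline under this
idealized measurement process, not robustness to those artefacts.

## Known limitations

* **No fluorophore maturation delay.** Newly translated protein is
  immediately fluorescent. Consequence: with the stable regime's long mRNA
  half-life, transcription-inhibited FRAP cells keep synthesizing visible
  protein from residual transcripts over the 5 h window, so the inhibitor
  band is not flat and the (envelope-calibrated) classifier is conservative
  in that regime. With fast mRNA turnover the contrast is sharp and the
  classifier behaves as intended.
* **Uniform cycle ages.** Asynchronous snapshots draw the age uniform over
  the cycle; the true age distribution in an exponentially growing culture
  is size-biased (∝ 2^(1−a/T)). The bias on NV is small next to the
  chromatin mixture but would matter for cycle-phase-resolved statistics.
* **Warm-start stationarity** is approximate (see above); statistics that
  depend on fine conditional structure of `(m, p)` given a long chromatin
  history converge only after the relaxation burn-in.
* The unstable-regime active-period NV is structurally below the measured
  value when the promoter is shared between regimes (see *Calibration*);
  treat its absolute value as order-of-magnitude, its contrast with the
  stable regime as the robust prediction.
* Chromatin is a pure two-state switch with no mechanism (no methylation,
  remodeling, or position effects); integration-site differences would map
  onto per-clone rate differences, not onto anything inside this model.

## Shared degradation

Optionally, one mean-1 lognormal factor per cell multiplies both genes'
`δ_p` (`apply_shared_degradation`, or `shared_degradation_cv` in the cohort
API; default off). It models a degradation capacity common to both
reporters and is the mechanism by which the two channels' per-cell memory
times become correlated while the genes stay transcriptionally independent.
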