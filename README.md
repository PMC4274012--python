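# memsim

Stochastic simulation and fluctuation analysis of **gene-expression memory
across cell divisions**.

Clonal mammalian cells can keep a characteristic expression level of a
reporter gene over many generations, even though every step of expression is
noisy. `memsim` implements the modelling side of that question: a
random-telegraph (two-state promoter) model of two independent fluorescent
reporters inside a growing, dividing cell, plus the fluctuation statistics
used to quantify "cellular memory" — the normalized variance of expression
and the autocorrelation time of single-cell traces. It is aimed at people
studying expression noise, epigenetic-looking inheritance, and the role of
mRNA/protein turnover in both.

## Model

Each reporter gene is a telegraph promoter embedded in a cell-cycle clock:

* chromatin switches `CLOSED ⇄ OPEN` at first-order rates `k_open`, `k_close`
  (slow: dwell times of the order of a week);
* while OPEN, transcriptional bursts fire at rate `k_burst`, each producing a
  shifted-geometric number of mRNAs with mean `b`;
* each mRNA is translated at rate `k_tl`; mRNA and protein decay at
  `δ_m = ln2/t½,m` and `δ_p = ln2/t½,p`;
* the cell divides every `T_div` (default 18 h); molecules are split equally
  between the daughters (odd molecule by fair coin) and a followed line picks
  one daughter at random;
* cell volume grows linearly from 1 to 2 over the cycle, and the observable
  is the volume-normalized protein level `p(t)/V(t)` — the analogue of mean
  fluorescence.

Everything between scheduled events (divisions, chromatin clamps,
photobleaching) is simulated with the exact Gillespie algorithm. Two
half-life regimes ship as presets: **stable** products (mRNA t½ 3.5–4 h,
protein t½ 43 h / 29.5 h) and **unstable**, destabilized products (mRNA t½
1.5–1.9 h, protein t½ 6 h 30 / 5 h 40).

The analysis layer computes the noise measure `NV = σ²/µ²`, the biased
single-mean autocorrelation function of a trace, and `τ½` — the lag at which
the ACF first drops to 0.5, the operational memory timescale — plus
half-life fits, positivity thresholds, quadrant fractions for two-channel
snapshots, and Pearson correlations of per-cell statistics.

Population modules reproduce the study designs end to end: lineage-tree
growth with passaging, sorting of HIGH / LOW / NEGATIVE founder cells and
subclone relaxation time courses, whole-cell FRAP cohorts with transcription
or translation inhibitor controls, silencing (chromatin clamp) scenarios,
and a synthetic-data generator that emulates time-lapse tracking tables
(10-min frames) and cytometry snapshots through a gain + lognormal-noise +
autofluorescence-floor measurement model.

## Worked example

```python
from memsim.experiments import clamped_open_nv, whole_model_nv, memory_cohorts

nv_s = clamped_open_nv("stable", seed=1)
nv_u = clamped_open_nv("unstable", seed=1)
print(f"active-period NV   stable {nv_s['nv']:.3f}   unstable {nv_u['nv']:.3f}")

full_s = whole_model_nv("stable", seed=1)
full_u = whole_model_nv("unstable", seed=1)
print(f"whole-model NV     stable {full_s['nv']:.2f}    unstable {full_u['nv']:.2f}")

coh = memory_cohorts(seed=1)
print(f"median ACF tau1/2  stable {coh['stable']['median_tau_half_min']/60:.1f} h   "
      f"unstable {coh['unstable']['median_tau_half_min']/60:.1f} h")
print(f"unstable cells with tau1/2 < 2 h: {coh['unstable']['fraction_below_2h']:.0%}")
```

prints

```
active-period NV   stable 0.011   unstable 0.057
whole-model NV     stable 1.45    unstable 1.63
median ACF tau1/2  stable 12.1 h   unstable 1.5 h
unstable cells with tau1/2 < 2 h: 68%
```

Reading: while chromatin is pinned OPEN, stable products filter burst noise
almost completely (NV ≈ 0.01) whereas destabilized products expose it
(NV ≈ 0.06, a several-fold amplification). Letting chromatin switch on its
week-long timescale raises the noise by roughly two orders of magnitude in
both regimes — the population variance is driven by the promoter state, not
by turnover. The same contrast appears in time: traces of stable products
decorrelate over half a day and more, while unstable-product cells forget
their level within about 1.5 h, i.e. well inside one cell cycle.

There is also a CLI for scripted runs, one scenario per subcommand:

```
memsim simulate|subclone|frap|silencing|synth|analyze --config conf.toml --seed 1 --out outdir
```

with TOML/YAML/JSON configs (half-lives may be given as
`protein_half_life_h = 43` instead of rates); every run writes its tables as
TSV plus a `manifest.json` echoing the fully resolved parameters and seed.

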