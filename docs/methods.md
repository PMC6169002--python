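# Methods

This note documents the models, estimators and numerical choices behind
`cmcoupling`, in the spirit of the methods documentation of estimator-heavy
scientific packages: what is computed, under which assumptions, and what the
synthetic benchmarks do and do not demonstrate.

## Problem setting

The package analyzes cortico-muscular coupling (CMC): the statistical
dependence between a cortical local field potential (LFP) and the
electromyogram (EMG) of a muscle it innervates, recorded simultaneously
(2 kHz by default) around trains of pulsed transcranial ultrasound
stimulation (pTUS). Two complementary measures are estimated per trial:

* **Mutual information (MI)** between paired LFP/EMG samples,
  `MI(X;Y) = H(X) + H(Y) − H(X,Y)` — the symmetric, model-free measure of
  total coupling strength.
* **Transfer entropy (TE)** in both directions,
  `TE(X→Y) = I(y_{t+u} ; X_t | Y_t)` — the directed, model-free measure of
  predictive information transfer, with `X_t`, `Y_t` delay-embedded states
  and `u` a prediction time absorbing the corticomuscular conduction delay.
  "Descending" is LFP→EMG (motor command), "ascending" EMG→LFP
  (proprioceptive feedback).

All information quantities are computed and stored in nats;
`CouplingEstimate.value_bits` converts on demand.

## Estimators

### KSG mutual information (`mi_ksg`)

Kraskov–Stögbauer–Grassberger algorithm 1: for each point the Chebyshev
distance `eps_i` to its k-th nearest neighbor in the joint space is found
(k = 4 by default, the conventional bias/variance compromise), the points
strictly within `eps_i` in each marginal are counted, and

    MI = psi(k) + psi(n) − ⟨ psi(n_x + 1) + psi(n_y + 1) ⟩.

Estimates near independence may be slightly negative; values are reported
unclipped so that trial averages remain unbiased.

### Nearest-neighbor conditional MI and TE (`te_ksg`)

TE is estimated as the conditional MI `I(y_{t+u}; X_t | Y_t)` in the
Frenzel–Pompe digamma form: neighbor counts are taken in the (future,
target-state), (source-state, target-state) and (target-state) projections
of the joint space at the per-point joint-space radius,

    TE = psi(k) − ⟨ psi(n_{yY}+1) + psi(n_{XY}+1) − psi(n_Y+1) ⟩.

A Theiler window `W` excludes temporal neighbors (|t−t'| ≤ W) from both the
k-th-neighbor search and all counts, preventing serial correlation from
masquerading as dependence. The default when not set explicitly is the lag
of the first zero crossing of the target's autocorrelation, capped at 100
samples.

### Determinism and ties

kNN counts are undefined under exact value ties. Every marginal is therefore
jittered with uniform noise of amplitude 1e−10 of its standard deviation
before estimation. The jitter stream is seeded from a fixed sub-seed and a
CRC of the column's bytes, making it a pure function of the data: estimates
are bit-reproducible, and `mi_ksg(x, y) == mi_ksg(y, x)` holds exactly.

### Embedding selection (`ragwitz_optimize`)

The embedding dimension d and delay tau are chosen by the Ragwitz
criterion: minimize the cross-validated MSE of a local-constant kNN
one-step predictor on the reconstructed states. Two numerical choices
matter:

* All candidates are scored on the same anchor time points (up to 4000,
  evenly spaced), so their CV errors are directly comparable.
* A **parsimony margin**: a more complex candidate displaces the incumbent
  only if it lowers the MSE by more than 5% of the series variance. Raw
  CV-MSE comparison over-selects large d on stochastic series, where
  between-candidate MSE fluctuations of 2–3% of variance are pure noise;
  genuinely informative coordinates (deterministic structure) improve the
  MSE on the variance scale and always win. Searched ranges default to
  d ∈ {1..6}, tau ∈ {1..10} samples.

### Prediction-time scan (`scan_prediction_time`)

TE is evaluated on a 1 ms grid over 10–49 ms (the physiological range of
ultrasound-evoked EMG latencies) and the maximizing u is returned, ties to
the smallest u. On the synthetic recordings this recovers the programmed
conduction delay to ±1 ms.

## Preprocessing chain (`preprocess_recording`)

Order: 50 Hz notch → moving-average baseline subtraction → band-pass
(LFP 0.5–200 Hz, EMG 10–200 Hz) → full-wave rectification of the EMG →
trial segmentation. Choices:

* Notch: second-order IIR, Q ≈ 35 (1.4 Hz bandwidth), forward–backward.
* Baseline: centered moving average (0.5 s window, reflected edges)
  subtracted — an adaptive zero-phase high-pass near 2 Hz without ringing.
* Band-pass: 4th-order Butterworth, forward–backward (8th-order magnitude).
* All stages are zero-phase; a delay-sensitive estimator downstream sees no
  filter-induced lag (verified by zero-lag cross-correlation peaks).
* Rectification is |·| applied before segmentation; a flag allows
  rectifying after cutting instead, since the original order is ambiguous
  in common descriptions of the workflow.
* Trials: 1.0 s pre-stimulation (ending at the trigger) and 1.0 s
  post-stimulation (starting at trigger + sonication duration), fitting
  comfortably within the 3.6 s inter-train interval; triggers whose windows
  would cross the record edge are dropped and counted in the log.

## Synthetic recording generator (`gen_cmc_recording`)

No public dataset of paired LFP/EMG under pTUS exists, so the generator
emulates one, and its defaults define the conditions under which every
end-to-end benchmark in this package runs.

* **Cortical drive** `s`: 0.85·(18–22 Hz band-limited noise) +
  0.53·(10–160 Hz broadband), unit variance. The ~20 Hz beta component is
  the band in which cortico-muscular coherence is physiologically
  strongest; at the default 25 ms conduction delay (half a 20 Hz period) it
  carries zero-lag LFP/EMG dependence, while the broadband component makes
  the conduction delay sharply identifiable by the u-scan.
* **LFP** = s + (ascending feedback) + 0.4·(1/f background) + 50 Hz line
  (10% RMS) + 0.2 Hz drift (10% RMS) + white noise (SD 0.5).
* **EMG**: an amplitude-modulated interference pattern — a 20–160 Hz
  broadband carrier multiplied by the nonnegative envelope
  `0.5 + gain·0.8·relu(s(t−Δ)) + 0.3·relu(m)`, plus white noise, where `m`
  is an independent 5–60 Hz muscle-intrinsic process and Δ the conduction
  delay. The half-wave (`relu`) recruitment nonlinearity and multiplicative
  carrier reproduce the key property of real EMG that full-wave
  rectification *demodulates* the envelope: an additive signed coupling
  would be destroyed by the band-pass → rectify chain, an envelope coupling
  survives it.
* **Ascending pathway**: `0.25·gain·relu(m(t−Δ))` added to the LFP — the
  weaker feedback direction.
* **Stimulation effect**: in the post-stimulation phase both coupling gains
  are multiplied by `1 + 0.002·NTB` (1.2× at NTB = 100 up to 1.6× at
  NTB = 300). The slope places the five dose levels on the responsive part
  of the measure's dose curve: above roughly 1.8× effective drive gain the
  envelope becomes drive-dominated and rectified-EMG demodulation is
  limited by the carrier's own variability, so further gain adds little
  measurable dependence. A 1.2–1.6× modulation is also the physiologically
  plausible scale for a neuromodulatory effect.
* All stochastic draws come from one seeded stream in fixed order, and none
  depends on the phase label — with a zero NTB slope the pre and post
  recordings are bit-identical, so any pre/post difference is attributable
  to the modeled gain.

What the generator does **not** model: acoustic/thermal ultrasound physics,
stimulus-evoked transients (the gain change is stationary within a phase),
nonstationary muscle fatigue, motor-unit discreteness, and
subject-level anatomical variability beyond a lognormal (SD 0.15) scaling
of the coupling gains. Benchmarks passing on these recordings demonstrate
estimator correctness and pipeline sensitivity under realistic spectra,
noise, line contamination and drift — not performance on any specific
in-vivo dataset.

## Statistics

* **Surrogate test**: the observed TE is ranked against TE values from
  circularly time-shifted copies of the source (shift ≥ Theiler window +
  prediction time, uniform), which preserve both marginals' dynamics while
  destroying their alignment; `p = (1 + #{TE_surr ≥ TE_obs}) / (1 + N)`.
  With 19 surrogates the null rejection rate at α = 0.05 is 5% by
  exchangeability, which the calibration benchmark confirms empirically.
* **Repeated-measures ANOVA**: classical one-way within-subjects
  decomposition, F = MS_condition/MS_error with df (c−1, (c−1)(s−1));
  multiple trial values per cell are averaged first; unbalanced designs are
  rejected with the missing cells named. No sphericity correction is
  applied by default (two within-level conditions, the main use here, have
  none to correct); no multiple-testing correction is applied by default,
  with Holm available as an option. α is fixed at 0.05.
* **Pearson correlation**: r, r² and the two-sided t-test p-value, used for
  per-trial amplitude-vs-coupling relations pooled across subjects within a
  condition.

## Problem sizes used by the benchmarks

The test suite and the acceptance script size their simulations to be
decisive yet desk-scale: MI oracle checks at n = 10 000 samples; TE–Granger
comparisons over 10–20 seeds at n = 10 000 against a regression oracle fit
on 200 000–400 000 simulated points; direction recovery over 50 runs at
n = 2500; delay recovery over 10–20 recordings of 8 trials; null
calibration over 200 surrogate tests at n = 800; and the dose-response over
5 NTB levels × 12–24 recordings of 12–24 trials. The full simulated study
(`cmc run`, 9 subjects × 5 levels × 30 trials, optional u-scans and
surrogates) is correspondingly heavier and is the deliverable analysis, not
part of the routine test run.

## Known limitations

* The KSG estimator's small negative bias near independence is reported,
  not clipped; aggregate statistics on null data straddle zero.
* Zero-lag per-trial MI depends on the drive's autocorrelation bridging
  the conduction delay; for delays far from a half/full period of the
  dominant rhythm the MI dose response weakens even though TE (which scans
  u) is unaffected.
* `ragwitz_optimize`'s parsimony margin (5% of variance) deliberately
  under-fits weakly informative extra coordinates; for processes whose
  higher-order structure is subtle, fix (d, tau) explicitly.
* The EDF variant of the recording format is not implemented; recordings
  are read and written as the documented delimited-text CSV.
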