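# cmcoupling

Analysis of **cortico-muscular coupling** (CMC) between local field
potentials (LFP) recorded in motor cortex and electromyograms (EMG) of the
innervated muscle, for stimulation experiments with pulsed transcranial
ultrasound (pTUS). The package provides the full chain a coupling study
needs — and, because no such dataset is publicly deposited, a synthetic
recording generator that emulates one, so every stage is exercisable and
testable end to end.

## What it computes

For paired LFP/EMG trials cut around stimulation triggers:

* **Mutual information** — the symmetric coupling strength
  `MI(X;Y) = H(X) + H(Y) − H(X,Y)`, estimated nonparametrically with the
  Kraskov–Stögbauer–Grassberger (KSG) k-nearest-neighbor estimator (k = 4,
  Chebyshev norm, digamma form), in nats.
* **Transfer entropy** in both directions — the directed information flow
  `TE(X→Y) = I(y_{t+u}; X_t | Y_t)`, with states `X_t`, `Y_t` delay-embedded
  (dimension d and delay τ selected by the Ragwitz criterion), a Theiler
  window excluding serially correlated neighbors, and the prediction time u
  optimized over 10–49 ms to absorb the corticomuscular conduction delay.
  Descending = LFP→EMG, ascending = EMG→LFP.
* **Significance and design statistics** — circular time-shift surrogate
  tests per estimate, one-way repeated-measures ANOVA across conditions
  (pre vs post stimulation, descending vs ascending, tone-burst-count
  levels), and Pearson correlations between signal amplitudes and coupling.

Preprocessing follows the standard electrophysiology chain, all zero-phase:
50 Hz notch, moving-average baseline removal, band-pass (LFP 0.5–200 Hz,
EMG 10–200 Hz), full-wave EMG rectification, trial segmentation.

The stimulation protocol is parameterized by acoustic intensity, cycles per
pulse, pulse repetition frequency (1 kHz), number of tone bursts
(NTB ∈ {100, …, 300}, so sonication lasts 0.1–0.3 s) and a 3.6 s
inter-train interval; the synthetic generator scales the post-stimulation
coupling gain with NTB, reproducing a dose-dependent enhancement of CMC.

## Worked example

Simulate a recording, then estimate coupling on its trials:

```bash
cmc simulate --ntb 250 --trials 8 --seed 42 --phase post --out rec.csv
cmc mi --in rec.csv --ntb 250
cmc te --in rec.csv --ntb 250
```

which prints (trial windows before each trigger and after each sonication,
8 trials of 1 s at 2 kHz; the whole recording is simulated in the
post-stimulation state):

```
pre: MI = 0.0917 ± 0.0341 nats (n=8 trials)
post: MI = 0.0682 ± 0.0337 nats (n=8 trials)
pre desc: TE = 0.0823 nats (u* = 24 ms)
pre asc: TE = 0.0108 nats (u* = 24 ms)
post desc: TE = 0.0790 nats (u* = 25 ms)
post asc: TE = 0.0181 nats (u* = 23 ms)
```

Reading these numbers: MI of ~0.07–0.09 nats is a weak-but-real dependence
(roughly |ρ| ≈ 0.35–0.4 if the data were Gaussian), and the two window
positions differ only by trial noise here since this single recording is
uniformly in the post-stimulation state. Descending TE is 4–7× the
ascending TE — the expected asymmetry of a motor pathway with a weak
feedback loop — and the u-scan puts its maximum at 24–25 ms in the
descending direction, matching the 25 ms conduction delay programmed into
the generator.

The full simulated study (several subjects, all five NTB levels, pre/post,
ANOVAs and correlation tables) runs with

```bash
cmc run --subjects 4 --trials 6 --ntb 100 --ntb 300 --seed 7 --out study/
```

and writes `estimates.csv` (per-trial values), `summary.csv`,
`correlations.csv` and a human-readable `report.txt`.

The same functionality is available as a library:

```python
from cmcoupling import (StimProtocol, SynthConfig, gen_cmc_recording,
                        preprocess_recording, segment_trials, mi_ksg,
                        te_bidirectional)

protocol = StimProtocol(ntb=250)
rec = gen_cmc_recording(protocol, SynthConfig(n_trials=8, seed=42), "post")
pre, post = segment_trials(preprocess_recording(rec), 1.0, 1.0, protocol)
mi = [mi_ksg(lfp, emg, k=4).value for lfp, emg in post]
```

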