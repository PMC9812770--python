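# consolipy

Analysis pipeline for the NREM-sleep electrophysiology of long-term motor
learning: oscillation detection, cross-area coupling statistics, across-day
transition dynamics, neural-manifold (GPFA) analysis, sharp-wave-ripple
reactivation, and the PFC–M1 communication subspace — together with a
synthetic-data generator that reproduces the study design with fully known
ground truth.

It is written for systems neuroscientists working with chronic multi-area
recordings (prefrontal cortex, motor cortex, hippocampal CA1: LFP plus
sorted units) across many days of skill training, where each day consists
of pre-training sleep, reach training, and post-training sleep.

## What it computes

**Sleep staging.** The channel-averaged LFP is cut into non-overlapping 6 s
epochs; per-epoch power spectral density is averaged over the slow-wave
(0.1–4 Hz) and gamma (30–60 Hz) bands, and a 2-means clustering of the
standardized features labels the high-delta cluster NREMS. Runs shorter
than 30 s are excluded.

**Oscillation detection.** On NREMS data:

* *Slow oscillations (SO)* — delta-filtered (Butterworth HP order 2 at
  0.1 Hz, then LP order 5 at 4 Hz, both zero-phase) channel average;
  candidate waves delimited by positive-to-negative zero crossings; an SO
  requires its peak above the 85th percentile of candidate peaks
  (down-state), its trough below the 40th percentile of candidate troughs
  (up-state), and a peak-to-trough time of 150–500 ms.
* *Spindles* — z-scored average, 10–15 Hz (orders 6/8), Hilbert envelope
  smoothed with a 200 ms Gaussian; events exceed μ+1.5σ for ≥ 500 ms with
  at least one sample above μ+2.5σ.
* *Sharp-wave ripples (SWR)* — z-scored average of three CA1 channels,
  150–250 Hz (orders 8/10), 20 ms envelope smoothing, μ+1σ / μ+4σ
  thresholds, ≥ 50 ms.

**Event coupling.** Each target event is linked to its nearest reference
(lag = target − reference); a coupling value is the percentage of lags in a
window: SO–SWR ±0.75 s, PFC–M1 SO ±0.2 s, SO–spindle nesting [−0.5, 1.0] s,
plus triple/quadruple coupling within ±1 s of an SWR peak. ΔSO–SWR coupling
is post-training minus pre-training sleep. Null distributions come from
circular permutation of one train on gap-excised NREMS time (1,000 reps);
a fixed-size (100-event) subsampling control removes rate effects.

**Transition dynamics.** Per-session values are split into tertiles
(39 samples over 13 days), padded with 2-day edge means, convolved with a
9-tertile Gaussian, min-max normalized per animal, and fitted with the
four-parameter sigmoid `L + (U−L)/(1+exp(−k(x−x_mid)))`. A mean-shift
change point is found by exhaustive SSE minimization, a moving-window slope
scan (3–7 day windows) locates the first abrupt rise, and the per-animal
grand-midpoint — the median of the coupling-rise and ΔSO–SWR-drop
midpoints — tags stage I/II sessions for a logistic staging model.

**Manifold (GPFA).** Trial-locked spiking is binned at 15 ms and z-scored;
Gaussian-process factor analysis (`y = Cx + d + ε`, squared-exponential
latent priors) is fitted by EM with leave-neuron-out dimensionality
selection. The top three orthonormalized factors define single-trial
trajectories; the GPFA correlation of a trial with the best-days template
(resampled to 100 points per factor) yields trajectory fidelity
(mean/sd over trials).

**Reactivation and communication subspace.** Sleep spiking around SWR
onsets is projected onto the awake template space; reactivation R is the
template correlation over a window-size (75–405 ms ≈ 0.2–2× compression)
and lag search, or the fixed 195 ms / zero-lag window, with per-unit
circular-shuffle nulls. CCA on 1 s post-SWR windows identifies the top
canonical pair; the cross-area R contrast between SWR⁺SO⁺ and SWR⁺SO⁻
conditions measures SO-gated PFC–M1 communication.

## Worked example

Recover the two-stage consolidation timing from a simulated 13-day study
(coupling probabilities follow the generator's day schedules: the PFC–M1
SO coupling rises with midpoint day 6, the ΔSO–SWR coupling drops with
midpoint day 8):

```python
import numpy as np
from consolipy import synth, study, dynamics as dyn

cfg = synth.SimConfig(sleep_block_s=900.0)
days = synth.simulate_study(cfg, seed=11, n_days=13, lfp=False, spiking=False)
rec = study.recover_transitions(study.events_from_ground_truth(days))
rise, drop = rec["rise_fit"], rec["drop_fit"]
print(f"PFC-M1 SO coupling rise:   x_mid = {rise.x_mid:.2f} d  (R^2 = {rise.r2:.3f})")
print(f"delta SO-SWR coupling drop: x_mid = {drop.x_mid:.2f} d  (R^2 = {drop.r2:.3f})")
print(f"grand-midpoint:            {rec['grand_midpoint']:.2f} d")
cp = dyn.change_point(rec["rise_series"].normalized)
print(f"change point (coupling):   tertile {cp.index} ~= day {rec['rise_series'].days[cp.index-1]}")
```

prints

```
PFC-M1 SO coupling rise:   x_mid = 5.90 d  (R^2 = 0.996)
delta SO-SWR coupling drop: x_mid = 8.36 d  (R^2 = 0.987)
grand-midpoint:            7.13 d
change point (coupling):   tertile 17 ~= day 6
```

The fitted midpoints recover the scheduled rise (day 6) before the
scheduled drop (day 8); their median — the grand-midpoint — separates the
two consolidation stages, and the change point of the smoothed coupling
series falls at the onset of the rise.

The full raw-signal path runs through the CLI: `consolipy simulate` writes
HDF5 session containers (LFP, spikes, trials, manifest), `consolipy
pipeline` stages, detects, couples, fits the manifold and computes
reactivation/CCA for one session, and `consolipy stage`/`detect` expose the
intermediate steps. All randomized procedures take an explicit `--seed` and
results carry a config-hash provenance record.

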