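# Methods

This note documents the models and procedures implemented in consolipy,
the choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and the problem sizes used by the
validation studies.

## Time and data conventions

All times are seconds on a per-session clock starting at 0; intervals are
half-open `[start, end)`; event timestamps are stored at 1 µs precision so
CSV round-trips are exact. Bad channels and artifact samples are masked
(artifacts by linear interpolation within a channel), never deleted, so
sample indices stay aligned to the clock. Every randomized procedure takes
an explicit seed and derives independent child streams through
`numpy.random.SeedSequence`.

## Sleep staging

Six-second epochs, per-epoch Hann-tapered periodogram (a single Welch
segment per epoch), band means over 0.1–4 Hz and 30–60 Hz. The two epoch
features are standardized before 2-means clustering (k-means++ with 10
restarts, fixed seed); the cluster with higher mean delta power is NREMS
regardless of solver label order. Merged NREMS runs shorter than 30 s are
excluded; runs of exactly 30 s are retained (only strictly shorter runs
are dropped). REM and wake are not told apart. The M1 average trace is the
default staging signal; the area is configurable.

## Oscillation detection

SO detection operates on the plain channel average, spindle and SWR
detection on per-channel z-scored averages (SWR on the three designated
CA1 channels). Filters are two independent zero-phase Butterworth stages
(high-pass then low-pass) at the stated orders; zero-phase application is
forward–backward (`sosfiltfilt`).

Open points resolved as follows, all config-exposed:

* "Top 15 percentile of the peaks" is read as the 85th percentile of the
  candidate-peak distribution, "bottom 40 percentile of the troughs" as the
  40th percentile of the candidate-trough distribution; both exceedances
  are strict.
* Percentile and envelope thresholds are computed once per sleep block
  over all NREMS samples/candidates (not per epoch or per bout), which
  stabilizes the percentiles.
* The Hilbert transform is taken per NREMS interval — never across gaps —
  and the envelope is smoothed with a Gaussian whose stated "window" is
  taken as the full width: sd = width/2, truncated at ±3 sd.
* Coupling windows are closed at both endpoints; at 1 µs timestamp
  precision the distinction from open windows is immaterial but it is
  fixed and documented.
* An SO event stores the down-state peak time in `t_onset`, the up-state
  trough in `t_peak`, and the following upward zero crossing in `t_end`.

## Event coupling and nulls

Lags are target − reference (positive = target after reference);
equidistant ties link to the earlier reference. Sessions with fewer than
10 events of a kind yield flagged/undefined metrics, never zero. Circular
permutation rotates all shuffle-target times by one uniform offset on
NREMS-concatenated time (gaps excised), so shuffled events stay in NREMS
and the inter-event-interval multiset is preserved; the analytic
expectation of the shuffled coupling is the window-coverage fraction of
the reference train, which the package computes exactly for use as an
oracle. SWR⁻ control epochs are drawn uniformly from NREMS positions where
the full 1 s epoch fits inside a single NREMS bout; they may overlap each
other.

## Transition dynamics

Tertiles split each session's time-ordered items into thirds of sizes
n//3, n//3, n − 2·(n//3). Smoothing pads each end with that end's 2-day
mean (6 tertile values) and convolves with a unit-sum Gaussian spanning 9
tertiles (±3 sd over the 9 taps); normalization is per-animal min-max.
Sigmoid fits are ordinary least squares via bounded `curve_fit`
(L, U ∈ [−0.5, 1.5], x_mid within the data range, |k| ≤ 20) with a
1-day-spaced multi-start grid on x_mid and both slope signs; fits with
negligible amplitude or R² < 0.1 are flagged "no transition". Sigmoid fits
use the smoothed, normalized series (a flag disables this).

The moving-window slope scan computes OLS slopes on per-day means — the
within-day tertile step structure otherwise biases slopes differently per
window size — in windows of 3–7 days attributed to their end day and
clipped at the series start, so a 7-day scan can still report an early
transition day. The baseline is the distribution of same-size windows
ending within days 2–4; the threshold is baseline mean + 2 sd, strict.
The change point minimizes the two-segment SSE about segment means by
exhaustive search, ties to the earliest index, reported 1-based as the
first post-change sample. Success-rate change subtracts the mean of the
two previous days (zero history before day 1). The grand-midpoint is the
median of the coupling-rise and ΔSO–SWR-drop midpoints; the logistic
staging model is fitted with statsmodels (an L2-penalized refit is used
and flagged under perfect separation).

## GPFA

Observation model `y_t = Cx_t + d + ε`, `ε ~ N(0, R)` diagonal, with each
latent an independent unit-variance GP over bins:
`K(dt) = (1−s_n)·exp(−dt²/2τ²) + s_n·δ`, innovation-noise fraction
`s_n = 1e−3` fixed. EM with factor-analysis initialization; C, d, R have
closed-form M-steps; timescales are updated by bounded 1-d minimization of
the expected latent prior term per latent, with the previous value kept if
no improvement is found (generalized EM), so the marginal log-likelihood —
computed exactly via the matrix inversion lemma in the qT-dimensional
latent space — is non-decreasing. Convergence at relative change < 1e−6 or
the iteration cap.

Latents are reported in the orthonormalized basis of C (SVD), ordered by
explained shared variance; the top three factors define trajectories.
Shared-over-total variance is tr(CCᵀ)/(tr(CCᵀ)+tr(R)). Dimensionality
selection is leave-neuron-out prediction error with trial-fold
cross-validation (contiguous folds; the model is fitted on training
trials, each unit predicted on held-out trials from the latents inferred
from the remaining units) — without held-out trials the error decreases
monotonically past the true dimensionality. Units with zero concatenated
variance or below 0.5 Hz in-window are excluded before fitting.

Day-to-day alignment uses MATLAB-convention Procrustes (rotation/
reflection, scaling and translation; scaling can be disabled) onto the
mean manifold of the final three days. The GPFA correlation resamples both
trajectory and template to 100 points per factor, centers each factor, and
correlates the concatenated factors — centering per factor makes the
measure invariant to a common rotation of trajectory and template. The
optimal template averages all trials (not only successful ones; an option
restricts it) of the three best-performance sessions. Fidelity is
mean/sd of the per-trial correlations and requires ≥ 3 trials with
non-zero dispersion.

## Reactivation and CCA

Sleep bins are z-scored with the awake per-unit statistics (template-space
consistency; sleep-local z-scoring is available) and projected on the top
three orthonormalized factors. The search grid steps window sizes by 30 ms
over 75–405 ms and lags by 15 ms with window end ≤ 405 ms from SWR onset;
the fixed comparison uses 195 ms at zero lag (13 bins). Shuffle nulls
rotate each unit's binned activity independently per event within
−200…400 ms around the onset (counts preserved exactly) and report the
session-mean R per repetition; the null computation is vectorized over
events and exact with respect to the per-event implementation.

CCA is computed in closed form: within-area covariances are Cholesky-
whitened and the cross-covariance SVD gives weights and correlations; a
ridge `1e−6·tr(S)/n` is added to a rank-deficient within-area covariance
and recorded on the model. Weights are fitted once on all SWR data and
applied per condition (per-condition refitting is an option); the sign
convention makes the first non-zero PFC weight positive. Conditions with
fewer than 5 events are rejected.

## The synthetic generator

The generator reproduces the study design — per day, pre-training sleep,
reach training, post-training sleep — with every placed event, coupling
flag, latent trajectory, replay tag and scheduled parameter recorded as
ground truth.

*Sleep LFP.* Per-channel brown (1/f²) background (sd 30 µV), a 3.5–4.8 Hz
"fast delta" component during NREMS and a 30–60 Hz gamma component during
wake (25 µV each), and a 4 µV white floor. The spectral split is
deliberate: within the SO band, the brown component produces candidate
waves longer than the 500 ms duration cap and the fast-delta component
produces candidates shorter than the 150 ms floor, so the SO duration
criterion separates background candidates from injected SOs — the same
role it plays against non-SO delta waves in cortical recordings. SOs are
one full sine cycle (peak→trough 200–400 ms, 160 µV), spindles are
Hann-enveloped 11–14 Hz bursts (0.6–1.0 s, 45 µV), SWRs are Hann-enveloped
200 Hz bursts (60–120 ms, 35 µV) on the CA1 channels. NREMS/wake alternate
in 90–240 s / 12–40 s bouts.

*Event placement.* Nominal Poisson rates 0.22 /s (SO), 0.095 /s (SWR),
0.035 /s (spindle) of NREMS; refractory spacings (1.2–1.4 s for SOs)
thin these to realized counts of roughly 300 SOs, 150 SWRs and 60 spindles
per 30 min of NREMS. Coupling is injected by moving a Binomial(p) subset
of a uniformly placed train onto free reference events (one coupled event
per reference, conflict-checked), which keeps both the event count and the
realized coupled fraction unbiased at the nominal probability — at p = 1
the reference count itself caps the realized fraction just below 1. Lags:
PFC→M1 N(0, 50 ms); SO→SWR N(0, 250 ms) truncated to ±0.7 s; spindles
uniform in [−0.4, 0.9] s around SOs.

*Spiking.* 30 units per area at 10 Hz baseline; trial spikes are Poisson
with rate `baseline·exp(U·z)` where z is a fixed smooth 3-latent template
plus AR(1) latent noise at the day-scheduled level and U has unit per-unit
loading norm (≈ e^±1 rate swing, a realistic task modulation). Replay
inserts template-driven spikes compressed by the configured factor
(default 0.5) after a configurable fraction of SWRs (default 0.3) at
1.5× gain — clean, strongly modulated reactivations, as required for
single-event window-size recovery. A separate PFC+M1 population carries a
condition-gated shared latent during the 1 s after SO-coupled SWRs (and
independent latents of the same magnitude otherwise) for the CCA
analyses.

*Day schedules.* PFC–M1 coupling rises 0.15→0.70 (midpoint day 6, k = 2);
post-sleep SO–SWR coupling drops 0.70→0.20 (midpoint day 8) against a
constant 0.20 pre-sleep, so ΔSO–SWR coupling drops at day 8; latent noise
falls 0.9→0.15 (midpoint day 6) so fidelity rises; success probability
rises 0.2→0.75.

*What it does not emulate.* No volume conduction, no state-dependent
spectra beyond the delta/gamma contrast, no REM, no electrode drift or
unit turnover within a day, no biophysical SO–spindle–SWR mechanisms —
couplings are imposed, not emergent. Passing tests therefore show that the
pipeline recovers known structure of this kind at realistic SNR, not that
it is robust to every artifact of chronic recordings.

## Validation studies and problem sizes

`consolipy.benchmarks` (driven by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs, per seed:

* Detector recovery on one sleep block sized for ~30 min of NREMS
  (staging included); F1 with 100 ms peak matching.
* Coupling calibration: 200 event-train replicates per p ∈ {0.2, 0.5, 0.8}
  at ~500 reference SOs each, against p + (1−p)·c with c the realized
  window coverage.
* Null correctness at 1,000 repetitions: the 1-SO/1-SWR/100 s analytic
  case (1.5%) and a multi-event configuration against realized coverage.
* Transition recovery: noiseless sigmoid (39 tertiles), 200 noisy
  replicates at σ = 0.1, change point vs brute force on 50 random series
  (n ≤ 50), and 50 event-level 13-day studies for rise-before-drop
  ordering. The 50-replicate study uses the generator's event-level path
  (ground-truth event trains → coupling → tertiles → fits) rather than
  raw-LFP detection per block; the full raw-signal path is exercised
  end-to-end by the detector study and the session pipeline tests.
* GPFA: subspace angle at q = 3, 30 units, 100 trials, 40 bins from the
  linear-Gaussian generative model; EM monotonicity on that run;
  dimensionality selection as the mode of 20 replicates at 25 units,
  40 trials, 30 bins, candidates 1–6, 2 trial folds.
* Fidelity ladder: five latent-noise levels, 40 trials each, shared seed.
* Reactivation: 50 replicates of 200 SWRs at 30% replay; detection =
  session-mean fixed-window R above the 97.5th percentile of a 100-rep
  shuffle null; modal best-window size pooled over the replay-tagged
  events of 3 search sessions.
* CCA: closed-form correlation against the true generative covariance
  (n = 20,000 samples), an independent-areas permutation check, and 40
  replicates of the condition-gated ΔCross-area R sign.

These sizes keep the whole validation run within a few minutes on one
core while leaving the statistical margins of each check wide.

## Known limitations

* The SO detector's percentile thresholds are rank-based: detection
  quality depends on the candidate-wave composition, and the generator's
  clean separation by duration is favorable; recordings with strong
  oscillatory delta in the 1–3 Hz range will yield more threshold-passing
  background waves.
* GPFA assumes Gaussian observations; on low-rate Poisson counts the
  recovered subspace is attenuated (the validation uses the model's own
  generative distribution for the subspace check, and the Poisson path
  for the end-to-end fidelity and reactivation checks).
* The event-level fast path places events on a single NREMS interval;
  bout structure matters only through the circular-permutation nulls,
  which always use the true interval sets.
* `run_session` fits the manifold on M1 only and the CCA on whatever PFC
  units are present; it does not currently fit a per-area GPFA for PFC.
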