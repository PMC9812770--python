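"""Synthetic multi-day sessions with fully known ground truth.

The generator emulates the study design: per day a pre-training sleep
block, a reach-training block and a post-training sleep block. Sleep LFP is
brown (1/f^2) background noise per channel with NREMS bouts carrying a fast
delta boost (3.5-4.8 Hz) and wake bouts a gamma boost (30-60 Hz); SOs are one
full sine cycle (down-state peak then up-state trough, peak-to-trough
150-500 ms), spindles are Hann-enveloped 10-15 Hz bursts and SWRs are
Hann-enveloped ~200 Hz bursts on the CA1 channels. Cross-area and
cross-kind coupling is injected with configurable probabilities and lags;
training spikes are inhomogeneous Poisson driven by a smooth 3-latent
template trajectory plus day-scheduled latent noise; a configurable
fraction of post-sleep SWRs carries a time-compressed replay of the trial
template. Every placed event, coupling flag and scheduled metric value is
recorded as ground truth.

The spectral design of the sleep background is deliberate: the slow brown
component produces candidate delta waves longer than the 500 ms SO
duration cap, and the NREMS delta boost produces candidates shorter than
the 150 ms floor, so the duration criterion separates background
candidates from injected SOs the same way it separates non-SO delta waves
from SOs in cortical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import IntervalSet, Recording, SessionManifest, SpikeTrainSet, make_trial_table


# ---------------------------------------------------------------- config

@dataclass
class SigmoidSchedule:
    """Day-indexed parameter time course L + (U-L)/(1+exp(-k(d-x_mid)))."""

    L: float
    U: float
    x_mid: float
    k: float

    def __call__(self, day):
        return self.L + (self.U - self.L) / (1.0 + np.exp(-self.k * (np.asarray(day, dtype=float) - self.x_mid)))


@dataclass
class SimConfig:
    # LFP
    rate: float = 1018.0
    n_channels: int = 4
    background_uv: float = 30.0     # brown-noise sd per channel
    delta_boost_uv: float = 25.0    # NREMS 3.5-4.8 Hz component
    gamma_boost_uv: float = 25.0    # wake 30-60 Hz component
    sensor_noise_uv: float = 4.0    # white noise floor
    # sleep structure
    sleep_block_s: float = 600.0
    nrem_bout_s: tuple = (90.0, 240.0)
    wake_bout_s: tuple = (12.0, 40.0)
    # oscillation rates (events per second of NREMS)
    so_rate: float = 0.22
    swr_rate: float = 0.095
    spindle_rate: float = 0.035
    so_amp_uv: float = 160.0
    so_dur_s: tuple = (0.20, 0.40)   # peak-to-trough
    spindle_amp_uv: float = 45.0
    spindle_dur_s: tuple = (0.6, 1.0)
    swr_amp_uv: float = 35.0
    swr_dur_s: tuple = (0.06, 0.12)
    swr_freq_hz: float = 200.0
    # coupling
    p_pfc_m1: float = 0.5
    pfc_m1_lag_sd: float = 0.05
    p_so_swr: float = 0.5
    so_swr_lag_sd: float = 0.25      # truncated to +/-0.7 s
    p_so_spindle: float = 0.5
    # spiking / trials
    n_units: int = 30
    latent_dim: int = 3
    baseline_hz: float = 10.0
    loading_scale: float = 1.0
    latent_noise_sd: float = 0.3
    n_trials: int = 45
    trial_gap_s: float = 12.0
    trial_window_s: tuple = (-0.2, 0.4)
    success_p: float = 0.5
    # replay
    replay_fraction: float = 0.3
    replay_compression: float = 0.5
    replay_gain: float = 1.5
    # day schedules
    n_days: int = 13
    pfc_m1_schedule: SigmoidSchedule = field(
        default_factory=lambda: SigmoidSchedule(0.15, 0.70, 6.0, 2.0))
    so_swr_post_schedule: SigmoidSchedule = field(
        default_factory=lambda: SigmoidSchedule(0.20, 0.70, 8.0, -2.0))
    so_swr_pre_p: float = 0.20
    latent_noise_schedule: SigmoidSchedule = field(
        default_factory=lambda: SigmoidSchedule(0.15, 0.9, 6.0, -1.5))
    success_schedule: SigmoidSchedule = field(
        default_factory=lambda: SigmoidSchedule(0.2, 0.75, 6.0, 1.5))


@dataclass
class GroundTruthEvents:
    """True event times for one sleep block (session clock)."""

    nrems: IntervalSet
    so_down: dict           # area -> down-state peak times
    so_up: dict             # area -> up-state trough times
    spindle_peak: dict
    swr_onset: np.ndarray
    swr_peak: np.ndarray
    swr_end: np.ndarray
    pfc_m1_coupled: np.ndarray = None   # bool per M1 SO
    so_swr_coupled: np.ndarray = None   # bool per SWR
    replay_tagged: np.ndarray = None    # bool per SWR


# ---------------------------------------------------------------- noise

def _brown_noise(n, rng):
    """Unit-sd 1/f^2 (integrated white) noise."""
    x = np.cumsum(rng.standard_normal(n))
    x -= np.linspace(x[0], x[-1], n)     # detrend so HP filtering is tame
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


def _band_noise(n, rate, lo, hi, rng):
    """Unit-sd Gaussian noise band-limited to [lo, hi] Hz (FFT mask)."""
    w = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    W = np.fft.rfft(w)
    W[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(W, n)
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


def _alternating_bouts(total, nrem_rng, wake_rng, rng, start_wake=True):
    """Wake/NREMS alternation covering [0, total)."""
    ivs, t, wake = [], 0.0, start_wake
    while t < total:
        lo, hi = wake_rng if wake else nrem_rng
        dur = min(rng.uniform(lo, hi), total - t)
        if not wake:
            ivs.append((t, t + dur))
        t += dur
        wake = not wake
    return IntervalSet([iv for iv in ivs if iv[1] - iv[0] > 1e-9])


def _poisson_times(nrems: IntervalSet, rate, rng, min_sep, margin):
    """Homogeneous Poisson times on NREMS with a refractory separation."""
    total = nrems.total_duration()
    n = rng.poisson(rate * total)
    if min_sep * n > 0.8 * total:
        raise ValueError("event rate denser than the refractory spacing allows")
    tc = np.sort(rng.uniform(margin, total - margin, size=max(n, 0)))
    keep = []
    last = -np.inf
    for t in tc:
        if t - last >= min_sep:
            keep.append(t)
            last = t
    return nrems.from_concat(np.array(keep)) if keep else np.empty(0)


def _fits_inside(nrems: IntervalSet, t, half_lo, half_hi):
    return bool(nrems.contains(t - half_lo)) and bool(nrems.contains(t + half_hi))


# ---------------------------------------------------------------- sleep

def simulate_sleep_block(cfg: SimConfig, seed, t0=0.0, p_so_swr=None,
                         p_pfc_m1=None):
    """One sleep block: LFP recordings per area plus ground-truth events."""
    rng = np.random.default_rng(seed)
    p_so_swr = cfg.p_so_swr if p_so_swr is None else p_so_swr
    p_pfc_m1 = cfg.p_pfc_m1 if p_pfc_m1 is None else p_pfc_m1
    rate, T = cfg.rate, cfg.sleep_block_s
    n = int(round(T * rate))
    nrems_rel = _alternating_bouts(T, cfg.nrem_bout_s, cfg.wake_bout_s, rng)
    nrems = IntervalSet([(t0 + s, t0 + e) for s, e in nrems_rel])

    # ---- event placement (relative clock; margins keep waves inside NREMS)
    pfc_up = _poisson_times(nrems_rel, cfg.so_rate, rng, 1.4, 0.8)
    n_m1 = rng.poisson(cfg.so_rate * nrems_rel.total_duration())
    m1_up, m1_coupled = [], []
    indep = _poisson_times(nrems_rel, cfg.so_rate, rng, 1.4, 0.8)
    for i in range(n_m1):
        if len(pfc_up) and rng.uniform() < p_pfc_m1:
            base = pfc_up[rng.integers(len(pfc_up))]
            t = base + rng.normal(0.0, cfg.pfc_m1_lag_sd)
            coupled = True
        elif len(indep):
            t = indep[rng.integers(len(indep))]
            coupled = False
        else:
            continue
        if _fits_inside(nrems_rel, t, 0.8, 0.8) and all(abs(t - u) > 1.2 for u in m1_up):
            m1_up.append(float(t))
            m1_coupled.append(coupled)
    m1_up = np.array(m1_up)
    m1_coupled = np.array(m1_coupled, dtype=bool)

    n_swr = rng.poisson(cfg.swr_rate * nrems_rel.total_duration())
    swr_peak, swr_coupled = [], []
    for i in range(n_swr):
        if len(m1_up) and rng.uniform() < p_so_swr:
            base = m1_up[rng.integers(len(m1_up))]
            lag = np.clip(rng.normal(0.0, cfg.so_swr_lag_sd), -0.7, 0.7)
            t = base + lag
            coupled = True
        else:
            tc = rng.uniform(0.3, nrems_rel.total_duration() - 0.3)
            t = float(nrems_rel.from_concat([tc])[0])
            coupled = False
        if _fits_inside(nrems_rel, t, 0.2, 0.2) and all(abs(t - u) > 0.3 for u in swr_peak):
            swr_peak.append(float(t))
            swr_coupled.append(coupled)
    swr_peak = np.sort(np.array(swr_peak))
    swr_coupled = np.array(swr_coupled, dtype=bool)[np.argsort(swr_peak)] if len(swr_peak) else np.empty(0, bool)

    spindles = {}
    for area, so_up in (("PFC", pfc_up), ("M1", m1_up)):
        n_sp = rng.poisson(cfg.spindle_rate * nrems_rel.total_duration())
        pk = []
        for i in range(n_sp):
            if len(so_up) and rng.uniform() < cfg.p_so_spindle:
                t = so_up[rng.integers(len(so_up))] + rng.uniform(-0.4, 0.9)
            else:
                tc = rng.uniform(1.0, nrems_rel.total_duration() - 1.0)
                t = float(nrems_rel.from_concat([tc])[0])
            if _fits_inside(nrems_rel, t, 0.7, 0.7) and all(abs(t - u) > 1.8 for u in pk):
                pk.append(float(t))
        spindles[area] = np.sort(np.array(pk))

    # ---- waveform synthesis
    tgrid = np.arange(n) / rate
    nrems_mask = nrems_rel.contains(tgrid)
    recordings = {}
    so_down = {}
    so_up_abs = {}
    swr_onsets = np.empty(len(swr_peak))
    swr_ends = np.empty(len(swr_peak))

    def add_sine_cycle(sig, t_down, d, amp):
        """One SO cycle: peak at t_down, trough at t_down + d."""
        P = 2.0 * d
        start = t_down - P / 4.0
        i0, i1 = int(start * rate), int((start + P) * rate)
        i0c, i1c = max(i0, 0), min(i1, n)
        tt = tgrid[i0c:i1c] - start
        sig[i0c:i1c] += amp * np.sin(2 * np.pi * tt / P)

    def add_burst(sig, t_center, dur, amp, freq):
        i0 = int((t_center - dur / 2) * rate)
        i1 = i0 + int(dur * rate)
        i0c, i1c = max(i0, 0), min(i1, n)
        tt = tgrid[i0c:i1c]
        env = np.hanning(i1 - i0)[i0c - i0: (i0c - i0) + (i1c - i0c)]
        sig[i0c:i1c] += amp * env * np.sin(2 * np.pi * freq * (tt - tt[0]))

    for area in ("PFC", "M1", "HPC"):
        common = np.zeros(n)
        if area in ("PFC", "M1"):
            ups = pfc_up if area == "PFC" else m1_up
            downs = []
            for t_up in ups:
                d = rng.uniform(*cfg.so_dur_s)
                t_down = t_up - d
                downs.append(t_down)
                add_sine_cycle(common, t_down, d, cfg.so_amp_uv)
            so_down[area] = t0 + np.asarray(downs)
            so_up_abs[area] = t0 + np.asarray(ups)
            for t_pk in spindles[area]:
                dur = rng.uniform(*cfg.spindle_dur_s)
                add_burst(common, t_pk, dur, cfg.spindle_amp_uv,
                          rng.uniform(11.0, 14.0))
        else:
            for j, t_pk in enumerate(swr_peak):
                dur = rng.uniform(*cfg.swr_dur_s)
                add_burst(common, t_pk, dur, cfg.swr_amp_uv, cfg.swr_freq_hz)
                swr_onsets[j] = t0 + t_pk - dur / 2
                swr_ends[j] = t0 + t_pk + dur / 2
        delta = _band_noise(n, rate, 3.5, 4.8, rng) * cfg.delta_boost_uv
        gamma = _band_noise(n, rate, 30.0, 60.0, rng) * cfg.gamma_boost_uv
        state = np.where(nrems_mask, 1.0, 0.0)
        samples = np.empty((cfg.n_channels, n), dtype=np.float32)
        for ch in range(cfg.n_channels):
            bg = _brown_noise(n, rng) * cfg.background_uv
            sn = rng.standard_normal(n) * cfg.sensor_noise_uv
            samples[ch] = (common + delta * state + gamma * (1 - state)
                           + bg + sn)
        recordings[area] = Recording(area, samples, rate,
                                     np.ones(cfg.n_channels, bool), t0=t0)

    gt = GroundTruthEvents(
        nrems=nrems,
        so_down=so_down,
        so_up=so_up_abs,
        spindle_peak={a: t0 + v for a, v in spindles.items()},
        swr_onset=swr_onsets, swr_peak=t0 + swr_peak, swr_end=swr_ends,
        pfc_m1_coupled=m1_coupled, so_swr_coupled=swr_coupled,
        replay_tagged=np.zeros(len(swr_peak), dtype=bool))
    return recordings, gt


# ---------------------------------------------------------------- events only

def simulate_event_trains(cfg: SimConfig, seed, duration_s=None,
                          p_so_swr=None, p_pfc_m1=None):
    """Fast event-level path: ground-truth event trains without LFP.

    Returns a GroundTruthEvents whose NREMS is a single interval of the
    stated duration. Used for large-replicate calibration studies where the
    quantity under test is downstream of detection.
    """
    rng = np.random.default_rng(seed)
    p_so_swr = cfg.p_so_swr if p_so_swr is None else p_so_swr
    p_pfc_m1 = cfg.p_pfc_m1 if p_pfc_m1 is None else p_pfc_m1
    T = duration_s if duration_s is not None else cfg.sleep_block_s
    nrems = IntervalSet([(0.0, T)])
    pfc_up = _poisson_times(nrems, cfg.so_rate, rng, 1.4, 0.8)

    def _place(n, coupled_p, bases, lag_fn, min_sep, margin):
        # place a uniform refractory train, then move a Binomial(p) subset
        # onto free reference events: the event count and the coupled
        # fraction are then unbiased by the refractory rule
        def ok_spacing(t, others):
            return not len(others) or np.abs(np.asarray(others) - t).min() > min_sep

        accepted = []
        for t in np.sort(rng.uniform(margin, T - margin, size=n)):
            if not accepted or t - accepted[-1] > min_sep:
                accepted.append(float(t))
        times = np.array(accepted)
        flags = np.zeros(len(times), dtype=bool)
        if len(bases) and coupled_p > 0:
            move = np.nonzero(rng.uniform(size=len(times)) < coupled_p)[0]
            free = list(rng.permutation(bases))
            for i in rng.permutation(move):
                others = np.delete(times, i)
                if not free:
                    break
                cand = rng.choice(len(free), size=min(30, len(free)),
                                  replace=False)
                for j in cand:
                    t_new = float(free[j] + lag_fn())
                    if margin < t_new < T - margin and ok_spacing(t_new, others):
                        times[i] = t_new
                        flags[i] = True
                        free.pop(int(j))
                        break
        order = np.argsort(times)
        return times[order], flags[order]

    m1_up, m1_coupled = _place(
        rng.poisson(cfg.so_rate * T), p_pfc_m1, pfc_up,
        lambda: rng.normal(0.0, cfg.pfc_m1_lag_sd), 1.2, 0.8)
    if len(m1_up):
        m1_order = np.argsort(m1_up)
        m1_up, m1_coupled = m1_up[m1_order], m1_coupled[m1_order]
    swr, swr_c = _place(
        rng.poisson(cfg.swr_rate * T), p_so_swr, m1_up,
        lambda: np.clip(rng.normal(0.0, cfg.so_swr_lag_sd), -0.7, 0.7),
        0.3, 0.2)
    order = np.argsort(swr) if len(swr) else []
    swr = swr[order] if len(swr) else np.empty(0)
    return GroundTruthEvents(
        nrems=nrems,
        so_down={"PFC": pfc_up - 0.3, "M1": m1_up - 0.3},
        so_up={"PFC": pfc_up, "M1": m1_up},
        spindle_peak={"PFC": np.empty(0), "M1": np.empty(0)},
        swr_onset=swr - 0.05, swr_peak=swr, swr_end=swr + 0.05,
        pfc_m1_coupled=m1_coupled,
        so_swr_coupled=swr_c[order] if len(swr) else np.empty(0, bool),
        replay_tagged=np.zeros(len(swr), bool))


# ---------------------------------------------------------------- training

def latent_template(n_bins, n_latents=3):
    """Fixed smooth per-study template trajectory (bins x latents)."""
    s = np.linspace(0, 1, n_bins)
    cols = [np.sin(np.pi * s),
            np.sin(2 * np.pi * s),
            np.cos(np.pi * s) - np.cos(np.pi * s).mean()]
    return np.column_stack(cols[:n_latents] +
                           [np.sin((3 + k) * np.pi * s) for k in range(max(0, n_latents - 3))])


def make_loadings(cfg: SimConfig, seed):
    """Per-study loading matrix U (units x latents), fixed across days."""
    rng = np.random.default_rng(seed)
    U = rng.normal(0.0, 1.0, size=(cfg.n_units, cfg.latent_dim))
    U, _ = np.linalg.qr(U)
    return U * cfg.loading_scale * np.sqrt(cfg.n_units / 3.0)


def _smooth_noise(n_bins, n_latents, sd, rng):
    """AR(1)-smoothed latent noise (rho 0.8), unit-calibrated then scaled."""
    e = rng.standard_normal((n_bins, n_latents))
    out = np.empty_like(e)
    out[0] = e[0]
    for t in range(1, n_bins):
        out[t] = 0.8 * out[t - 1] + np.sqrt(1 - 0.8 ** 2) * e[t]
    return sd * out


def simulate_training_block(cfg: SimConfig, seed, t0=0.0, latent_noise_sd=None,
                            success_p=None, loadings=None, bin_s=0.015):
    """Reach trials with latent-driven Poisson spiking.

    Returns (SpikeTrainSet (M1 units), TrialTable, dict ground truth with
    the template, per-trial latents and loadings).
    """
    rng = np.random.default_rng(seed)
    sd = cfg.latent_noise_sd if latent_noise_sd is None else latent_noise_sd
    p_s = cfg.success_p if success_p is None else success_p
    U = make_loadings(cfg, seed=0) if loadings is None else loadings
    lo, hi = cfg.trial_window_s
    n_bins = int(round((hi - lo) / bin_s))
    template = latent_template(n_bins, cfg.latent_dim)
    onsets = t0 + 5.0 + np.arange(cfg.n_trials) * cfg.trial_gap_s
    unit_spikes = [[] for _ in range(cfg.n_units)]
    latents = []
    rows = []
    block_end = onsets[-1] + cfg.trial_gap_s
    # baseline activity between trials keeps units alive outside windows
    for u in range(cfg.n_units):
        n_bg = rng.poisson(cfg.baseline_hz * (block_end - t0))
        unit_spikes[u].extend(rng.uniform(t0, block_end, size=n_bg))
    for k, onset in enumerate(onsets):
        z = cfg.replay_gain * template + _smooth_noise(n_bins, cfg.latent_dim, sd, rng)
        latents.append(z)
        rate_per_bin = cfg.baseline_hz * bin_s * np.exp(U @ z.T)  # units x bins
        counts = rng.poisson(rate_per_bin)
        for u in range(cfg.n_units):
            for b in np.nonzero(counts[u])[0]:
                t_lo = onset + lo + b * bin_s
                unit_spikes[u].extend(t_lo + rng.uniform(0, bin_s, size=counts[u, b]))
        touch = onset + rng.uniform(0.25, 0.45)
        rows.append((f"t{k:03d}", onset, touch, bool(rng.uniform() < p_s), "R"))
    spikes = SpikeTrainSet([(f"u{u:02d}", "M1", np.sort(unit_spikes[u]))
                            for u in range(cfg.n_units)])
    trials = make_trial_table(rows)
    gt = {"template": template, "latents": latents, "loadings": U,
          "latent_noise_sd": sd, "bin_s": bin_s}
    return spikes, trials, gt


def _shift_gt(gt: GroundTruthEvents, t0: float) -> None:
    """Shift all ground-truth event times onto the session clock (in place)."""
    gt.nrems = IntervalSet([(s + t0, e + t0) for s, e in gt.nrems])
    gt.so_down = {a: v + t0 for a, v in gt.so_down.items()}
    gt.so_up = {a: v + t0 for a, v in gt.so_up.items()}
    gt.spindle_peak = {a: v + t0 for a, v in gt.spindle_peak.items()}
    gt.swr_onset = gt.swr_onset + t0
    gt.swr_peak = gt.swr_peak + t0
    gt.swr_end = gt.swr_end + t0


def simulate_sleep_spikes(cfg: SimConfig, seed, t0, duration_s) -> SpikeTrainSet:
    """Baseline Poisson spiking of the task units during a sleep block."""
    rng = np.random.default_rng(seed)
    units = []
    for u in range(cfg.n_units):
        n = rng.poisson(cfg.baseline_hz * duration_s)
        units.append((f"u{u:02d}", "M1",
                      np.sort(rng.uniform(t0, t0 + duration_s, size=n))))
    return SpikeTrainSet(units)


def merge_spikes(*sets) -> SpikeTrainSet:
    """Union of spike trains, merged per unit id/area."""
    pooled = {}
    for st in sets:
        for uid, area, t in st.units:
            pooled.setdefault((uid, area), []).append(t)
    return SpikeTrainSet([(uid, area, np.sort(np.concatenate(ts)))
                          for (uid, area), ts in sorted(pooled.items())])


def inject_replay(spikes: SpikeTrainSet, swr_onsets, template, loadings,
                  cfg: SimConfig, seed, fraction=None, compression=None,
                  bin_s=0.015):
    """Insert compressed template-driven spikes after a fraction of SWRs.

    Returns (modified SpikeTrainSet, replay tags per SWR)."""
    fraction = cfg.replay_fraction if fraction is None else fraction
    compression = cfg.replay_compression if compression is None else compression
    if not 0.2 < compression < 2.0:
        raise ValueError("compression must lie in (0.2, 2.0)")
    rng = np.random.default_rng(seed)
    swr_onsets = np.asarray(swr_onsets, dtype=float)
    tags = rng.uniform(size=len(swr_onsets)) < fraction
    n_bins = template.shape[0]
    dur = n_bins * bin_s * compression
    cbin = dur / n_bins
    new_times = [list(t) for _, _, t in spikes.units]
    for onset in swr_onsets[tags]:
        rate_per_bin = cfg.baseline_hz * cbin * np.exp(
            cfg.replay_gain * loadings @ template.T)
        counts = rng.poisson(rate_per_bin)
        for u in range(len(new_times)):
            for b in np.nonzero(counts[u])[0]:
                t_lo = onset + b * cbin
                new_times[u].extend(t_lo + rng.uniform(0, cbin, size=counts[u, b]))
    out = SpikeTrainSet([(uid, area, np.sort(t))
                         for (uid, area, _), t in zip(spikes.units, new_times)])
    return out, tags


def assemble_session_recordings(day_data, cfg: SimConfig, seed=0) -> dict:
    """Stitch pre-sleep, training-gap and post-sleep LFP into one Recording
    per area on the session clock (training gap filled with wake-like
    noise)."""
    rng = np.random.default_rng(seed)
    recs = {}
    t_train0, t_train1 = day_data.manifest.block_interval("training")
    n_gap = int(round((t_train1 - t_train0) * cfg.rate))
    for area in ("PFC", "M1", "HPC"):
        pre = day_data.recordings_pre[area]
        post = day_data.recordings_post[area]
        gap = np.empty((cfg.n_channels, n_gap), dtype=np.float32)
        gamma = _band_noise(n_gap, cfg.rate, 30.0, 60.0, rng) * cfg.gamma_boost_uv
        for ch in range(cfg.n_channels):
            gap[ch] = (_brown_noise(n_gap, rng) * cfg.background_uv + gamma
                       + rng.standard_normal(n_gap) * cfg.sensor_noise_uv)
        samples = np.concatenate([pre.samples, gap, post.samples], axis=1)
        recs[area] = Recording(area, samples, cfg.rate,
                               np.ones(cfg.n_channels, bool), t0=0.0)
    return recs


def simulate_swr_population(cfg: SimConfig, seed, swr_onsets, so_plus,
                            t0, duration_s, shared_gain=1.0, window_s=1.0,
                            bin_s=0.015, n_units_per_area=None):
    """PFC and M1 spiking around SWRs with a condition-gated shared latent.

    Baseline Poisson units in both areas; during the 1 s window after each
    SO-coupled SWR (``so_plus``) a common smooth 1-d latent drives both
    areas (communication), while windows after non-coupled SWRs carry
    independent area-private latents of the same magnitude. Returns a
    SpikeTrainSet with PFC units 'p..' and M1 units 'm..'.
    """
    rng = np.random.default_rng(seed)
    n_u = n_units_per_area or cfg.n_units
    w = {a: rng.normal(0.0, 0.6, size=n_u) for a in ("PFC", "M1")}
    spikes = {a: [[] for _ in range(n_u)] for a in ("PFC", "M1")}
    for a in ("PFC", "M1"):
        for u in range(n_u):
            nb = rng.poisson(cfg.baseline_hz * duration_s)
            spikes[a][u].extend(rng.uniform(t0, t0 + duration_s, size=nb))
    n_bins = int(round(window_s / bin_s))
    for onset, plus in zip(np.asarray(swr_onsets, dtype=float),
                           np.asarray(so_plus, dtype=bool)):
        shared = _smooth_noise(n_bins, 1, shared_gain, rng)[:, 0]
        for a in ("PFC", "M1"):
            lat = shared if plus else _smooth_noise(n_bins, 1, shared_gain,
                                                    rng)[:, 0]
            rate = cfg.baseline_hz * bin_s * np.exp(np.outer(w[a], lat))
            counts = rng.poisson(rate)
            for u in range(n_u):
                for b in np.nonzero(counts[u])[0]:
                    t_lo = onset + b * bin_s
                    spikes[a][u].extend(
                        t_lo + rng.uniform(0, bin_s, size=counts[u, b]))
    units = [(f"p{u:02d}", "PFC", np.sort(spikes["PFC"][u])) for u in range(n_u)]
    units += [(f"m{u:02d}", "M1", np.sort(spikes["M1"][u])) for u in range(n_u)]
    return SpikeTrainSet(units)


# ---------------------------------------------------------------- study

@dataclass
class DayData:
    day: int
    manifest: SessionManifest
    pre: GroundTruthEvents
    post: GroundTruthEvents
    recordings_pre: dict | None
    recordings_post: dict | None
    spikes: SpikeTrainSet | None
    trials: object | None
    training_gt: dict | None
    true_values: dict


def simulate_study(cfg: SimConfig, seed, n_days=None, lfp=True,
                   sleep_duration_s=None, spiking=True):
    """Full multi-day dataset following the day schedules.

    With ``lfp=False`` only ground-truth event trains are generated (fast
    path for large replicate studies of downstream estimators); with
    ``spiking=False`` the spike/trial streams are skipped as well
    (coupling-only studies).
    """
    n_days = cfg.n_days if n_days is None else n_days
    ss = np.random.SeedSequence(seed)
    day_seeds = ss.spawn(n_days)
    loadings = make_loadings(cfg, seed=0)
    days = []
    for d in range(1, n_days + 1):
        s_pre, s_train, s_post, s_replay = [
            int(x.generate_state(1)[0] % (2 ** 31)) for x in day_seeds[d - 1].spawn(4)]
        p_pm = float(cfg.pfc_m1_schedule(d))
        p_sw_post = float(cfg.so_swr_post_schedule(d))
        noise = float(cfg.latent_noise_schedule(d))
        p_succ = float(cfg.success_schedule(d))
        T = sleep_duration_s or cfg.sleep_block_s
        train_dur = cfg.n_trials * cfg.trial_gap_s + 10.0
        t_pre, t_train, t_post = 0.0, T, T + train_dur
        manifest = SessionManifest("synthetic", d, {
            "pre_sleep": (t_pre, T),
            "training": (T, t_post),
            "post_sleep": (t_post, t_post + T)})
        if lfp:
            rec_pre, gt_pre = simulate_sleep_block(
                replace(cfg, sleep_block_s=T), s_pre, t0=t_pre,
                p_so_swr=cfg.so_swr_pre_p, p_pfc_m1=cfg.pfc_m1_schedule.L)
            rec_post, gt_post = simulate_sleep_block(
                replace(cfg, sleep_block_s=T), s_post, t0=t_post,
                p_so_swr=p_sw_post, p_pfc_m1=p_pm)
        else:
            rec_pre = rec_post = None
            gt_pre = simulate_event_trains(
                replace(cfg, sleep_block_s=T), s_pre,
                p_so_swr=cfg.so_swr_pre_p, p_pfc_m1=cfg.pfc_m1_schedule.L)
            gt_post = simulate_event_trains(
                replace(cfg, sleep_block_s=T), s_post,
                p_so_swr=p_sw_post, p_pfc_m1=p_pm)
            _shift_gt(gt_post, t_post)
        spikes = trials = tgt = None
        if spiking:
            spikes, trials, tgt = simulate_training_block(
                replace(cfg, trial_gap_s=min(cfg.trial_gap_s,
                                             (train_dur - 10.0) / cfg.n_trials)),
                s_train, t0=t_train, latent_noise_sd=noise, success_p=p_succ,
                loadings=loadings)
            sleep_spk = simulate_sleep_spikes(cfg, s_post + 1, t_post, T)
            spikes = merge_spikes(spikes, sleep_spk)
        if spiking and len(gt_post.swr_onset):
            spikes, tags = inject_replay(spikes, gt_post.swr_onset,
                                         tgt["template"], loadings, cfg,
                                         s_replay)
            gt_post.replay_tagged = tags
            m1_up = np.sort(gt_post.so_up["M1"])
            so_plus = np.array([
                np.any((m1_up > t) & (m1_up <= t + 1.0))
                for t in gt_post.swr_onset])
            pop = simulate_swr_population(cfg, s_replay + 1,
                                          gt_post.swr_onset, so_plus,
                                          t_post, T)
            spikes = merge_spikes(spikes, pop)
        days.append(DayData(d, manifest, gt_pre, gt_post, rec_pre, rec_post,
                            spikes, trials, tgt,
                            true_values={"p_pfc_m1": p_pm,
                                         "p_so_swr_post": p_sw_post,
                                         "p_so_swr_pre": cfg.so_swr_pre_p,
                                         "latent_noise_sd": noise,
                                         "success_p": p_succ}))
    return days
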