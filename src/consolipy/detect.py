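"""Detection of slow oscillations, spindles and sharp-wave ripples.

All detectors operate on a channel-averaged trace restricted to NREMS:

* SO: plain channel average, band-passed 0.1-4 Hz (Butterworth HP order 2
  then LP order 5, both zero-phase). Candidate waves are delimited by
  positive-to-negative zero crossings; an SO requires its preceding peak
  above the 85th percentile of all candidate peaks (down-state), its trough
  below the 40th percentile of all candidate troughs (up-state), and a
  peak-to-trough time of 150-500 ms.
* Spindle: per-channel z-scored average, 10-15 Hz (orders 6/8), Hilbert
  envelope smoothed with a 200 ms Gaussian window; thresholds mu+2.5 sd
  (upper) / mu+1.5 sd (lower) of the NREMS envelope, minimum 500 ms above
  the lower threshold with at least one sample above the upper.
* SWR: z-scored average of the designated CA1 channels, 150-250 Hz
  (orders 8/10), 20 ms Gaussian envelope smoothing, mu+4 sd / mu+1 sd,
  minimum 50 ms.

Samples exceeding 10 sd within a channel are treated as artifacts and
replaced by linear interpolation before averaging so detection is
unaffected by isolated glitches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .types import IntervalSet, Recording, make_event_table


@dataclass(frozen=True)
class BandSpec:
    """Two-stage zero-phase Butterworth band (HP then LP, independent orders)."""

    name: str
    hp_cutoff: float
    hp_order: int
    lp_cutoff: float
    lp_order: int
    zero_phase: bool = True

    def __post_init__(self):
        if not self.hp_cutoff < self.lp_cutoff:
            raise ValueError("hp_cutoff must be below lp_cutoff")
        if self.hp_order < 1 or self.lp_order < 1:
            raise ValueError("filter orders must be >= 1")


SO_BAND = BandSpec("so", 0.1, 2, 4.0, 5)
SPINDLE_BAND = BandSpec("spindle", 10.0, 6, 15.0, 8)
RIPPLE_BAND = BandSpec("swr", 150.0, 8, 250.0, 10)


def _deglitch(x: np.ndarray, artifact_sd: float) -> np.ndarray:
    """Replace |x| > artifact_sd * sd(x) samples by linear interpolation."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return x.copy()
    bad = np.abs(x - x.mean()) > artifact_sd * sd
    if not np.any(bad):
        return x.copy()
    out = x.copy()
    idx = np.arange(len(x))
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def make_trace(recording: Recording, mode="plain_mean", channels=None,
               artifact_sd=10.0) -> np.ndarray:
    """Channel-averaged detection trace.

    mode='plain_mean' averages raw channels; 'zscore_mean' standardizes each
    channel first so all channels contribute unit variance. ``channels``
    restricts to a subset (e.g. the three designated CA1 channels); bad
    channels are always excluded.
    """
    ok = recording.channel_ok.copy()
    if channels is not None:
        sub = np.zeros_like(ok)
        sub[np.asarray(channels, dtype=int)] = True
        ok &= sub
    if not np.any(ok):
        raise ValueError("no good channels to average")
    rows = []
    for ch in np.nonzero(ok)[0]:
        x = _deglitch(recording.samples[ch].astype(float), artifact_sd)
        if mode == "zscore_mean":
            sd = x.std()
            x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        elif mode != "plain_mean":
            raise ValueError(f"unknown mode {mode!r}")
        rows.append(x)
    return np.mean(rows, axis=0)


def bandpass_zero_phase(trace, band: BandSpec, rate: float) -> np.ndarray:
    """HP then LP Butterworth, each applied forward-backward (zero phase)."""
    if rate <= 2 * band.lp_cutoff:
        raise ValueError("sampling rate must exceed twice the low-pass cutoff")
    sos_hp = signal.butter(band.hp_order, band.hp_cutoff, "highpass",
                           fs=rate, output="sos")
    sos_lp = signal.butter(band.lp_order, band.lp_cutoff, "lowpass",
                           fs=rate, output="sos")
    y = signal.sosfiltfilt(sos_hp, np.asarray(trace, dtype=float))
    return signal.sosfiltfilt(sos_lp, y)


def _interval_slices(nrems: IntervalSet, rate: float, t0: float, n: int):
    """Sample index ranges covering each NREMS interval."""
    out = []
    for s, e in nrems:
        i0 = max(int(np.ceil((s - t0) * rate)), 0)
        i1 = min(int(np.floor((e - t0) * rate)), n)
        if i1 > i0:
            out.append((i0, i1))
    return out


def _so_candidates(seg: np.ndarray, rate: float, t_start: float):
    """Candidate waves from positive-to-negative zero crossings.

    Returns (peak_time, peak_val, trough_time, trough_val, end_time) per
    candidate: the peak before the crossing, the trough after it, and the
    following negative-to-positive crossing.
    """
    sgn = np.sign(seg)
    sgn[sgn == 0] = 1
    d = np.diff(sgn)
    pn = np.nonzero(d < 0)[0]   # + -> - crossings (last positive sample)
    np_ = np.nonzero(d > 0)[0]  # - -> + crossings
    cands = []
    for c in pn:
        prev_up = np_[np_ < c]
        start = prev_up[-1] + 1 if len(prev_up) else 0
        next_up = np_[np_ > c]
        end = next_up[0] + 1 if len(next_up) else len(seg)
        if c + 1 >= end or start > c:
            continue
        pk = start + int(np.argmax(seg[start:c + 1]))
        tr = (c + 1) + int(np.argmin(seg[c + 1:end]))
        cands.append((t_start + pk / rate, seg[pk],
                      t_start + tr / rate, seg[tr],
                      t_start + min(end, len(seg) - 1) / rate))
    return cands


def detect_so(filtered, rate, nrems: IntervalSet, area, t0=0.0,
              peak_pct=85.0, trough_pct=40.0, dur_min=0.150, dur_max=0.500):
    """SO detection on the delta-filtered trace.

    Thresholds are percentiles of the candidate-wave peak/trough
    distributions pooled over the whole sleep block; both exceedances are
    strict. The emitted t_onset is the down-state peak time, t_peak the
    up-state trough time and t_end the following upward zero crossing.
    """
    filtered = np.asarray(filtered, dtype=float)
    cands = []
    for i0, i1 in _interval_slices(nrems, rate, t0, len(filtered)):
        cands.extend(_so_candidates(filtered[i0:i1], rate, t0 + i0 / rate))
    if not cands:
        return make_event_table()
    peaks = np.array([c[1] for c in cands])
    troughs = np.array([c[3] for c in cands])
    peak_thr = np.percentile(peaks, peak_pct)
    trough_thr = np.percentile(troughs, trough_pct)
    rows = []
    for t_pk, v_pk, t_tr, v_tr, t_end in cands:
        dur = t_tr - t_pk
        if v_pk > peak_thr and v_tr < trough_thr and dur_min <= dur <= dur_max:
            rows.append(dict(kind="SO", area=area, t_onset=t_pk, t_peak=t_tr,
                             t_end=max(t_end, t_tr), amp_peak=v_pk,
                             amp_trough=v_tr))
    return make_event_table(rows)


def smoothed_envelope(filtered_seg, rate, smooth_s):
    """Hilbert magnitude convolved with a Gaussian window.

    The stated window length is taken as the full width; the Gaussian sd is
    half that width, truncated at +/-3 sd.
    """
    env = np.abs(signal.hilbert(np.asarray(filtered_seg, dtype=float)))
    sigma = (smooth_s / 2.0) * rate
    return gaussian_filter1d(env, sigma=sigma, truncate=3.0)


def detect_envelope_events(filtered, rate, nrems: IntervalSet, kind, area,
                           t0=0.0, upper_sd=2.5, lower_sd=1.5, min_dur=0.5,
                           env_smooth=0.2):
    """Threshold-crossing detection on the smoothed Hilbert envelope.

    An event is a maximal run above the lower threshold that contains at
    least one sample above the upper threshold and lasts >= min_dur.
    Envelope mean and sd are computed over NREMS samples of the whole block;
    the Hilbert transform is taken per NREMS interval (never across gaps).
    """
    filtered = np.asarray(filtered, dtype=float)
    slices = _interval_slices(nrems, rate, t0, len(filtered))
    if not slices:
        raise ValueError("no NREMS samples available")
    envs = [smoothed_envelope(filtered[i0:i1], rate, env_smooth)
            for i0, i1 in slices]
    allenv = np.concatenate(envs)
    mu, sd = allenv.mean(), allenv.std()
    upper = mu + upper_sd * sd
    lower = mu + lower_sd * sd
    rows = []
    for (i0, i1), env in zip(slices, envs):
        above = env > lower
        if not np.any(above):
            continue
        padded = np.concatenate([[False], above, [False]]).astype(int)
        d = np.diff(padded)
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        for s, e in zip(starts, ends):
            if (e - s) / rate < min_dur:
                continue
            if not np.any(env[s:e] > upper):
                continue
            pk = s + int(np.argmax(env[s:e]))
            rows.append(dict(kind=kind, area=area,
                             t_onset=t0 + (i0 + s) / rate,
                             t_peak=t0 + (i0 + pk) / rate,
                             t_end=t0 + (i0 + e - 1) / rate,
                             amp_peak=env[pk], amp_trough=np.nan))
    return make_event_table(rows)


def detect_block(recordings: dict, nrems: IntervalSet, cfg, swr_channels=None):
    """Run all detectors for one sleep block.

    recordings maps area -> Recording (PFC, M1 required; HPC optional).
    Returns a dict of event tables keyed (kind, area).
    """
    det = cfg["detection"]
    art = det["artifact_sd"]
    out = {}
    for area in ("PFC", "M1"):
        if area not in recordings:
            continue
        rec = recordings[area]
        so_cfg = det["so"]
        tr = make_trace(rec, "plain_mean", artifact_sd=art)
        filt = bandpass_zero_phase(tr, SO_BAND, rec.rate)
        out[("SO", area)] = detect_so(
            filt, rec.rate, nrems, area, t0=rec.t0,
            peak_pct=so_cfg["peak_pct"], trough_pct=so_cfg["trough_pct"],
            dur_min=so_cfg["dur_min"], dur_max=so_cfg["dur_max"])
        sp_cfg = det["spindle"]
        trz = make_trace(rec, "zscore_mean", artifact_sd=art)
        filt = bandpass_zero_phase(trz, SPINDLE_BAND, rec.rate)
        out[("SPINDLE", area)] = detect_envelope_events(
            filt, rec.rate, nrems, "SPINDLE", area, t0=rec.t0,
            upper_sd=sp_cfg["upper_sd"], lower_sd=sp_cfg["lower_sd"],
            min_dur=sp_cfg["min_dur"], env_smooth=sp_cfg["env_smooth"])
    if "HPC" in recordings:
        rec = recordings["HPC"]
        swr_cfg = det["swr"]
        if swr_channels is None:
            good = np.nonzero(rec.channel_ok)[0]
            swr_channels = good[:swr_cfg.get("n_channels", 3)]
        trz = make_trace(rec, "zscore_mean", channels=swr_channels,
                         artifact_sd=art)
        filt = bandpass_zero_phase(trz, RIPPLE_BAND, rec.rate)
        out[("SWR", "HPC")] = detect_envelope_events(
            filt, rec.rate, nrems, "SWR", "HPC", t0=rec.t0,
            upper_sd=swr_cfg["upper_sd"], lower_sd=swr_cfg["lower_sd"],
            min_dur=swr_cfg["min_dur"], env_smooth=swr_cfg["env_smooth"])
    return out
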