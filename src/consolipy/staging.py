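"""NREMS staging from LFP band power.

The averaged LFP of one area (M1 by default) is cut into non-overlapping
6 s epochs; per epoch the power spectral density is averaged over the
slow-wave band (0.1-4 Hz) and the gamma band (30-60 Hz). A 2-means
clustering of the standardized (delta, gamma) features separates NREMS
from the rest (REM/wake are not told apart); the cluster with the higher
mean delta power is NREMS. Adjacent NREMS epochs are merged and runs
shorter than 30 s are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.cluster import KMeans

from .types import IntervalSet

NREMS = "NREMS"
OTHER = "OTHER"


@dataclass
class EpochFeature:
    index: int
    start: float          # s, relative to trace start
    delta_power: float    # mean PSD over 0.1-4 Hz (uV^2/Hz)
    gamma_power: float    # mean PSD over 30-60 Hz


def epoch_features(trace, rate, epoch_s=6.0, delta_band=(0.1, 4.0),
                   gamma_band=(30.0, 60.0)):
    """Per-epoch band-power features; trailing partial epoch is discarded."""
    trace = np.asarray(trace, dtype=float)
    n_per = int(round(epoch_s * rate))
    n_epochs = len(trace) // n_per
    if n_epochs < 1:
        raise ValueError(f"trace shorter than one {epoch_s} s epoch")
    feats = []
    for i in range(n_epochs):
        seg = trace[i * n_per:(i + 1) * n_per]
        # one Hann-tapered segment per epoch (periodogram-style Welch)
        f, pxx = signal.welch(seg, fs=rate, window="hann", nperseg=n_per)
        d = pxx[(f >= delta_band[0]) & (f <= delta_band[1])].mean()
        g = pxx[(f >= gamma_band[0]) & (f <= gamma_band[1])].mean()
        feats.append(EpochFeature(i, i * epoch_s, float(d), float(g)))
    return feats


def classify_nrems(features, seed=0, n_restarts=10):
    """2-means on standardized (delta, gamma); high-delta cluster is NREMS."""
    X = np.array([[f.delta_power, f.gamma_power] for f in features], dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 epochs to cluster")
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate clustering: all epoch features identical")
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(Xs)
    # label-invariance: whichever cluster has higher mean delta power is NREMS
    delta_means = [X[raw == k, 0].mean() if np.any(raw == k) else -np.inf
                   for k in (0, 1)]
    nrems_cluster = int(np.argmax(delta_means))
    return [NREMS if r == nrems_cluster else OTHER for r in raw]


def consolidate_nrems(labels, epoch_starts, epoch_s=6.0, min_run_s=30.0,
                      t_offset=0.0) -> IntervalSet:
    """Merge adjacent NREMS epochs; drop merged runs shorter than min_run_s.

    Runs of exactly min_run_s are retained (only strictly shorter runs are
    excluded). ``t_offset`` shifts interval bounds onto the session clock.
    """
    intervals = []
    run_start = None
    prev_end = None
    for lab, s in zip(labels, epoch_starts):
        if lab == NREMS:
            if run_start is None or not np.isclose(s, prev_end):
                if run_start is not None:
                    intervals.append((run_start, prev_end))
                run_start = s
            prev_end = s + epoch_s
        else:
            if run_start is not None:
                intervals.append((run_start, prev_end))
                run_start = None
    if run_start is not None:
        intervals.append((run_start, prev_end))
    kept = [(t_offset + s, t_offset + e) for s, e in intervals
            if e - s >= min_run_s - 1e-9]
    return IntervalSet(kept)


def stage_block(trace, rate, seed=0, cfg=None, t_offset=0.0) -> IntervalSet:
    """Convenience: features -> 2-means -> consolidated NREMS intervals."""
    cfg = cfg or {}
    epoch_s = cfg.get("epoch_s", 6.0)
    feats = epoch_features(trace, rate, epoch_s,
                           tuple(cfg.get("delta_band", (0.1, 4.0))),
                           tuple(cfg.get("gamma_band", (30.0, 60.0))))
    labels = classify_nrems(feats, seed=seed,
                            n_restarts=cfg.get("kmeans_restarts", 10))
    return consolidate_nrems(labels, [f.start for f in feats], epoch_s,
                             cfg.get("min_run_s", 30.0), t_offset=t_offset)
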