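"""Core data containers for multi-area NREM-sleep electrophysiology.

All times are seconds on a per-session clock starting at 0. Intervals are
half-open ``[start, end)``. Event timestamps are stored and serialized at
1 microsecond precision so that write/read round-trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AREAS = ("PFC", "M1", "HPC")
EVENT_KINDS = ("SO", "SPINDLE", "SWR")

#: timestamp quantum (seconds)
TIME_PRECISION = 1e-6


def _round_t(t):
    """Quantize times to the 1 µs storage precision."""
    return np.round(np.asarray(t, dtype=float) / TIME_PRECISION) * TIME_PRECISION


class IntervalSet:
    """Sorted, non-overlapping half-open intervals ``[start, end)`` in seconds."""

    def __init__(self, intervals: Iterable[tuple[float, float]] = ()):
        arr = np.asarray(list(intervals), dtype=float).reshape(-1, 2)
        if arr.size:
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError("intervals must satisfy start < end")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError("intervals overlap")
        self._arr = arr

    @property
    def starts(self) -> np.ndarray:
        return self._arr[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self._arr[:, 1]

    def __len__(self) -> int:
        return len(self._arr)

    def __iter__(self):
        return iter(map(tuple, self._arr))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._arr.shape == other._arr.shape and np.allclose(
            self._arr, other._arr, atol=TIME_PRECISION
        )

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, total={self.total_duration():.1f}s)"

    def total_duration(self) -> float:
        if not len(self):
            return 0.0
        return float(np.sum(self._arr[:, 1] - self._arr[:, 0]))

    def contains(self, t) -> np.ndarray:
        """Membership test, vectorized over times (half-open intervals)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if not len(self):
            return np.zeros(t.shape, dtype=bool)
        idx = np.searchsorted(self.starts, t, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(t.shape, dtype=bool)
        inside[ok] = t[ok] < self.ends[idx[ok]]
        return inside

    def to_concat(self, t) -> np.ndarray:
        """Map session times inside the intervals onto gap-excised time.

        Concatenated time runs from 0 to :meth:`total_duration`.
        """
        t = np.asarray(t, dtype=float)
        if not np.all(self.contains(t)):
            raise ValueError("times must lie inside the interval set")
        offsets = np.concatenate([[0.0], np.cumsum(self.ends - self.starts)])[:-1]
        idx = np.searchsorted(self.starts, t, side="right") - 1
        return offsets[idx] + (t - self.starts[idx])

    def from_concat(self, tc) -> np.ndarray:
        """Inverse of :meth:`to_concat` (tc taken modulo total duration)."""
        total = self.total_duration()
        if total <= 0:
            raise ValueError("empty interval set")
        tc = np.mod(np.asarray(tc, dtype=float), total)
        offsets = np.concatenate([[0.0], np.cumsum(self.ends - self.starts)])
        idx = np.clip(np.searchsorted(offsets, tc, side="right") - 1, 0, len(self) - 1)
        return self.starts[idx] + (tc - offsets[idx])

    def intersect(self, lo: float, hi: float) -> "IntervalSet":
        out = []
        for s, e in self:
            s2, e2 = max(s, lo), min(e, hi)
            if s2 < e2:
                out.append((s2, e2))
        return IntervalSet(out)


@dataclass
class Recording:
    """One area's multichannel LFP block.

    samples are microvolts, shape (channels, time); ``channel_ok`` flags
    channels kept for averaging (bad channels are masked, never dropped).
    """

    area: str
    samples: np.ndarray
    rate: float
    channel_ok: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        if self.area not in AREAS:
            raise ValueError(f"unknown area {self.area!r}")
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (channels, time)")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        self.channel_ok = np.asarray(self.channel_ok, dtype=bool)
        if self.channel_ok.shape != (self.samples.shape[0],):
            raise ValueError("channel_ok length must equal channel count")
        if not np.all(np.isfinite(self.samples[self.channel_ok])):
            raise ValueError("retained samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.shape[1]) / self.rate


@dataclass
class SessionManifest:
    """Labels one day's pre-sleep / training / post-sleep block layout."""

    animal_id: str
    day: int
    blocks: dict  # {"pre_sleep": (s,e), "training": (s,e), "post_sleep": (s,e)}

    def __post_init__(self):
        if self.day < 1:
            raise ValueError("day must be >= 1")
        need = ("pre_sleep", "training", "post_sleep")
        if set(self.blocks) != set(need):
            raise ValueError(f"blocks must be exactly {need}")
        prev_end = -np.inf
        for name in need:
            s, e = self.blocks[name]
            if not s < e:
                raise ValueError(f"block {name}: start must precede end")
            if s < prev_end:
                raise ValueError("blocks must be disjoint and ordered")
            prev_end = e

    def block_interval(self, name: str) -> tuple[float, float]:
        return tuple(map(float, self.blocks[name]))


@dataclass
class SpikeTrainSet:
    """Sorted spike times per unit; each unit is (unit_id, area, times)."""

    units: list = field(default_factory=list)

    def __post_init__(self):
        clean = []
        for unit_id, area, times in self.units:
            if area not in AREAS:
                raise ValueError(f"unknown area {area!r} for unit {unit_id}")
            t = np.asarray(times, dtype=float)
            if t.size and np.any(np.diff(t) < 0):
                raise ValueError(f"unit {unit_id}: spike times must be nondecreasing")
            clean.append((str(unit_id), area, t))
        self.units = clean

    def by_area(self, area: str) -> "SpikeTrainSet":
        return SpikeTrainSet([u for u in self.units if u[1] == area])

    @property
    def unit_ids(self) -> list:
        return [u[0] for u in self.units]

    def __len__(self) -> int:
        return len(self.units)


_TRIAL_COLUMNS = ["trial_id", "reach_onset", "pellet_touch", "success", "hand"]


def make_trial_table(rows: Sequence[tuple]) -> pd.DataFrame:
    """Build a validated trial table (reach onsets, pellet touch, outcome)."""
    df = pd.DataFrame(list(rows), columns=_TRIAL_COLUMNS)
    return validate_trial_table(df)


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["reach_onset"] = _round_t(df["reach_onset"])
    df["pellet_touch"] = pd.to_numeric(df["pellet_touch"], errors="coerce")
    ok = df["pellet_touch"].notna()
    df.loc[ok, "pellet_touch"] = _round_t(df.loc[ok, "pellet_touch"])
    if (df.loc[ok, "pellet_touch"] < df.loc[ok, "reach_onset"]).any():
        raise ValueError("pellet_touch must be >= reach_onset")
    if not df["hand"].isin(["L", "R", "X"]).all():
        raise ValueError("hand must be one of L, R, X")
    df["success"] = df["success"].astype(bool)
    return df


_EVENT_COLUMNS = ["kind", "area", "t_onset", "t_peak", "t_end", "amp_peak", "amp_trough"]


def make_event_table(rows: Sequence[dict] | pd.DataFrame | None = None) -> pd.DataFrame:
    """Build a validated oscillation-event table.

    Columns: kind (SO/SPINDLE/SWR), area, t_onset, t_peak, t_end and the
    kind-specific amplitudes (NaN where not applicable). For SOs t_onset is
    the down-state peak time and t_peak the up-state trough time; for
    envelope events t_onset/t_end are the lower-threshold crossings and
    t_peak the envelope maximum.
    """
    if rows is None or (hasattr(rows, "__len__") and len(rows) == 0):
        return pd.DataFrame(columns=_EVENT_COLUMNS).astype(
            {"kind": str, "area": str, "t_onset": float, "t_peak": float,
             "t_end": float, "amp_peak": float, "amp_trough": float}
        )
    df = pd.DataFrame(rows)
    for c in ("amp_peak", "amp_trough"):
        if c not in df:
            df[c] = np.nan
    df = df[_EVENT_COLUMNS]
    return validate_event_table(df)


def validate_event_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if not df["kind"].isin(EVENT_KINDS).all():
        bad = sorted(set(df["kind"]) - set(EVENT_KINDS))
        raise ValueError(f"unknown event kind(s): {bad}")
    if not df["area"].isin(AREAS).all():
        raise ValueError("unknown area in event table")
    for c in ("t_onset", "t_peak", "t_end"):
        df[c] = _round_t(df[c])
    if ((df["t_onset"] > df["t_peak"]) | (df["t_peak"] > df["t_end"])).any():
        raise ValueError("events must satisfy t_onset <= t_peak <= t_end")
    df = df.sort_values("t_onset", kind="stable").reset_index(drop=True)
    return df
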