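"""Event-coupling statistics between sleep oscillations.

Every target event is linked to its nearest reference event (lag = target
minus reference, positive when the target follows); a coupling metric is
the percentage of targets whose lag falls in a stated window, e.g.

* SO-SWR coupling: SWR peaks vs SO up-states, window [-0.75, 0.75] s;
* PFC-M1 SO coupling: M1 SO up-states vs PFC SO up-states, [-0.2, 0.2] s;
* SO-spindle nesting: spindle peaks vs SO up-states, [-0.5, 1.0] s.

Null distributions come from circular permutation of one event train on
NREMS-concatenated time (gaps excised so shuffled events stay in NREMS),
repeated (default) 1,000 times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import IntervalSet

MIN_EVENTS = 10  # below this the metric is flagged undefined, never 0


@dataclass
class LagSet:
    """Signed target-to-nearest-reference lags (one per target event)."""

    lags: np.ndarray
    target_idx: np.ndarray  # index of linked reference per target

    @property
    def n_targets(self) -> int:
        return len(self.lags)


@dataclass
class CouplingSummary:
    metric: str
    value: float | None      # percent, or None when undefined
    window: tuple
    n_events: int
    flagged: bool = False
    note: str = ""


@dataclass
class NullDistribution:
    values: np.ndarray       # percent per rep
    seed: int
    reps: int = field(default=0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.reps = len(self.values)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1))


def nearest_lags(targets, references) -> LagSet:
    """Link each target to its nearest reference; equidistant ties go to the
    earlier reference (yielding a positive lag)."""
    targets = np.asarray(targets, dtype=float)
    references = np.sort(np.asarray(references, dtype=float))
    if len(references) == 0:
        raise ValueError("empty reference set")
    pos = np.searchsorted(references, targets)
    left = np.clip(pos - 1, 0, len(references) - 1)
    right = np.clip(pos, 0, len(references) - 1)
    dl = np.abs(targets - references[left])
    dr = np.abs(targets - references[right])
    # tie -> earlier (left) reference
    use_left = dl <= dr
    idx = np.where(use_left, left, right)
    return LagSet(lags=targets - references[idx], target_idx=idx)


def coupling_fraction(lagset: LagSet, window, metric="coupling") -> CouplingSummary:
    """Percent of lags inside the closed window [lo, hi]."""
    lo, hi = window
    n = lagset.n_targets
    if n == 0:
        return CouplingSummary(metric, None, (lo, hi), 0, flagged=True,
                               note="no target events")
    inside = np.sum((lagset.lags >= lo) & (lagset.lags <= hi))
    flagged = n < MIN_EVENTS
    return CouplingSummary(metric, 100.0 * inside / n, (lo, hi), n,
                           flagged=flagged,
                           note="fewer than %d events" % MIN_EVENTS if flagged else "")


def event_coupling(target_times, reference_times, window, metric="coupling"):
    if len(np.atleast_1d(reference_times)) == 0:
        return CouplingSummary(metric, None, tuple(window), 0, flagged=True,
                               note="no reference events")
    return coupling_fraction(nearest_lags(target_times, reference_times),
                             window, metric)


def so_swr_coupling(swr_peaks, so_upstates, window=(-0.75, 0.75)):
    return event_coupling(swr_peaks, so_upstates, window, "so_swr_coupling")


def pfc_m1_so_coupling(pfc_upstates, m1_upstates, window=(-0.2, 0.2)):
    """Percent of M1 SOs with a PFC SO up-state within +/-0.2 s."""
    return event_coupling(m1_upstates, pfc_upstates, window, "pfc_m1_so_coupling")


def so_spindle_coupling(so_upstates, spindle_peaks, window=(-0.5, 1.0)):
    """Percent of spindles nested in the asymmetric [-0.5, 1.0] s window."""
    return event_coupling(spindle_peaks, so_upstates, window, "so_spindle_coupling")


def delta_coupling(post: CouplingSummary, pre: CouplingSummary) -> float:
    """Post-minus-pre coupling difference in percentage points."""
    if post.value is None or pre.value is None:
        raise ValueError("delta undefined: one side has no metric value")
    return post.value - pre.value


def multi_coupling(swr_peaks, so_upstates, spindle_peaks, mode="triple",
                   pfc_m1_coupled_mask=None, window=(-1.0, 1.0)):
    """Triple (SWR & SO & spindle) or quadruple coupling percentage.

    An SWR counts if at least one SO up-state AND one spindle peak lie
    within the window of its peak; 'quadruple' additionally requires the SO
    to be PFC-M1-coupled (mask aligned with so_upstates).
    """
    swr_peaks = np.asarray(swr_peaks, dtype=float)
    if len(swr_peaks) == 0:
        raise ValueError("empty SWR set")
    sos = np.sort(np.asarray(so_upstates, dtype=float))
    if mode == "quadruple":
        if pfc_m1_coupled_mask is None:
            raise ValueError("quadruple mode requires pfc_m1_coupled_mask")
        order = np.argsort(np.asarray(so_upstates, dtype=float))
        sos = np.asarray(so_upstates, dtype=float)[order]
        sos = sos[np.asarray(pfc_m1_coupled_mask, dtype=bool)[order]]
    elif mode != "triple":
        raise ValueError(f"unknown mode {mode!r}")
    spin = np.sort(np.asarray(spindle_peaks, dtype=float))
    lo, hi = window

    def _has_within(train, t):
        if len(train) == 0:
            return False
        i = np.searchsorted(train, t + lo)
        return i < len(train) and train[i] <= t + hi

    count = sum(1 for t in swr_peaks if _has_within(sos, t) and _has_within(spin, t))
    return CouplingSummary(f"{mode}_coupling", 100.0 * count / len(swr_peaks),
                           (lo, hi), len(swr_peaks))


def circular_shift(times, nrems: IntervalSet, offset) -> np.ndarray:
    """Rotate event times by ``offset`` on NREMS-concatenated time."""
    tc = nrems.to_concat(times)
    return np.sort(nrems.from_concat(tc + offset))


def circular_null(metric_fn, shuffle_times, nrems: IntervalSet, reps=1000,
                  seed=0) -> NullDistribution:
    """Shuffle null: rotate the target train by a uniform offset per rep.

    ``metric_fn(shuffled_times) -> CouplingSummary``; event counts and the
    inter-event-interval multiset are preserved by the rotation.
    """
    shuffle_times = np.asarray(shuffle_times, dtype=float)
    if len(shuffle_times) == 0:
        raise ValueError("empty shuffle train")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    total = nrems.total_duration()
    vals = np.empty(reps)
    for r in range(reps):
        shifted = circular_shift(shuffle_times, nrems, rng.uniform(0, total))
        s = metric_fn(shifted)
        vals[r] = np.nan if s.value is None else s.value
    return NullDistribution(vals, seed=seed)


def subsampled_coupling(pfc_upstates, m1_upstates, n_sub=100, reps=1000,
                        seed=0, window=(-0.2, 0.2)):
    """PFC-M1 coupling recomputed on random subsamples of the PFC SOs.

    Fixed-size subsample (default 100 PFC SOs) drawn without replacement per
    rep; the mean over reps is the reported, rate-controlled coupling.
    """
    pfc = np.asarray(pfc_upstates, dtype=float)
    if len(pfc) < n_sub:
        raise ValueError(
            f"only {len(pfc)} PFC SOs; need >= {n_sub} for subsampling")
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for r in range(reps):
        sub = pfc[rng.choice(len(pfc), size=n_sub, replace=False)]
        s = pfc_m1_so_coupling(sub, m1_upstates, window)
        vals[r] = np.nan if s.value is None else s.value
    return NullDistribution(vals, seed=seed)


@dataclass
class SwrConditionLabels:
    """SWR+ condition splits and the matched SWR- control epochs."""

    swr_onsets: np.ndarray
    so_plus: np.ndarray          # bool per SWR: M1 SO up-state within (0, 1] s
    swr_minus_onsets: np.ndarray  # random NREMS onsets, one per SWR


def label_swr_conditions(swr_onsets, m1_so_upstates, nrems: IntervalSet,
                         seed=0, follow_s=1.0) -> SwrConditionLabels:
    """Split SWRs into SO+ / SO- and draw matched random (SWR-) epochs.

    so_plus is true when an M1 SO up-state falls in (onset, onset+1 s].
    SWR- onsets are uniform over NREMS positions where the whole 1 s epoch
    fits inside a single NREMS interval; their count equals the SWR count.
    """
    swr_onsets = np.asarray(swr_onsets, dtype=float)
    sos = np.sort(np.asarray(m1_so_upstates, dtype=float))
    so_plus = np.zeros(len(swr_onsets), dtype=bool)
    for i, t in enumerate(swr_onsets):
        j = np.searchsorted(sos, t, side="right")
        so_plus[i] = j < len(sos) and sos[j] <= t + follow_s
    eligible = IntervalSet([(s, e - follow_s) for s, e in nrems
                            if e - s > follow_s])
    if eligible.total_duration() <= 0:
        raise ValueError("NREMS too short to place SWR- epochs")
    rng = np.random.default_rng(seed)
    tc = rng.uniform(0, eligible.total_duration(), size=len(swr_onsets))
    minus = np.sort(eligible.from_concat(tc))
    return SwrConditionLabels(swr_onsets, so_plus, minus)


def window_coverage(reference_times, window, nrems: IntervalSet) -> float:
    """Fraction of NREMS time within ``window`` of some reference event.

    This is the chance-coincidence rate c: a uniformly placed target is
    "coupled" with probability c, so an injected coupling probability p is
    observed as p + (1-p)*c.
    """
    lo, hi = window
    covered = []
    for t in np.asarray(reference_times, dtype=float):
        for s, e in nrems:
            a, b = max(s, t + lo), min(e, t + hi)
            if a < b:
                covered.append((a, b))
    if not covered:
        return 0.0
    covered.sort()
    merged = [list(covered[0])]
    for a, b in covered[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    total = sum(b - a for a, b in merged)
    return total / nrems.total_duration()
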