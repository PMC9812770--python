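"""Across-day transition dynamics of coupling/fidelity metrics.

Per-session items (trials or sleep events) are split into tertiles, giving
three samples per day; the 13-day series (39 tertiles) is padded with each
end's 2-day mean, convolved with a Gaussian kernel spanning 9 tertiles
(3 days), min-max normalized per animal, and then summarized by

* a 4-parameter sigmoid fit  L + (U-L) / (1 + exp(-k (x - x_mid))),
* piecewise linear slopes over configured day ranges,
* a single mean-shift change point (exhaustive SSE minimization),
* a moving-window slope scan locating the first abrupt rise, and
* a two-stage logistic model tagged by the per-animal grand-midpoint
  (median of the coupling rise midpoint and the delta-coupling drop
  midpoint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit


@dataclass
class DaySeries:
    """Tertile-resolved metric time course for one animal and metric."""

    metric: str
    days: np.ndarray        # day per sample (1-based, repeated per tertile)
    tertiles: np.ndarray    # 1..3
    values: np.ndarray
    smoothed: np.ndarray | None = None
    normalized: np.ndarray | None = None
    flags: list = field(default_factory=list)

    @property
    def x_days(self) -> np.ndarray:
        """Fractional-day abscissa: tertile k of day d sits at d + (k-2)/3."""
        return self.days + (self.tertiles - 2) / 3.0


def tertile_series(session_items: dict, metric="metric",
                   reducer=None) -> DaySeries:
    """Split each session's time-ordered items into three contiguous thirds.

    ``session_items`` maps day -> 1-d array of per-item values in temporal
    order; ``reducer`` (default mean) turns each third into the tertile
    value. With n items the thirds have sizes n//3, n//3, n - 2*(n//3)
    (remainder goes to the last tertile). Sessions with fewer than 3 items
    replicate the session-level value and are flagged.
    """
    reducer = reducer or np.mean
    days, terts, vals, flags = [], [], [], []
    for day in sorted(session_items):
        items = np.asarray(session_items[day], dtype=float)
        n = len(items)
        if n < 3:
            v = reducer(items) if n else np.nan
            for k in (1, 2, 3):
                days.append(day); terts.append(k); vals.append(v)
            flags.append(f"day {day}: fewer than 3 items, value replicated")
            continue
        third = n // 3
        bounds = [0, third, 2 * third, n]
        for k in (1, 2, 3):
            days.append(day)
            terts.append(k)
            vals.append(reducer(items[bounds[k - 1]:bounds[k]]))
    return DaySeries(metric, np.array(days), np.array(terts),
                     np.array(vals, dtype=float), flags=flags)


def gaussian_kernel(n_taps=9):
    """Unit-sum Gaussian kernel spanning ``n_taps`` tertiles (+/-3 sd)."""
    half = (n_taps - 1) / 2
    sigma = half / 3.0
    x = np.arange(n_taps) - half
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def smooth_normalize(series: DaySeries, kernel_tertiles=9, pad_days=2,
                     tertiles_per_day=3) -> DaySeries:
    """Gaussian smoothing with 2-day-mean edge padding, then min-max scaling."""
    v = series.values
    npad = pad_days * tertiles_per_day
    head = float(np.nanmean(v[:npad]))
    tail = float(np.nanmean(v[-npad:]))
    padded = np.concatenate([np.full(npad, head), v, np.full(npad, tail)])
    k = gaussian_kernel(kernel_tertiles)
    sm_ = np.convolve(padded, k, mode="same")[npad:-npad]
    series.smoothed = sm_
    lo, hi = np.nanmin(sm_), np.nanmax(sm_)
    if hi - lo <= 0:
        series.normalized = np.full_like(sm_, np.nan)
        series.flags.append("constant series: normalization undefined")
    else:
        series.normalized = (sm_ - lo) / (hi - lo)
    return series


# ---------------------------------------------------------------- sigmoid

def sigmoid(x, L, U, x_mid, k):
    return L + (U - L) / (1.0 + np.exp(-k * (x - x_mid)))


@dataclass
class SigmoidFit:
    L: float
    U: float
    x_mid: float
    k: float
    r2: float
    direction: str           # 'rise' or 'drop'
    flagged: bool = False
    note: str = ""

    def predict(self, x):
        return sigmoid(np.asarray(x, dtype=float), self.L, self.U,
                       self.x_mid, self.k)


def fit_sigmoid(x, y, fit_range=None, k_max=20.0, flat_tol=0.05) -> SigmoidFit:
    """Bounded nonlinear least squares with a 1-day multi-start grid on x_mid.

    Bounds: L, U in [-0.5, 1.5], x_mid within the data range, |k| <= k_max.
    A fit whose amplitude or R^2 is negligible is flagged 'no transition'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if fit_range is not None:
        m = (x >= fit_range[0]) & (x <= fit_range[1])
        x, y = x[m], y[m]
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 8:
        raise ValueError("need at least 8 samples in the fit range")
    lo = [-0.5, -0.5, x.min(), -k_max]
    hi = [1.5, 1.5, x.max(), k_max]
    best, best_sse = None, np.inf
    amp0 = y.max() - y.min()
    for x0 in np.arange(np.ceil(x.min()), np.floor(x.max()) + 1):
        for k0 in (2.0, -2.0):
            p0 = [max(y.min(), -0.5), min(y.max(), 1.5), float(x0), k0]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(sigmoid, x, y, p0=p0,
                                        bounds=(lo, hi), maxfev=5000)
            except RuntimeError:
                continue
            sse = float(np.sum((sigmoid(x, *popt) - y) ** 2))
            if sse < best_sse:
                best, best_sse = popt, sse
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from all starts")
    L, U, x_mid, k = map(float, best)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_sse / ss_tot if ss_tot > 0 else 0.0
    rising = (U - L) * k > 0
    amp = abs(U - L)
    flagged = amp < flat_tol * max(amp0, 1e-12) or r2 < 0.1 or amp < 1e-9
    return SigmoidFit(L, U, x_mid, k, r2, "rise" if rising else "drop",
                      flagged=flagged,
                      note="no transition" if flagged else "")


# ---------------------------------------------------------------- scans

def _ols_slope(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    den = np.sum((x - xm) ** 2)
    return float(np.sum((x - xm) * (y - ym)) / den) if den > 0 else 0.0


def transition_scan(series: DaySeries, window_sizes=(3, 4, 5, 6, 7),
                    baseline_days=(1, 4), sd_mult=2.0, use="normalized"):
    """First day whose moving-window slope exceeds the early-days baseline.

    Tertiles are aggregated to per-day means; for each window size w the
    OLS slope is computed over the w-day window ending at each day (clipped
    at the series start so early days still carry a window) and attributed
    to that end day. The baseline distribution is the slopes of the windows
    ending within days 1-4; the detection threshold is baseline
    mean + 2 sd (strict exceedance). The reported transition day must agree
    across window sizes, otherwise the modal day is returned with a
    disagreement flag.
    """
    y = getattr(series, use) if use != "values" else series.values
    if y is None:
        raise ValueError(f"series has no {use} values; run smooth_normalize")
    dmin, dmax = int(series.days.min()), int(series.days.max())
    if dmax - dmin + 1 < max(window_sizes):
        raise ValueError("series shorter than the largest scan window")
    day_range = np.arange(dmin, dmax + 1)
    day_mean = np.array([np.nanmean(y[series.days == d]) for d in day_range])

    def win_slope(d_end, w):
        lo = max(dmin, d_end - w + 1)
        m = (day_range >= lo) & (day_range <= d_end)
        return _ols_slope(day_range[m], day_mean[m])

    per_size = {}
    for w in window_sizes:
        base = [win_slope(d, w)
                for d in range(baseline_days[0] + 1, baseline_days[1] + 1)]
        thr = np.mean(base) + sd_mult * np.std(base)
        day = None
        for d_end in range(baseline_days[1] + 1, dmax + 1):
            if win_slope(d_end, w) > thr + 1e-12:
                day = d_end
                break
        per_size[w] = day
    found = [d for d in per_size.values() if d is not None]
    if not found:
        return None, per_size, ["no transition detected"]
    vals, counts = np.unique(found, return_counts=True)
    modal = int(vals[np.argmax(counts)])
    flags = []
    if len(found) < len(per_size) or len(vals) > 1:
        flags.append(f"window sizes disagree: {per_size}")
    return modal, per_size, flags


@dataclass
class PiecewiseFit:
    segments: list  # (day_lo, day_hi, slope, intercept, n)


def piecewise_slopes(series: DaySeries, breakpoints, truncate_last_at_max=False,
                     use="normalized") -> PiecewiseFit:
    """Independent OLS per contiguous day segment.

    ``breakpoints`` are interior day boundaries: segments are
    [d_min, b1-1], [b1, b2-1], ..., [b_last, d_max]. With
    ``truncate_last_at_max`` the final segment keeps only tertiles up to the
    series argmax (the rising phase, excluding the plateau).
    """
    y = getattr(series, use) if use != "values" else series.values
    x = series.x_days
    edges = [int(series.days.min())] + list(breakpoints) + [int(series.days.max()) + 1]
    segs = []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1] - 1
        m = (series.days >= lo) & (series.days <= hi)
        xs, ys = x[m], y[m]
        if truncate_last_at_max and i == len(edges) - 2 and len(ys):
            kmax = int(np.nanargmax(ys))
            xs, ys = xs[:kmax + 1], ys[:kmax + 1]
        if len(ys) < 3:
            raise ValueError(f"segment days {lo}-{hi} has fewer than 3 samples")
        b = _ols_slope(xs, ys)
        a = float(np.mean(ys) - b * np.mean(xs))
        segs.append((lo, hi, b, a, len(ys)))
    return PiecewiseFit(segs)


@dataclass
class ChangePoint:
    index: int        # 1-based index of the first post-change sample
    pre_mean: float
    post_mean: float
    residual: float
    flagged: bool = False


def change_point(values) -> ChangePoint:
    """Single mean-shift change point by exhaustive SSE minimization.

    Over every split 1 <= i < n the residual is the SSE about the two
    segment means; the minimizing split is returned (earliest index on
    ties) as the 1-based index of the first post-change sample.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 4:
        raise ValueError("series too short for change-point analysis")
    best_i, best_sse = None, np.inf
    for i in range(1, n):
        pre, post = v[:i], v[i:]
        sse = np.sum((pre - pre.mean()) ** 2) + np.sum((post - post.mean()) ** 2)
        if sse < best_sse - 1e-12:
            best_i, best_sse = i, sse
    total = np.sum((v - v.mean()) ** 2)
    return ChangePoint(best_i + 1, float(v[:best_i].mean()),
                       float(v[best_i:].mean()), float(best_sse),
                       flagged=bool(np.isclose(best_sse, total)))


def success_rate_change(daily_rates) -> np.ndarray:
    """Change in success rate vs the mean of the previous two days.

    change(d) = rate(d) - mean(rate(d-2), rate(d-1)); days before day 1
    count as zero history.
    """
    r = np.asarray(daily_rates, dtype=float)
    out = np.empty_like(r)
    for i in range(len(r)):
        h1 = r[i - 1] if i - 1 >= 0 else 0.0
        h2 = r[i - 2] if i - 2 >= 0 else 0.0
        out[i] = r[i] - 0.5 * (h1 + h2)
    return out


# ---------------------------------------------------------------- staging

@dataclass
class StageModel:
    grand_midpoint: dict       # animal -> days
    coefficients: np.ndarray   # (intercept, beta_delta_so_swr, beta_pfc_m1)
    probabilities: np.ndarray  # per-session P(stage II)
    labels: np.ndarray         # per-session stage (1 or 2)
    separated: bool = False


def grand_midpoint(rise_x_mid: float, drop_x_mid: float) -> float:
    """Median of the rise and drop sigmoid midpoints (= their mean for two)."""
    return float(np.median([rise_x_mid, drop_x_mid]))


def stage_model(sessions, midpoints) -> StageModel:
    """Two-stage logistic classification of sessions.

    ``sessions``: iterable of (animal, day, delta_so_swr, pfc_m1_coupling);
    ``midpoints``: animal -> (rise_x_mid, drop_x_mid). Sessions after the
    per-animal grand-midpoint are stage II; a logistic regression of stage
    on the two coupling metrics is fit over all sessions.
    """
    gm = {a: grand_midpoint(r, d) for a, (r, d) in midpoints.items()}
    rows = [(a, day, ds, pm) for a, day, ds, pm in sessions]
    y = np.array([1.0 if day > gm[a] else 0.0 for a, day, _, _ in rows])
    X = np.array([[ds, pm] for _, _, ds, pm in rows], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: all sessions in one stage")
    Xc = sm.add_constant(X)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = np.asarray(res.params)
            if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e4:
                raise RuntimeError("separation")
            proba = np.asarray(res.predict(Xc))
        except Exception:
            separated = True
            res = sm.Logit(y, Xc).fit_regularized(alpha=1.0, disp=0)
            params = np.asarray(res.params)
            proba = np.asarray(res.predict(Xc))
    proba = np.clip(proba, 1e-12, 1 - 1e-12)
    return StageModel(gm, params, proba, (y + 1).astype(int),
                      separated=separated)
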