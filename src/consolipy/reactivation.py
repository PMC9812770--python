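"""SWR-locked population analyses: reactivation and cross-area CCA.

Sleep spike trains around SWR onsets are binned at 15 ms, z-scored with the
awake (task) per-unit statistics, and projected onto the session's top
three GPFA factors (the "template space"). The reactivation correlation R
of an event is the Pearson correlation between the projected sleep
trajectory and the reach template (mean awake trajectory), both resampled
to 100 points per factor. A search over window sizes (75-405 ms, ~0.2-2x
compression) and onset lags (15 ms steps, window end within 405 ms of SWR
onset) finds the best reactivation per event; the fixed comparison uses a
195 ms window at zero lag. Shuffle nulls circularly permute each unit's
binned activity within a -200..400 ms window around the event.

The communication subspace between PFC and M1 is the top canonical pair of
a CCA fit to 1 s post-onset windows concatenated over SWRs; the
cross-area R of a condition is the correlation of the two areas' top-CV
projections over that condition's bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpfa import GpfaModel, TrialTensor, bin_counts, gpfa_correlation


def event_peth(unit_times, event_times, window, bin_s=0.015, normalize=False):
    """Binned counts per event (list of units x bins), optionally per-unit
    z-scored within each event window."""
    mats = bin_counts(unit_times, event_times, window, bin_s)
    if normalize:
        out = []
        for m in mats:
            mu = m.mean(axis=1, keepdims=True)
            sd = m.std(axis=1, keepdims=True)
            out.append((m - mu) / np.where(sd > 0, sd, 1.0))
        return out
    return mats


def reach_template(trajectories) -> np.ndarray:
    """Mean neural trajectory across task trials (bins x factors)."""
    if len(trajectories) == 0:
        raise ValueError("no trials for the reach template")
    return np.mean([np.asarray(t, dtype=float) for t in trajectories], axis=0)


def _project(counts, awake: TrialTensor, basis: np.ndarray) -> np.ndarray:
    """Project binned sleep counts into the awake template space.

    counts: (units x bins); z-scored with the awake per-unit mean/sd, then
    linearly combined with the top-factor basis (units x 3).
    """
    z = (counts - awake.mean[:, None]) / awake.sd[:, None]
    return (basis.T @ z).T           # bins x 3


def template_basis(model: GpfaModel, top=3) -> np.ndarray:
    U, _ = model.orthonormal_basis()
    return U[:, :top]


@dataclass
class ReactivationResult:
    r: np.ndarray            # per event
    window_ms: np.ndarray    # per event
    lag_ms: np.ndarray       # per event


def reactivation_fixed(unit_times, swr_onsets, model, awake: TrialTensor,
                       template, window_s=0.195, bin_s=0.015) -> np.ndarray:
    """Per-event reactivation R in the fixed [onset, onset + 195 ms] window."""
    basis = template_basis(model)
    mats = bin_counts(unit_times, swr_onsets, (0.0, window_s), bin_s)
    out = np.full(len(mats), np.nan)
    for i, m in enumerate(mats):
        proj = _project(m, awake, basis)
        try:
            out[i] = gpfa_correlation(proj, template)
        except ValueError:
            pass  # no spikes in window -> undefined R
    return out


def search_grid(size_lo=0.075, size_hi=0.405, size_step=0.030,
                lag_step=0.015, max_s=0.405):
    """(size, lag) combinations with the window end inside ``max_s``."""
    sizes = np.round(np.arange(size_lo, size_hi + 1e-9, size_step), 6)
    grid = []
    for s in sizes:
        lags = np.round(np.arange(0.0, max_s - s + 1e-9, lag_step), 6)
        for l in lags:
            grid.append((float(s), float(l)))
    return grid


def reactivation_search(unit_times, swr_onsets, model, awake: TrialTensor,
                        template, bin_s=0.015, grid=None) -> ReactivationResult:
    """Best (window size, lag) per SWR by maximal template correlation."""
    if grid is None:
        grid = search_grid()
    basis = template_basis(model)
    swr_onsets = np.asarray(swr_onsets, dtype=float)
    n = len(swr_onsets)
    best_r = np.full(n, -np.inf)
    best_sz = np.full(n, np.nan)
    best_lag = np.full(n, np.nan)
    for size, lag in grid:
        mats = bin_counts(unit_times, swr_onsets + lag, (0.0, size), bin_s)
        for i, m in enumerate(mats):
            proj = _project(m, awake, basis)
            try:
                r = gpfa_correlation(proj, template)
            except ValueError:
                continue
            if r > best_r[i]:
                best_r[i] = r
                best_sz[i] = size
                best_lag[i] = lag
    best_r[~np.isfinite(best_r)] = np.nan
    return ReactivationResult(best_r, best_sz * 1000.0, best_lag * 1000.0)


def _resample_matrix(n_from, n_to=100):
    """Linear-interpolation operator (n_to x n_from)."""
    if n_from == 1:
        return np.ones((n_to, 1))
    xi = np.linspace(0, n_from - 1, n_to)
    lo = np.floor(xi).astype(int)
    hi = np.minimum(lo + 1, n_from - 1)
    w = xi - lo
    L = np.zeros((n_to, n_from))
    L[np.arange(n_to), lo] += 1 - w
    L[np.arange(n_to), hi] += w
    return L


def _batch_r(projs, template, n_points=100):
    """Template correlation (per-factor centered) for a batch of
    (bins x 3) projections; matches gpfa_correlation exactly."""
    n_bins = projs.shape[1]
    L = _resample_matrix(n_bins, n_points)
    from .gpfa import resample_trajectory
    t = resample_trajectory(template, n_points)
    tv = (t - t.mean(axis=0)).ravel(order="F")
    tn = np.linalg.norm(tv)
    res = np.einsum("tb,ebf->etf", L, projs)          # events x n_to x 3
    res = res - res.mean(axis=1, keepdims=True)       # center per factor
    flat = res.transpose(0, 2, 1).reshape(res.shape[0], -1)  # factor-major
    norms = np.linalg.norm(flat, axis=1)
    out = np.full(projs.shape[0], np.nan)
    ok = norms > 0
    out[ok] = (flat[ok] @ tv) / (norms[ok] * tn)
    return out


def reactivation_null(unit_times, swr_onsets, model, awake: TrialTensor,
                      template, seed=0, reps=1000, shuffle_window=(-0.2, 0.4),
                      analysis_window_s=0.195, bin_s=0.015):
    """Shuffle null of the session-mean fixed-window reactivation R.

    Per rep, each unit's binned activity is circularly rotated within the
    shuffle window (independently per unit and event, counts preserved);
    the fixed-window R is recomputed and averaged over events.
    """
    rng = np.random.default_rng(seed)
    basis = template_basis(model)
    mats = bin_counts(unit_times, np.asarray(swr_onsets, dtype=float),
                      shuffle_window, bin_s)
    counts = np.stack(mats)                      # events x units x bins
    n_ev, n_u, n_b = counts.shape
    a0 = int(round((0.0 - shuffle_window[0]) / bin_s))
    a1 = a0 + int(np.floor(analysis_window_s / bin_s + 1e-9))
    z = (counts - awake.mean[None, :, None]) / awake.sd[None, :, None]
    col = np.arange(n_b)
    null_means = np.empty(reps)
    for r_i in range(reps):
        shifts = rng.integers(n_b, size=(n_ev, n_u))
        idx = (col[None, None, :] + shifts[:, :, None]) % n_b
        rolled = np.take_along_axis(z, idx, axis=2)[:, :, a0:a1]
        projs = np.einsum("uf,eub->ebf", basis, rolled)
        rs = _batch_r(projs, template)
        null_means[r_i] = np.nanmean(rs)
    return null_means


# ---------------------------------------------------------------- CCA

@dataclass
class CcaModel:
    wx: np.ndarray           # PFC weights (top CV)
    wy: np.ndarray           # M1 weights
    corr: float              # top canonical correlation
    ridge: float             # regularization applied to within-area covs
    mean_x: np.ndarray
    mean_y: np.ndarray

    def project(self, X, Y):
        """Top-CV projections of (bins x units) data from each area."""
        return (X - self.mean_x) @ self.wx, (Y - self.mean_y) @ self.wy


def fit_cca(X, Y, ridge=None) -> CcaModel:
    """Canonical correlation via whitened cross-covariance SVD.

    X, Y: (bins x units) mean-subtracted internally. A ridge term is added
    to rank-deficient within-area covariances (logged on the model).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("areas must share the time axis")
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise ValueError("need at least 2 units per area")
    if X.shape[0] <= max(X.shape[1], Y.shape[1]):
        raise ValueError("need more bins than units")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    n = X.shape[0] - 1
    Sxx = Xc.T @ Xc / n
    Syy = Yc.T @ Yc / n
    Sxy = Xc.T @ Yc / n
    if ridge is None:
        eps = 0.0
        for S in (Sxx, Syy):
            w = np.linalg.eigvalsh(S)
            if w.min() <= 1e-10 * max(w.max(), 1e-30):
                eps = max(eps, 1e-6 * np.trace(S) / S.shape[0])
        ridge = eps
    if ridge > 0:
        Sxx = Sxx + ridge * np.eye(Sxx.shape[0])
        Syy = Syy + ridge * np.eye(Syy.shape[0])
    Lx = np.linalg.cholesky(Sxx)
    Ly = np.linalg.cholesky(Syy)
    Mw = np.linalg.solve(Lx, Sxy) @ np.linalg.inv(Ly).T
    U, s, Vt = np.linalg.svd(Mw)
    wx = np.linalg.solve(Lx.T, U[:, 0])
    wy = np.linalg.solve(Ly.T, Vt[0])
    # sign convention: first nonzero PFC weight positive
    nz = np.nonzero(np.abs(wx) > 1e-12)[0]
    if len(nz) and wx[nz[0]] < 0:
        wx, wy = -wx, -wy
    return CcaModel(wx, wy, float(min(s[0], 1.0)), float(ridge), mx, my)


def cca_event_matrix(unit_times, swr_onsets, window_s=1.0, bin_s=0.015):
    """Concatenated (bins x units) count matrix over 1 s post-onset windows."""
    mats = bin_counts(unit_times, swr_onsets, (0.0, window_s), bin_s)
    return np.concatenate([m.T for m in mats], axis=0)


def cross_area_r(model: CcaModel, X_cond, Y_cond, min_bins=5) -> float:
    """Pearson correlation of the two areas' top-CV projections."""
    px, py = model.project(X_cond, Y_cond)
    if len(px) < min_bins or px.std() == 0 or py.std() == 0:
        raise ValueError("condition too small or degenerate for cross-area R")
    return float(np.corrcoef(px, py)[0, 1])


def delta_cross_area_r(model: CcaModel, so_plus_data, so_minus_data) -> float:
    """R(SWR+SO+) - R(SWR+SO-) on the shared top CV."""
    r_plus = cross_area_r(model, *so_plus_data)
    r_minus = cross_area_r(model, *so_minus_data)
    return r_plus - r_minus
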