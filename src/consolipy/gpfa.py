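"""Gaussian-process factor analysis of trial-locked population spiking.

The observation model per 15 ms bin is

    y_t = C x_t + d + eps,   eps ~ N(0, R)  (R diagonal, private noise)

with each latent x_i an independent zero-mean GP over bins with a squared-
exponential kernel K_i(dt) = (1 - s_n) exp(-dt^2 / (2 tau_i^2)) + s_n delta
(unit marginal variance; s_n a small fixed innovation-noise fraction). The
model is fit by EM (factor-analysis initialization, timescales optimized in
the M step); the marginal log-likelihood is non-decreasing across
iterations. Latents are reported in the orthonormalized basis of C ordered
by explained shared variance; the top three factors define the manifold
used for trajectories, templates and reactivation projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.linalg import orthogonal_procrustes
from scipy.optimize import minimize_scalar
from sklearn.decomposition import FactorAnalysis


# ---------------------------------------------------------------- binning

@dataclass
class TrialTensor:
    """Binned, z-scored spike counts per trial (units x bins, 15 ms bins)."""

    counts: list                 # raw counts per trial, (n_units, n_bins)
    z: list                      # z-scored counts per trial
    unit_ids: list
    mean: np.ndarray             # per-unit mean of concatenated counts
    sd: np.ndarray
    bin_s: float
    window: tuple                # (lo, hi) s relative to the alignment event
    excluded: list = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_bins(self) -> int:
        return self.counts[0].shape[1] if self.counts else 0

    @property
    def n_trials(self) -> int:
        return len(self.counts)


def bin_counts(unit_times, event_times, window, bin_s=0.015) -> list:
    """Raw per-event count matrices (units x bins); partial last bin dropped."""
    lo, hi = window
    n_bins = int(np.floor((hi - lo) / bin_s + 1e-9))
    edges = lo + np.arange(n_bins + 1) * bin_s
    out = []
    for t0 in np.asarray(event_times, dtype=float):
        m = np.empty((len(unit_times), n_bins))
        for u, st in enumerate(unit_times):
            m[u] = np.histogram(st - t0, bins=edges)[0]
        out.append(m)
    return out


def bin_zscore(unit_times, unit_ids, event_times, window, bin_s=0.015,
               min_rate_hz=0.0) -> TrialTensor:
    """Bin and z-score using concatenated-trial statistics per unit.

    Units with zero concatenated variance (or mean rate below
    ``min_rate_hz`` in-window) are excluded with a warning.
    """
    if len(event_times) == 0:
        raise ValueError("no trials to bin")
    if window[1] <= window[0]:
        raise ValueError("empty analysis window")
    counts = bin_counts(unit_times, event_times, window, bin_s)
    concat = np.concatenate(counts, axis=1)
    mean = concat.mean(axis=1)
    sd = concat.std(axis=1)
    rate = mean / bin_s
    keep = (sd > 0) & (rate >= min_rate_hz)
    excluded = [uid for uid, k in zip(unit_ids, keep) if not k]
    if excluded:
        warnings.warn(f"excluding {len(excluded)} unit(s) with degenerate "
                      f"or sub-threshold rates: {excluded}")
    if not np.any(keep):
        raise ValueError("no units left after exclusion")
    mean, sd = mean[keep], sd[keep]
    counts = [c[keep] for c in counts]
    z = [(c - mean[:, None]) / sd[:, None] for c in counts]
    return TrialTensor(counts, z, [u for u, k in zip(unit_ids, keep) if k],
                       mean, sd, bin_s, tuple(window), excluded)


# ---------------------------------------------------------------- model

@dataclass
class GpfaModel:
    C: np.ndarray            # loadings, units x q
    d: np.ndarray            # per-unit mean
    R: np.ndarray            # private noise variances (diagonal entries)
    tau: np.ndarray          # per-latent GP timescale (s)
    gp_noise_frac: float
    bin_s: float
    unit_ids: list
    loglik_trace: np.ndarray = None
    converged: bool = False

    @property
    def q(self) -> int:
        return self.C.shape[1]

    def orthonormal_basis(self):
        """SVD of C: returns (U_orth, transform) with x_orth = transform @ x.

        Columns of U_orth are ordered by explained shared variance
        (descending singular values of C).
        """
        U, s, Vt = np.linalg.svd(self.C, full_matrices=False)
        return U, s[:, None] * Vt

    def shared_over_total(self) -> float:
        """tr(C C') / (tr(C C') + tr(R)); latents have unit variance."""
        shared = float(np.sum(self.C ** 2))
        return shared / (shared + float(np.sum(self.R)))

    def shared_variance_fractions(self) -> np.ndarray:
        _, s, _ = np.linalg.svd(self.C, full_matrices=False)
        return s ** 2 / np.sum(s ** 2)


def _gp_K(T, tau_bins, noise_frac):
    dt = np.arange(T)[:, None] - np.arange(T)[None, :]
    K = (1.0 - noise_frac) * np.exp(-0.5 * (dt / tau_bins) ** 2)
    K[np.diag_indices(T)] += noise_frac
    return K


def _big_K(T, q, tau_bins, noise_frac):
    """qT x qT latent prior covariance, time-major ordering (t*q + i)."""
    Kbig = np.zeros((q * T, q * T))
    for i in range(q):
        Ki = _gp_K(T, tau_bins[i], noise_frac)
        Kbig[i::q, i::q] = Ki
    return Kbig


def _posterior(model: GpfaModel, Ys, T):
    """Shared posterior machinery: returns (Sigma_x, mus, loglik).

    Ys: list of (N, T) observations. Latents are stacked time-major.
    """
    C, d, R = model.C, model.d, model.R
    q, N = model.q, C.shape[0]
    tau_bins = model.tau / model.bin_s
    Kbig = _big_K(T, q, tau_bins, model.gp_noise_frac)
    Kinv_chol = linalg.cho_factor(Kbig, lower=True)
    Kinv = linalg.cho_solve(Kinv_chol, np.eye(q * T))
    logdet_K = 2.0 * np.sum(np.log(np.diag(Kinv_chol[0])))
    A = (C / R[:, None]).T @ C                      # C' R^-1 C
    M = Kinv.copy()
    for t in range(T):
        M[t * q:(t + 1) * q, t * q:(t + 1) * q] += A
    M_chol = linalg.cho_factor(M, lower=True)
    logdet_M = 2.0 * np.sum(np.log(np.diag(M_chol[0])))
    Sigma_x = linalg.cho_solve(M_chol, np.eye(q * T))
    CtRi = (C / R[:, None]).T                       # q x N
    mus, ll = [], 0.0
    log2pi = np.log(2 * np.pi)
    sum_logR = float(np.sum(np.log(R)))
    for Y in Ys:
        Yc = Y - d[:, None]
        b = (CtRi @ Yc).T.reshape(-1)               # time-major qT
        mu = Sigma_x @ b
        mus.append(mu.reshape(T, q))
        quad = float(np.sum(Yc * Yc / R[:, None])) - float(b @ mu)
        ll += -0.5 * (N * T * log2pi + logdet_K + T * sum_logR
                      + logdet_M + quad)
    return Sigma_x, mus, ll


def _optimize_tau(Sigma_x, mus, q, T, tau_bins, noise_frac):
    """Per-latent timescale update (generalized M step, never worsening)."""
    n = len(mus)
    new = tau_bins.copy()
    for i in range(q):
        idx = np.arange(T) * q + i
        S = n * Sigma_x[np.ix_(idx, idx)]
        for mu in mus:
            S += np.outer(mu[:, i], mu[:, i])

        def nll(log_tau):
            K = _gp_K(T, np.exp(log_tau), noise_frac)
            try:
                ch = linalg.cho_factor(K, lower=True)
            except linalg.LinAlgError:
                return np.inf
            logdet = 2.0 * np.sum(np.log(np.diag(ch[0])))
            return n * logdet + float(np.trace(linalg.cho_solve(ch, S)))

        cur = nll(np.log(tau_bins[i]))
        res = minimize_scalar(nll, bounds=(np.log(0.5), np.log(10.0 * T)),
                              method="bounded",
                              options={"xatol": 1e-3})
        if res.success and res.fun < cur:
            new[i] = np.exp(res.x)
    return new


def fit_gpfa(tensor: TrialTensor, q, tol=1e-6, max_iter=500, seed=0,
             gp_noise_frac=1e-3, tau_init_s=0.1, update_tau=True) -> GpfaModel:
    """EM fit of the GPFA model to z-scored trial tensors.

    q = 0 degenerates to an independent diagonal-Gaussian fit. The returned
    model carries the marginal log-likelihood trace (non-decreasing).
    """
    Ys = tensor.z
    if len(Ys) == 0:
        raise ValueError("no trials")
    N, T = Ys[0].shape
    if q >= N:
        raise ValueError("latent dimensionality must be below the unit count")
    Yall = np.concatenate(Ys, axis=1)
    if q == 0:
        d = Yall.mean(axis=1)
        R = np.maximum(Yall.var(axis=1), 1e-6)
        ll = float(np.sum(
            -0.5 * (np.log(2 * np.pi * R)[:, None]
                    + (Yall - d[:, None]) ** 2 / R[:, None])))
        return GpfaModel(np.zeros((N, 0)), d, R, np.zeros(0), gp_noise_frac,
                         tensor.bin_s, tensor.unit_ids,
                         loglik_trace=np.array([ll]), converged=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = FactorAnalysis(n_components=q, random_state=seed, max_iter=500)
        fa.fit(Yall.T)
    C = fa.components_.T.copy()
    d = Yall.mean(axis=1)
    R = np.maximum(fa.noise_variance_.copy(), 1e-6)
    tau = np.full(q, tau_init_s)
    model = GpfaModel(C, d, R, tau, gp_noise_frac, tensor.bin_s,
                      tensor.unit_ids)
    trace = []
    prev = -np.inf
    for it in range(max_iter):
        Sigma_x, mus, ll = _posterior(model, Ys, T)
        trace.append(ll)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite GPFA log-likelihood")
        if it > 0 and abs(ll - prev) < tol * abs(prev):
            model.converged = True
            break
        prev = ll
        # --- M step: loadings/mean/noise (closed form)
        n_total = len(Ys) * T
        # second moments of latents summed over trials and bins
        Sxx = np.zeros((q, q))
        for t in range(T):
            Sxx += len(Ys) * Sigma_x[t * q:(t + 1) * q, t * q:(t + 1) * q]
        Ex_sum = np.zeros(q)
        H = np.zeros((N, q + 1))
        for Y, mu in zip(Ys, mus):
            Sxx += mu.T @ mu
            Ex_sum += mu.sum(axis=0)
            H[:, :q] += Y @ mu
            H[:, q] += Y.sum(axis=1)
        G = np.empty((q + 1, q + 1))
        G[:q, :q] = Sxx
        G[:q, q] = Ex_sum
        G[q, :q] = Ex_sum
        G[q, q] = n_total
        Cd = np.linalg.solve(G.T, H.T).T
        C_new, d_new = Cd[:, :q], Cd[:, q]
        Syy_diag = np.sum(Yall ** 2, axis=1)
        R_new = np.maximum((Syy_diag - np.sum(Cd * H, axis=1)) / n_total, 1e-6)
        model.C, model.d, model.R = C_new, d_new, R_new
        if update_tau:
            tau_bins = _optimize_tau(Sigma_x, mus, q, T,
                                     model.tau / model.bin_s, gp_noise_frac)
            model.tau = tau_bins * model.bin_s
    model.loglik_trace = np.array(trace)
    return model


def sample_gpfa(model: GpfaModel, n_trials, T, seed=0):
    """Draw trials from the generative model (GP latents + private noise).

    Returns (Ys, Xs): observations (N, T) and latent paths (T, q) per trial.
    """
    rng = np.random.default_rng(seed)
    q = model.q
    tau_bins = model.tau / model.bin_s
    Ys, Xs = [], []
    Ls = [np.linalg.cholesky(_gp_K(T, tau_bins[i], model.gp_noise_frac))
          for i in range(q)]
    for _ in range(n_trials):
        X = np.column_stack([L @ rng.standard_normal(T) for L in Ls])
        noise = rng.standard_normal((model.C.shape[0], T)) * np.sqrt(model.R)[:, None]
        Ys.append(model.C @ X.T + model.d[:, None] + noise)
        Xs.append(X)
    return Ys, Xs


def tensor_from_arrays(Ys, bin_s=0.015, window=None):
    """Wrap pre-binned observation arrays as a TrialTensor (already scaled)."""
    N = Ys[0].shape[0]
    ids = [f"u{i:02d}" for i in range(N)]
    mean = np.zeros(N)
    sd = np.ones(N)
    win = window or (0.0, Ys[0].shape[1] * bin_s)
    return TrialTensor([Y.copy() for Y in Ys], [Y.copy() for Y in Ys], ids,
                       mean, sd, bin_s, tuple(win))


def infer_latents(model: GpfaModel, Ys):
    """Posterior-mean latent paths, one (T, q) array per trial."""
    T = Ys[0].shape[1]
    _, mus, _ = _posterior(model, Ys, T)
    return mus


def _fold_tensors(tensor: TrialTensor, cv_folds):
    """Deterministic contiguous trial folds -> (train_tensor, test_trials)."""
    n = tensor.n_trials
    bounds = np.linspace(0, n, cv_folds + 1).astype(int)
    for f in range(cv_folds):
        test_idx = np.arange(bounds[f], bounds[f + 1])
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train = TrialTensor([tensor.counts[i] for i in train_idx],
                            [tensor.z[i] for i in train_idx],
                            tensor.unit_ids, tensor.mean, tensor.sd,
                            tensor.bin_s, tensor.window)
        yield train, [tensor.z[i] for i in test_idx]


def select_dim(tensor: TrialTensor, candidates, seed=0, tol=1e-5,
               max_iter=200, cv_folds=4):
    """Leave-neuron-out dimensionality selection with trial-fold CV.

    For each candidate q the model is fit on the training trials of each
    fold; on the held-out trials each unit is predicted from the latents
    inferred from the remaining units. The summed squared prediction error
    over folds and units picks q*.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    if len(candidates) == 1:
        return candidates[0], {}
    errors = {q: 0.0 for q in candidates}
    for train, test in _fold_tensors(tensor, cv_folds):
        for q in candidates:
            model = fit_gpfa(train, q, tol=tol, max_iter=max_iter, seed=seed)
            errors[q] += leave_neuron_out_error(model, test)
    q_star = min(errors, key=lambda q: errors[q])
    return q_star, errors


def leave_neuron_out_error(model: GpfaModel, data) -> float:
    Ys = data.z if isinstance(data, TrialTensor) else data
    N, T = Ys[0].shape
    q = model.q
    if q == 0:
        return float(sum(np.sum((Y - model.d[:, None]) ** 2) for Y in Ys))
    tau_bins = model.tau / model.bin_s
    Kbig = _big_K(T, q, tau_bins, model.gp_noise_frac)
    Kinv = np.linalg.inv(Kbig)
    err = 0.0
    for i in range(N):
        keep = np.arange(N) != i
        C_, R_ = model.C[keep], model.R[keep]
        d_ = model.d[keep]
        A = (C_ / R_[:, None]).T @ C_
        M = Kinv.copy()
        for t in range(T):
            M[t * q:(t + 1) * q, t * q:(t + 1) * q] += A
        M_chol = linalg.cho_factor(M, lower=True)
        CtRi = (C_ / R_[:, None]).T
        for Y in Ys:
            b = (CtRi @ (Y[keep] - d_[:, None])).T.reshape(-1)
            mu = linalg.cho_solve(M_chol, b).reshape(T, q)
            pred = model.C[i] @ mu.T + model.d[i]
            err += float(np.sum((Y[i] - pred) ** 2))
    return err


# ---------------------------------------------------------------- trajectories

def extract_trajectories(model: GpfaModel, tensor: TrialTensor, top=3):
    """Orthonormalized posterior trajectories (top factors) per trial.

    Returns (trajectories, shared_fractions, shared_over_total) where each
    trajectory is (T, top) and shared_fractions are the per-factor shared-
    variance fractions of the full model.
    """
    if model.C.shape[0] != tensor.n_units:
        raise ValueError("model and tensor unit counts differ")
    mus = infer_latents(model, tensor.z)
    _, transform = model.orthonormal_basis()
    top = min(top, model.q)
    trajs = [(transform @ mu.T).T[:, :top] for mu in mus]
    return trajs, model.shared_variance_fractions(), model.shared_over_total()


def procrustes_transform(reference, data, scaling=True):
    """MATLAB-style Procrustes: map ``data`` onto ``reference``.

    Returns (Z, transform, disparity) with Z = b * data @ T + c and
    disparity the normalized SSE between Z and the reference.
    """
    X = np.asarray(reference, dtype=float)
    Y = np.asarray(data, dtype=float)
    muX, muY = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - muX, Y - muY
    normX = np.linalg.norm(X0)
    normY = np.linalg.norm(Y0)
    if normX == 0 or normY == 0:
        raise ValueError("degenerate (constant) trajectory in Procrustes")
    Rmat, s = orthogonal_procrustes(Y0 / normY, X0 / normX)
    b = s * normX / normY if scaling else 1.0
    Z = b * Y0 @ Rmat + muX
    disparity = float(np.sum((Z - X) ** 2) / normX ** 2)
    return Z, {"rotation": Rmat, "scale": b, "t_ref": muX, "t_day": muY}, disparity


def apply_procrustes(traj, tf):
    return tf["scale"] * (np.asarray(traj, dtype=float) - tf["t_day"]) @ tf["rotation"] + tf["t_ref"]


def align_days(day_mean_trajs: dict, final_days=3, scaling=True):
    """Procrustes-align each day's manifold to the mean of the final days.

    ``day_mean_trajs`` maps day -> mean trajectory (T, 3) resampled to a
    common length. Returns (transforms, disparities, reference).
    """
    days = sorted(day_mean_trajs)
    if len(days) < final_days:
        raise ValueError(f"need at least {final_days} days for the reference")
    ref = np.mean([day_mean_trajs[d] for d in days[-final_days:]], axis=0)
    tfs, disp = {}, {}
    for d in days:
        _, tf, ds = procrustes_transform(ref, day_mean_trajs[d], scaling=scaling)
        tfs[d] = tf
        disp[d] = ds
    return tfs, disp, ref


def resample_trajectory(traj, n_points=100):
    """Linear per-factor resampling to a fixed number of samples."""
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    if traj.shape[0] == 1 and traj.shape[1] > 3:
        traj = traj.T
    T = traj.shape[0]
    if T == 1:
        return np.repeat(traj, n_points, axis=0)
    xi = np.linspace(0, T - 1, n_points)
    return np.column_stack([np.interp(xi, np.arange(T), traj[:, j])
                            for j in range(traj.shape[1])])


def gpfa_correlation(trajectory, template, n_points=100) -> float:
    """Correlation with the optimal template.

    Both paths are linearly resampled to ``n_points`` per factor; each
    factor is mean-centered and the correlation is taken over the
    concatenated factors (this makes the measure invariant to a common
    rotation of trajectory and template).
    """
    a = resample_trajectory(trajectory, n_points)
    b = resample_trajectory(template, n_points)
    a = (a - a.mean(axis=0)).ravel(order="F")
    b = (b - b.mean(axis=0)).ravel(order="F")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance trajectory")
    return float(a @ b / (na * nb))


@dataclass
class FidelityResult:
    mean_r: float
    sd_r: float
    fidelity: float
    n_trials: int


def fidelity(r_values) -> FidelityResult:
    """Trajectory fidelity: mean over sd of the GPFA correlations."""
    r = np.asarray(r_values, dtype=float)
    if len(r) < 3:
        raise ValueError("need at least 3 trials for fidelity")
    sd = float(np.std(r, ddof=1))
    if sd == 0:
        raise ValueError("zero dispersion: fidelity undefined")
    return FidelityResult(float(np.mean(r)), sd, float(np.mean(r)) / sd, len(r))


def spike_shuffle_surrogate(unit_times, event_times, window, seed=0):
    """Circular permutation of spike times within per-event windows.

    Each unit's spikes inside [event + lo, event + hi) are rotated by an
    independent uniform offset (modulo the window length) per unit and
    event; per-unit counts are preserved exactly.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty shuffle window")
    width = hi - lo
    rng = np.random.default_rng(seed)
    out = []
    events = np.asarray(event_times, dtype=float)
    for st in unit_times:
        st = np.asarray(st, dtype=float)
        new = st.copy()
        for t0 in events:
            m = (st >= t0 + lo) & (st < t0 + hi)
            if not np.any(m):
                rng.uniform()  # keep stream alignment unit x event
                continue
            off = rng.uniform(0, width)
            new[m] = t0 + lo + np.mod(st[m] - (t0 + lo) + off, width)
        out.append(np.sort(new))
    return out
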