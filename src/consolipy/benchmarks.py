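"""Recovery and calibration studies on the synthetic generator.

Each function simulates data at the generator's default study conditions,
runs the corresponding pipeline stage from scratch and measures how well
the known ground truth is recovered. These are the quantitative checks
behind the package's validation suite; problem sizes are chosen so each
study runs in minutes on one core (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.linalg import subspace_angles

from . import coupling as cpl
from . import detect, dynamics as dyn, gpfa, io, reactivation as rx, staging
from . import study as study_mod
from . import synth


def _spawn(seed, n):
    """Independent child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _match_f1(detected, truth, tol=0.1):
    det = np.sort(np.asarray(detected, dtype=float))
    true = np.sort(np.asarray(truth, dtype=float))
    used = np.zeros(len(det), bool)
    tp = 0
    for t in true:
        if not len(det):
            break
        d = np.abs(det - t)
        i = int(np.argmin(np.where(used, np.inf, d)))
        if not used[i] and d[i] < tol:
            used[i] = True
            tp += 1
    prec = tp / len(det) if len(det) else 0.0
    rec = tp / len(true) if len(true) else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def detector_recovery(seed=0, nrems_minutes=30.0):
    """Detector F1 against ground truth on one long synthetic sleep block.

    The block length is chosen so the NREMS total is about
    ``nrems_minutes``; staging runs first, so the measured F1 includes
    staging imperfections.
    """
    cfg = synth.SimConfig(sleep_block_s=nrems_minutes * 60.0 / 0.86)
    recs, gt = synth.simulate_sleep_block(cfg, seed=seed)
    trace = detect.make_trace(recs["M1"])
    nrems = staging.stage_block(trace, cfg.rate, seed=seed)
    tables = detect.detect_block(recs, nrems, io.DEFAULT_CONFIG)
    return {
        "f1_so": _match_f1(tables[("SO", "M1")].t_peak, gt.so_up["M1"]),
        "f1_swr": _match_f1(tables[("SWR", "HPC")].t_peak, gt.swr_peak),
        "f1_spindle": _match_f1(tables[("SPINDLE", "M1")].t_peak,
                                gt.spindle_peak["M1"]),
        "n_so_true": len(gt.so_up["M1"]),
        "n_swr_true": len(gt.swr_peak),
        "n_spindle_true": len(gt.spindle_peak["M1"]),
        "nrems_minutes": nrems.total_duration() / 60.0,
    }


def coupling_calibration(seed=0, probabilities=(0.2, 0.5, 0.8), reps=200,
                         n_events=500):
    """Bias of the coupling estimator versus p + (1-p)*c.

    Event trains with ``n_events`` reference SOs are simulated per rep; the
    chance-coincidence rate c is the realized window coverage of the
    reference train.
    """
    cfg = synth.SimConfig()
    duration = n_events / 0.19  # realized event-path SO rate
    out = {}
    seeds = _spawn(seed, reps * len(probabilities))
    k = 0
    for p in probabilities:
        errs = []
        for _ in range(reps):
            gt = synth.simulate_event_trains(cfg, seed=seeds[k],
                                             duration_s=duration, p_pfc_m1=p)
            k += 1
            est = cpl.pfc_m1_so_coupling(gt.so_up["PFC"],
                                         gt.so_up["M1"]).value
            c = cpl.window_coverage(gt.so_up["PFC"], (-0.2, 0.2), gt.nrems)
            errs.append(est - 100.0 * (p + (1 - p) * c))
        out[p] = abs(float(np.mean(errs)))
    return out


def null_correctness(seed=0, reps=1000):
    """Circular-permutation null mean versus analytic window coverage."""
    from .types import IntervalSet

    # analytic single-event case: 1 SO, 1 SWR, 100 s, +/-0.75 s -> 1.5 %
    nrems = IntervalSet([(0.0, 100.0)])
    so = np.array([50.0])
    null = cpl.circular_null(lambda s: cpl.so_swr_coupling(s, so),
                             np.array([20.0]), nrems, reps=reps, seed=seed)
    se_single = np.sqrt(1.5 * 98.5 / reps)
    # random multi-event configuration vs realized coverage
    rng = np.random.default_rng(seed)
    nrems2 = IntervalSet([(0, 300), (400, 600)])
    so2 = np.sort(nrems2.from_concat(rng.uniform(0, 500, 40)))
    swr2 = np.sort(nrems2.from_concat(rng.uniform(0, 500, 60)))
    null2 = cpl.circular_null(lambda s: cpl.so_swr_coupling(s, so2),
                              swr2, nrems2, reps=reps, seed=seed + 1)
    cov2 = 100.0 * cpl.window_coverage(so2, (-0.75, 0.75), nrems2)
    return {
        "single_null_mean": null.mean,
        "single_analytic": 1.5,
        "single_err_se": abs(null.mean - 1.5) / se_single,
        "multi_null_mean": null2.mean,
        "multi_coverage": cov2,
        "multi_err_se": abs(null2.mean - cov2)
                        / max(null2.sd / np.sqrt(reps), 1e-9),
    }


def transition_recovery(seed=0, noisy_reps=200, study_reps=50,
                        cp_series=50):
    """Sigmoid midpoint and change-point recovery."""
    x = np.repeat(np.arange(1, 14), 3) + np.tile([-1 / 3, 0, 1 / 3], 13)
    y = dyn.sigmoid(x, 0.0, 1.0, 6.5, 2.0)
    noiseless_err = abs(dyn.fit_sigmoid(x, y).x_mid - 6.5)

    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(noisy_reps):
        yn = y + rng.normal(0, 0.1, len(y))
        errs.append(abs(dyn.fit_sigmoid(x, yn).x_mid - 6.5))
    noisy_median = float(np.median(errs))

    cp_ok = 0
    for _ in range(cp_series):
        n = rng.integers(4, 51)
        v = rng.normal(size=n)
        cp = dyn.change_point(v)
        sses = [np.var(v[:i]) * i + np.var(v[i:]) * (n - i)
                for i in range(1, n)]
        cp_ok += np.isclose(cp.residual, min(sses), atol=1e-9)

    cfg = synth.SimConfig(sleep_block_s=900.0)
    order_ok = 0
    for s in _spawn(seed, study_reps):
        days = synth.simulate_study(cfg, seed=s, n_days=13, lfp=False,
                                    spiking=False)
        rec = study_mod.recover_transitions(
            study_mod.events_from_ground_truth(days))
        order_ok += rec["rise_fit"].x_mid < rec["drop_fit"].x_mid
    return {
        "noiseless_xmid_err_days": float(noiseless_err),
        "noisy_xmid_median_err_days": noisy_median,
        "changepoint_bruteforce_agreement": cp_ok / cp_series,
        "rise_before_drop_fraction": order_ok / study_reps,
    }


def gpfa_recovery(seed=0, n_units=30, n_trials=100, T=40, select_reps=20):
    """Subspace-angle recovery, EM monotonicity, dimensionality selection."""
    seeds = _spawn(seed, select_reps + 2)
    rng = np.random.default_rng(seeds[0])
    C = rng.normal(size=(n_units, 3))
    C, _ = np.linalg.qr(C)
    C *= 2.0
    true = gpfa.GpfaModel(C, rng.normal(0, 0.2, n_units),
                          np.full(n_units, 1.0),
                          np.array([0.08, 0.12, 0.2]), 1e-3, 0.015,
                          [f"u{i}" for i in range(n_units)])
    Ys, _ = gpfa.sample_gpfa(true, n_trials, T, seed=seeds[1])
    model = gpfa.fit_gpfa(gpfa.tensor_from_arrays(Ys), 3, max_iter=150)
    angle = float(np.rad2deg(subspace_angles(model.C, C)).max())
    ll = model.loglik_trace
    monotone = bool(np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1])))

    # dimensionality selection: mode over smaller replicates
    q_hats = []
    for s in seeds[2:]:
        rng_r = np.random.default_rng(s)
        Cr = rng_r.normal(size=(25, 3))
        Cr, _ = np.linalg.qr(Cr)
        Cr *= 2.0
        tm = gpfa.GpfaModel(Cr, np.zeros(25), np.full(25, 1.0),
                            np.array([0.08, 0.12, 0.2]), 1e-3, 0.015,
                            [f"u{i}" for i in range(25)])
        Yr, _ = gpfa.sample_gpfa(tm, 40, 30, seed=s + 1)
        q, _ = gpfa.select_dim(gpfa.tensor_from_arrays(Yr),
                               [1, 2, 3, 4, 5, 6], max_iter=60, cv_folds=2)
        q_hats.append(q)
    vals, counts = np.unique(q_hats, return_counts=True)
    return {
        "subspace_angle_deg": angle,
        "loglik_monotone": monotone,
        "selected_dim_mode": int(vals[np.argmax(counts)]),
        "selected_dims": q_hats,
    }


def fidelity_ladder(seed=0, noise_levels=(0.1, 0.3, 0.5, 0.8, 1.2),
                    n_trials=40):
    """Trajectory fidelity across increasing latent-noise levels."""
    cfg = synth.SimConfig(n_trials=n_trials)
    fids = []
    for sd in noise_levels:
        spikes, trials, _ = synth.simulate_training_block(
            cfg, seed=seed, latent_noise_sd=sd)
        tensor = gpfa.bin_zscore([t for _, _, t in spikes.units],
                                 spikes.unit_ids,
                                 trials["reach_onset"].to_numpy(),
                                 cfg.trial_window_s)
        model = gpfa.fit_gpfa(tensor, 3, max_iter=60, tol=1e-5)
        trajs, _, _ = gpfa.extract_trajectories(model, tensor)
        tmpl = rx.reach_template(trajs)
        rs = [gpfa.gpfa_correlation(t, tmpl) for t in trajs]
        fids.append(gpfa.fidelity(rs).fidelity)
    return {"noise_levels": list(noise_levels), "fidelities": fids,
            "strictly_decreasing": bool(np.all(np.diff(fids) < 0))}


def _reactivation_session(cfg, seed, n_swr=200, fraction=0.3,
                          compression=None):
    """One awake-fit + sleep-replay session; returns everything needed."""
    s_train, s_sleep, s_replay = _spawn(seed, 3)
    spikes, trials, gt = synth.simulate_training_block(cfg, seed=s_train)
    tensor = gpfa.bin_zscore([t for _, _, t in spikes.units],
                             spikes.unit_ids,
                             trials["reach_onset"].to_numpy(),
                             cfg.trial_window_s)
    model = gpfa.fit_gpfa(tensor, 3, max_iter=50, tol=1e-5)
    trajs, _, _ = gpfa.extract_trajectories(model, tensor)
    template = rx.reach_template(trajs)
    t0 = 3000.0
    onsets = t0 + 5.0 + np.arange(n_swr) * 3.0
    sleep = synth.simulate_sleep_spikes(cfg, s_sleep, t0, n_swr * 3.0 + 15.0)
    sleep, tags = synth.inject_replay(sleep, onsets, gt["template"],
                                      gt["loadings"], cfg, s_replay,
                                      fraction=fraction,
                                      compression=compression)
    ut = [t for (uid, _, t) in sleep.units if uid in tensor.unit_ids]
    return dict(model=model, tensor=tensor, template=template, ut=ut,
                onsets=onsets, tags=tags)


def reactivation_power(seed=0, reps=50, n_swr=200, fraction=0.3,
                       null_reps=100):
    """Power to detect replay (SWR+ mean R above the shuffle-null 97.5th
    percentile) and modal best-window recovery of the compression."""
    cfg = synth.SimConfig()
    detected = 0
    contrast = []
    for s in _spawn(seed, reps):
        sess = _reactivation_session(cfg, s, n_swr=n_swr, fraction=fraction)
        r = rx.reactivation_fixed(sess["ut"], sess["onsets"], sess["model"],
                                  sess["tensor"], sess["template"])
        null = rx.reactivation_null(sess["ut"], sess["onsets"],
                                    sess["model"], sess["tensor"],
                                    sess["template"], seed=s,
                                    reps=null_reps)
        detected += np.nanmean(r) > np.percentile(null, 97.5)
        contrast.append(np.nanmean(r[sess["tags"]])
                        - np.nanmean(r[~sess["tags"]]))
    # modal best-window size over replay-tagged events, pooled sessions
    sizes = []
    for s in _spawn(seed + 1, 3):
        sess = _reactivation_session(cfg, s, n_swr=n_swr, fraction=fraction,
                                     compression=0.5)
        res = rx.reactivation_search(sess["ut"],
                                     sess["onsets"][sess["tags"]],
                                     sess["model"], sess["tensor"],
                                     sess["template"])
        sizes.extend(res.window_ms[~np.isnan(res.window_ms)])
    vals, counts = np.unique(sizes, return_counts=True)
    modal = float(vals[np.argmax(counts)])
    return {
        "power": detected / reps,
        "mean_contrast": float(np.mean(contrast)),
        "modal_window_ms": modal,
        "true_compressed_ms": 0.5 * (cfg.trial_window_s[1]
                                     - cfg.trial_window_s[0]) * 1000.0,
    }


def cca_checks(seed=0, delta_reps=40):
    """CCA correctness vs the generative covariance and condition contrast."""
    seeds = _spawn(seed, delta_reps + 2)
    rng = np.random.default_rng(seeds[0])
    p, m, rho, n = 8, 10, 0.6, 20000
    wx = rng.normal(size=p)
    wy = rng.normal(size=m)
    z = rng.standard_normal(n)
    X = np.outer(z, wx) * np.sqrt(rho) + rng.standard_normal((n, p))
    Y = np.outer(z, wy) * np.sqrt(rho) + rng.standard_normal((n, m))
    model = rx.fit_cca(X, Y)
    # brute force from the true covariance blocks
    Sxx = rho * np.outer(wx, wx) + np.eye(p)
    Syy = rho * np.outer(wy, wy) + np.eye(m)
    Sxy = rho * np.outer(wx, wy)
    Lx, Ly = np.linalg.cholesky(Sxx), np.linalg.cholesky(Syy)
    s = np.linalg.svd(np.linalg.solve(Lx, Sxy) @ np.linalg.inv(Ly).T,
                      compute_uv=False)
    corr_err = abs(model.corr - s[0])

    rng2 = np.random.default_rng(seeds[1])
    Xi = rng2.standard_normal((3000, 6))
    Yi = rng2.standard_normal((3000, 8))
    indep_corr = rx.fit_cca(Xi, Yi).corr
    null = [rx.fit_cca(Xi, Yi[rng2.permutation(3000)]).corr
            for _ in range(20)]
    indep_at_null = bool(indep_corr < np.mean(null) + 3 * np.std(null))

    cfg = synth.SimConfig()
    positive = 0
    for s_i in seeds[2:]:
        onsets = np.arange(120) * 3.0
        so_plus = np.zeros(120, bool)
        so_plus[::2] = True
        pop = synth.simulate_swr_population(cfg, s_i, onsets, so_plus, 0.0,
                                            370.0, n_units_per_area=15)
        pfc = [t for _, a, t in pop.units if a == "PFC"]
        m1 = [t for _, a, t in pop.units if a == "M1"]
        Xc = rx.cca_event_matrix(pfc, onsets)
        Yc = rx.cca_event_matrix(m1, onsets)
        cca = rx.fit_cca(Xc, Yc)
        mask = np.repeat(so_plus, 66)
        delta = rx.delta_cross_area_r(cca, (Xc[mask], Yc[mask]),
                                      (Xc[~mask], Yc[~mask]))
        positive += delta > 0
    return {
        "corr_err_vs_bruteforce": float(corr_err),
        "independent_at_null": indep_at_null,
        "independent_corr": float(indep_corr),
        "null_mean_corr": float(np.mean(null)),
        "delta_positive_fraction": positive / delta_reps,
    }
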