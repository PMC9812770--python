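import numpy as np
import pytest
from scipy.linalg import subspace_angles

from consolipy import gpfa


def _true_model(N=20, q=3, seed=0, noise=1.0, tau=(0.08, 0.12, 0.2)):
    rng = np.random.default_rng(seed)
    C = rng.normal(size=(N, q))
    C, _ = np.linalg.qr(C)
    C = C * 2.0
    return gpfa.GpfaModel(C, rng.normal(0, 0.2, N), np.full(N, noise),
                          np.asarray(tau[:q]), 1e-3, 0.015,
                          [f"u{i:02d}" for i in range(N)])


class TestBinZscore:
    def test_bin_count_and_standardization(self):
        rng = np.random.default_rng(0)
        events = np.arange(10.0, 100.0, 10.0)
        spikes = [np.sort(rng.uniform(0, 100, 2000)) for _ in range(5)]
        tensor = gpfa.bin_zscore(spikes, [f"u{i}" for i in range(5)],
                                 events, (0.0, 0.6))
        assert tensor.n_bins == 40  # 600 ms / 15 ms
        concat = np.concatenate(tensor.z, axis=1)
        assert np.allclose(concat.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(concat.std(axis=1), 1, atol=1e-12)

    def test_silent_unit_excluded_with_warning(self):
        events = np.array([10.0, 20.0])
        spikes = [np.array([10.1, 20.1]), np.array([])]
        with pytest.warns(UserWarning, match="excluding"):
            tensor = gpfa.bin_zscore(spikes, ["a", "b"], events, (0.0, 0.3))
        assert tensor.unit_ids == ["a"] and tensor.excluded == ["b"]

    def test_counts_match_bruteforce_histogram(self):
        rng = np.random.default_rng(1)
        spikes = [np.sort(rng.uniform(0, 50, 300))]
        events = np.array([5.0, 25.0])
        mats = gpfa.bin_counts(spikes, events, (-0.2, 0.4), 0.015)
        for t0, m in zip(events, mats):
            for b in range(m.shape[1]):
                lo = t0 - 0.2 + b * 0.015
                expect = np.sum((spikes[0] >= lo) & (spikes[0] < lo + 0.015))
                assert m[0, b] == expect


class TestFitGpfa:
    def test_q0_equals_diagonal_gaussian_fit(self):
        true = _true_model(q=1)
        Ys, _ = gpfa.sample_gpfa(true, 20, 30, seed=2)
        tensor = gpfa.tensor_from_arrays(Ys)
        model = gpfa.fit_gpfa(tensor, 0)
        Yall = np.concatenate(Ys, axis=1)
        mu, var = Yall.mean(axis=1), Yall.var(axis=1)
        expect = float(np.sum(-0.5 * (np.log(2 * np.pi * var)[:, None]
                                      + (Yall - mu[:, None]) ** 2
                                      / var[:, None])))
        assert model.loglik_trace[-1] == pytest.approx(expect, rel=1e-9)

    def test_loglik_monotone_nondecreasing(self):
        true = _true_model()
        Ys, _ = gpfa.sample_gpfa(true, 30, 30, seed=3)
        model = gpfa.fit_gpfa(gpfa.tensor_from_arrays(Ys), 3, max_iter=60)
        ll = model.loglik_trace
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_subspace_recovered_from_generative_data(self):
        true = _true_model(N=30)
        Ys, _ = gpfa.sample_gpfa(true, 80, 40, seed=4)
        model = gpfa.fit_gpfa(gpfa.tensor_from_arrays(Ys), 3, max_iter=150)
        ang = np.rad2deg(subspace_angles(model.C, true.C)).max()
        assert ang < 15.0

    def test_q_at_least_unit_count_rejected(self):
        true = _true_model(N=5, q=2, tau=(0.1, 0.1))
        Ys, _ = gpfa.sample_gpfa(true, 10, 20, seed=5)
        with pytest.raises(ValueError):
            gpfa.fit_gpfa(gpfa.tensor_from_arrays(Ys), 5)

    def test_unit_permutation_permutes_loadings_not_latents(self):
        true = _true_model(N=12)
        Ys, _ = gpfa.sample_gpfa(true, 25, 25, seed=6)
        perm = np.random.default_rng(0).permutation(12)
        m1 = gpfa.fit_gpfa(gpfa.tensor_from_arrays(Ys), 2, max_iter=40)
        m2 = gpfa.fit_gpfa(gpfa.tensor_from_arrays([Y[perm] for Y in Ys]),
                           2, max_iter=40)
        t1, _, _ = gpfa.extract_trajectories(m1, gpfa.tensor_from_arrays(Ys))
        t2, _, _ = gpfa.extract_trajectories(
            m2, gpfa.tensor_from_arrays([Y[perm] for Y in Ys]))
        for a, b in zip(t1, t2):
            # latent paths agree up to per-factor sign
            for j in range(a.shape[1]):
                assert min(np.abs(a[:, j] - b[:, j]).max(),
                           np.abs(a[:, j] + b[:, j]).max()) < 0.05


class TestSelectDim:
    def test_true_dimensionality_recovered(self):
        true = _true_model(N=25)
        Ys, _ = gpfa.sample_gpfa(true, 40, 30, seed=7)
        q, errs = gpfa.select_dim(gpfa.tensor_from_arrays(Ys), [1, 2, 3, 4, 5],
                                  max_iter=60, cv_folds=2)
        assert q == 3

    def test_pure_noise_selects_smallest_candidate(self):
        rng = np.random.default_rng(8)
        Ys = [rng.standard_normal((15, 25)) for _ in range(30)]
        q, errs = gpfa.select_dim(gpfa.tensor_from_arrays(Ys), [1, 2, 4],
                                  max_iter=40, cv_folds=2)
        assert q == 1

    def test_single_candidate_returned_as_is(self):
        q, errs = gpfa.select_dim(None, [4])
        assert q == 4 and errs == {}


class TestTrajectoriesAndVariance:
    def test_zero_private_noise_single_latent_explains_all_shared(self):
        true = _true_model(N=10, q=1, noise=1e-6, tau=(0.1,))
        assert true.shared_variance_fractions()[0] == pytest.approx(1.0)
        assert true.shared_over_total() > 0.999

    def test_shared_over_total_close_to_ground_truth(self):
        true = _true_model(N=30)
        Ys, _ = gpfa.sample_gpfa(true, 60, 30, seed=9)
        model = gpfa.fit_gpfa(gpfa.tensor_from_arrays(Ys), 3, max_iter=100)
        assert model.shared_over_total() == pytest.approx(
            true.shared_over_total(), abs=0.05)

    def test_unit_mismatch_errors(self, trained_session):
        s = trained_session
        bad = gpfa.tensor_from_arrays(
            [np.zeros((s["tensor"].n_units + 1, 10))])
        with pytest.raises(ValueError):
            gpfa.extract_trajectories(s["model"], bad)


class TestProcrustes:
    def test_identity_gives_zero_disparity(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        Z, tf, d = gpfa.procrustes_transform(X, X)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(Z, X)

    def test_rotation_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        Rm, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        Z, tf, d = gpfa.procrustes_transform(X, 2.5 * X @ Rm + 1.0)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_orthogonal_procrustes(self):
        from scipy.linalg import orthogonal_procrustes
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 3))
        _, tf, _ = gpfa.procrustes_transform(X, Y, scaling=False)
        X0 = X - X.mean(0)
        Y0 = Y - Y.mean(0)
        R_ref, _ = orthogonal_procrustes(Y0 / np.linalg.norm(Y0),
                                         X0 / np.linalg.norm(X0))
        assert np.allclose(tf["rotation"], R_ref)

    def test_align_days_needs_three_final_days(self):
        trajs = {1: np.random.default_rng(0).normal(size=(20, 3))}
        with pytest.raises(ValueError):
            gpfa.align_days(trajs)

    def test_aligned_rotated_day_matches_reference(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(30, 3))
        Rm, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        trajs = {d: ref.copy() for d in (2, 3, 4)}
        trajs[1] = ref @ Rm * 0.5 + 2.0
        tfs, disp, _ = gpfa.align_days(trajs)
        assert disp[1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(gpfa.apply_procrustes(trajs[1], tfs[1]), ref)


class TestGpfaCorrelation:
    def test_self_and_negated_template(self):
        t = np.random.default_rng(0).normal(size=(40, 3))
        assert gpfa.gpfa_correlation(t, t) == pytest.approx(1.0)
        assert gpfa.gpfa_correlation(-t, t) == pytest.approx(-1.0)

    def test_invariant_to_simultaneous_rotation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(30, 3))
        b = rng.normal(size=(30, 3))
        Rm, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert gpfa.gpfa_correlation(a @ Rm, b @ Rm) == pytest.approx(
            gpfa.gpfa_correlation(a, b), abs=1e-9)

    def test_noise_attenuation_matches_closed_form(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=(100, 3))
        var = t.ravel(order="F").var()
        sigma = 0.8
        rs = [gpfa.gpfa_correlation(t + rng.normal(0, sigma, t.shape), t)
              for _ in range(300)]
        expect = 1.0 / np.sqrt(1.0 + sigma ** 2 / var)
        assert np.mean(rs) == pytest.approx(expect, abs=0.02)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            gpfa.gpfa_correlation(np.zeros((10, 3)), np.ones((10, 3)))


class TestFidelity:
    def test_arithmetic_example(self):
        res = gpfa.fidelity([0.5, 0.5, 0.6])
        assert res.mean_r == pytest.approx(0.53333, abs=1e-4)
        assert res.sd_r == pytest.approx(0.05774, abs=1e-4)
        assert res.fidelity == pytest.approx(9.2376, abs=1e-3)

    def test_scale_invariance(self):
        r = np.array([0.2, 0.4, 0.5, 0.3])
        assert gpfa.fidelity(3 * r).fidelity == pytest.approx(
            gpfa.fidelity(r).fidelity)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            gpfa.fidelity([0.5, 0.5])
        with pytest.raises(ValueError):
            gpfa.fidelity([0.5, 0.5, 0.5])


class TestSpikeShuffle:
    def test_per_unit_counts_preserved_inside_windows(self):
        rng = np.random.default_rng(0)
        spikes = [np.sort(rng.uniform(0, 100, 500)) for _ in range(4)]
        events = np.array([10.0, 50.0, 80.0])
        out = gpfa.spike_shuffle_surrogate(spikes, events, (-0.6, 1.0),
                                           seed=1)
        for orig, sh in zip(spikes, out):
            assert len(sh) == len(orig)
            for t0 in events:
                m0 = np.sum((orig >= t0 - 0.6) & (orig < t0 + 1.0))
                m1 = np.sum((sh >= t0 - 0.6) & (sh < t0 + 1.0))
                assert m0 == m1

    def test_shuffle_destroys_shared_variance(self, trained_session):
        s = trained_session
        events = s["trials"]["reach_onset"].to_numpy()
        shuffled = gpfa.spike_shuffle_surrogate(
            [t for _, _, t in s["spikes"].units], events, (-0.6, 1.0), seed=2)
        tensor_sh = gpfa.bin_zscore(shuffled, s["spikes"].unit_ids, events,
                                    s["cfg"].trial_window_s)
        model_sh = gpfa.fit_gpfa(tensor_sh, 3, max_iter=40, tol=1e-5)
        assert model_sh.shared_over_total() < \
            0.5 * s["model"].shared_over_total()
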