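import numpy as np
import pytest

from consolipy import gpfa, reactivation as rx, synth


class TestEventPeth:
    def test_one_second_window_gives_66_bins(self):
        rng = np.random.default_rng(0)
        spikes = [np.sort(rng.uniform(0, 50, 400))]
        mats = rx.event_peth(spikes, [10.0, 20.0], (0.0, 1.0))
        assert all(m.shape == (1, 66) for m in mats)

    def test_normalized_peth_has_zero_mean_unit_sd_per_window(self):
        rng = np.random.default_rng(1)
        spikes = [np.sort(rng.uniform(0, 50, 2000)) for _ in range(3)]
        mats = rx.event_peth(spikes, [10.0], (0.0, 1.0), normalize=True)
        assert np.allclose(mats[0].mean(axis=1), 0, atol=1e-12)
        sd = mats[0].std(axis=1)
        assert np.allclose(sd[sd > 0], 1, atol=1e-12)

    def test_counts_match_bruteforce(self):
        rng = np.random.default_rng(2)
        spikes = [np.sort(rng.uniform(0, 30, 500))]
        mats = rx.event_peth(spikes, [5.0], (0.0, 0.195))
        for b in range(13):
            lo = 5.0 + b * 0.015
            assert mats[0][0, b] == np.sum((spikes[0] >= lo) &
                                           (spikes[0] < lo + 0.015))


class TestReachTemplate:
    def test_identical_trials_and_idempotence(self):
        t = np.random.default_rng(0).normal(size=(40, 3))
        tmpl = rx.reach_template([t, t, t])
        assert np.allclose(tmpl, t)
        assert np.allclose(rx.reach_template([tmpl]), tmpl)

    def test_mean_equals_per_bin_arithmetic_mean(self):
        rng = np.random.default_rng(1)
        trials = [rng.normal(size=(20, 3)) for _ in range(7)]
        tmpl = rx.reach_template(trials)
        assert np.allclose(tmpl, sum(trials) / 7)

    def test_no_trials_errors(self):
        with pytest.raises(ValueError):
            rx.reach_template([])


class TestSearchGrid:
    def test_lag_plus_size_bounded_by_405ms(self):
        grid = rx.search_grid()
        assert all(s + l <= 0.405 + 1e-9 for s, l in grid)
        sizes = sorted({s for s, _ in grid})
        assert sizes[0] == pytest.approx(0.075)
        assert sizes[-1] == pytest.approx(0.405)
        assert len(grid) > 50

    def test_fixed_window_is_13_bins(self):
        assert int(np.floor(0.195 / 0.015 + 1e-9)) == 13


class TestReactivation:
    def test_event_equal_to_its_own_projection_gives_r_one(self, trained_session):
        s = trained_session
        # template := the projection of the event window itself -> R = 1
        onset = s["trials"]["reach_onset"].iloc[0] + s["cfg"].trial_window_s[0]
        ut = [t for (uid, _, t) in s["spikes"].units
              if uid in s["tensor"].unit_ids]
        counts = gpfa.bin_counts(ut, [onset], (0.0, 0.6), 0.015)[0]
        tmpl = rx._project(counts, s["tensor"],
                           rx.template_basis(s["model"]))
        r = rx.reactivation_fixed(ut, np.array([onset]), s["model"],
                                  s["tensor"], tmpl, window_s=0.6)
        assert r[0] == pytest.approx(1.0, abs=1e-9)

    def test_replay_contrast_and_null_exceedance(self, trained_session):
        s = trained_session
        cfg = s["cfg"]
        onsets = 2000.0 + np.arange(120) * 3.0
        sleep = synth.simulate_sleep_spikes(cfg, 11, 2000.0, 400.0)
        sleep, tags = synth.inject_replay(sleep, onsets, s["gt"]["template"],
                                          s["gt"]["loadings"], cfg, 12,
                                          fraction=0.4)
        ut = [t for (uid, _, t) in sleep.units
              if uid in s["tensor"].unit_ids]
        r = rx.reactivation_fixed(ut, onsets, s["model"], s["tensor"],
                                  s["template"])
        assert np.nanmean(r[tags]) > np.nanmean(r[~tags]) + 0.1
        null = rx.reactivation_null(ut, onsets, s["model"], s["tensor"],
                                    s["template"], seed=0, reps=60)
        assert np.nanmean(r) > np.percentile(null, 97.5)
        # spike counts preserved by the shuffle is implied by construction;
        # the null must be tight around its mean
        assert null.std() < 0.05

    def test_search_respects_grid_and_finds_compression(self):
        # default-size session: 45 training trials give a stable template
        cfg = synth.SimConfig()
        spikes, trials, gt = synth.simulate_training_block(cfg, seed=7)
        tensor = gpfa.bin_zscore([t for _, _, t in spikes.units],
                                 spikes.unit_ids,
                                 trials["reach_onset"].to_numpy(),
                                 cfg.trial_window_s)
        model = gpfa.fit_gpfa(tensor, 3, max_iter=60, tol=1e-5)
        trajs, _, _ = gpfa.extract_trajectories(model, tensor)
        tmpl = rx.reach_template(trajs)
        onsets = 3000.0 + np.arange(200) * 3.0
        sleep = synth.simulate_sleep_spikes(cfg, 20, 3000.0, 620.0)
        sleep, tags = synth.inject_replay(sleep, onsets, gt["template"],
                                          gt["loadings"], cfg, 30,
                                          fraction=0.3, compression=0.5)
        ut = [t for (uid, _, t) in sleep.units if uid in tensor.unit_ids]
        res = rx.reactivation_search(ut, onsets[tags], model, tensor, tmpl)
        assert np.all(res.window_ms + res.lag_ms <= 405.0 + 1e-6)
        # modal best size within 1 grid bin of the compressed duration
        # (0.5 x 600 ms template = 300 ms)
        vals, counts = np.unique(res.window_ms[~np.isnan(res.window_ms)],
                                 return_counts=True)
        modal = vals[np.argmax(counts)]
        assert abs(modal - 300.0) <= 15.0 + 1e-6


class TestCca:
    def test_identical_latent_no_noise_gives_correlation_one(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(500)
        X = np.outer(z, rng.normal(size=4))
        Y = np.outer(z, rng.normal(size=6))
        X += 1e-8 * rng.standard_normal(X.shape)  # break exact rank 1
        Y += 1e-8 * rng.standard_normal(Y.shape)
        model = rx.fit_cca(X, Y)
        assert model.corr == pytest.approx(1.0, abs=1e-4)

    def test_weights_match_hand_computed_eigenproblem(self):
        # 2x2 toy with known covariance structure solved by hand:
        # x2, y2 pure noise; x1 = z + e, y1 = z + f  ->  top CV picks
        # (1, 0) in both areas up to scale
        rng = np.random.default_rng(1)
        z = rng.standard_normal(20000)
        X = np.column_stack([z + 0.5 * rng.standard_normal(20000),
                             rng.standard_normal(20000)])
        Y = np.column_stack([z + 0.5 * rng.standard_normal(20000),
                             rng.standard_normal(20000)])
        model = rx.fit_cca(X, Y)
        # true canonical correlation: corr(x1,y1) = 1/1.25 = 0.8
        assert model.corr == pytest.approx(0.8, abs=0.02)
        assert abs(model.wx[1] / model.wx[0]) < 0.05
        assert abs(model.wy[1] / model.wy[0]) < 0.05

    def test_matches_sklearn_cca_on_random_data(self):
        from sklearn.cross_decomposition import CCA as SkCCA
        rng = np.random.default_rng(2)
        z = rng.standard_normal(2000)
        X = np.outer(z, rng.normal(size=5)) * 0.7 + rng.standard_normal((2000, 5))
        Y = np.outer(z, rng.normal(size=7)) * 0.7 + rng.standard_normal((2000, 7))
        ours = rx.fit_cca(X, Y)
        u, v = SkCCA(n_components=1, max_iter=2000).fit(X, Y).transform(X, Y)
        sk_corr = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert ours.corr == pytest.approx(sk_corr, abs=1e-3)

    def test_independent_areas_at_permutation_null_level(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((3000, 6))
        Y = rng.standard_normal((3000, 8))
        model = rx.fit_cca(X, Y)
        # permutation oracle: break any dependence by shuffling rows of Y
        null = [rx.fit_cca(X, Y[rng.permutation(3000)]).corr
                for _ in range(20)]
        assert model.corr < np.mean(null) + 3 * np.std(null)

    def test_cross_area_r_sign_flip_invariance_and_zero_delta(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(1000)
        X = np.outer(z, rng.normal(size=4)) + 0.5 * rng.standard_normal((1000, 4))
        Y = np.outer(z, rng.normal(size=4)) + 0.5 * rng.standard_normal((1000, 4))
        model = rx.fit_cca(X, Y)
        r = rx.cross_area_r(model, X[:500], Y[:500])
        flipped = rx.CcaModel(-model.wx, -model.wy, model.corr, model.ridge,
                              model.mean_x, model.mean_y)
        assert rx.cross_area_r(flipped, X[:500], Y[:500]) == pytest.approx(r)
        assert rx.delta_cross_area_r(model, (X[:500], Y[:500]),
                                     (X[:500], Y[:500])) == pytest.approx(0.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rx.fit_cca(np.zeros((10, 1)), np.zeros((10, 3)))
        with pytest.raises(ValueError):
            rx.fit_cca(np.zeros((5, 6)), np.zeros((5, 6)))

    def test_condition_gated_shared_latent_raises_so_plus_r(self):
        cfg = synth.SimConfig()
        onsets = np.arange(150) * 3.0
        so_plus = np.zeros(150, bool)
        so_plus[::2] = True
        pop = synth.simulate_swr_population(cfg, 5, onsets, so_plus, 0.0,
                                            460.0, n_units_per_area=15)
        pfc = [t for _, a, t in pop.units if a == "PFC"]
        m1 = [t for _, a, t in pop.units if a == "M1"]
        X = rx.cca_event_matrix(pfc, onsets)
        Y = rx.cca_event_matrix(m1, onsets)
        model = rx.fit_cca(X, Y)
        mask = np.repeat(so_plus, 66)
        delta = rx.delta_cross_area_r(model, (X[mask], Y[mask]),
                                      (X[~mask], Y[~mask]))
        assert delta > 0.1
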