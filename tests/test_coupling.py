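import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consolipy import coupling as cpl
from consolipy.types import IntervalSet


class TestNearestLags:
    def test_identical_trains_give_zero_lags(self):
        ls = cpl.nearest_lags([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.allclose(ls.lags, 0.0)

    def test_midpoint_tie_links_to_earlier_reference(self):
        ls = cpl.nearest_lags([5.0], [4.0, 6.0])
        assert ls.lags[0] == pytest.approx(1.0)  # positive: after earlier ref

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            cpl.nearest_lags([1.0], [])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce_nearest_neighbor(self, seed):
        rng = np.random.default_rng(seed)
        targets = rng.uniform(0, 100, size=rng.integers(1, 40))
        refs = rng.uniform(0, 100, size=rng.integers(1, 40))
        ls = cpl.nearest_lags(targets, refs)
        for t, lag in zip(targets, ls.lags):
            d = np.abs(np.sort(refs) - t)
            assert abs(lag) == pytest.approx(d.min(), abs=1e-12)


class TestCouplingFractions:
    def test_all_zero_lags_give_100_percent(self):
        s = cpl.event_coupling([1.0, 2.0], [1.0, 2.0], (-0.5, 0.5))
        assert s.value == 100.0

    def test_direct_count_example(self):
        ls = cpl.LagSet(np.array([-1.0, 0.5, 0.9]), np.zeros(3, int))
        s = cpl.coupling_fraction(ls, (-0.75, 0.75))
        assert s.value == pytest.approx(100.0 / 3)

    def test_window_is_closed_at_both_ends(self):
        ls = cpl.LagSet(np.array([-0.75, 0.75]), np.zeros(2, int))
        assert cpl.coupling_fraction(ls, (-0.75, 0.75)).value == 100.0

    def test_zero_targets_flagged_not_zero(self):
        s = cpl.coupling_fraction(cpl.LagSet(np.empty(0), np.empty(0, int)),
                                  (-0.75, 0.75))
        assert s.value is None and s.flagged

    def test_pfc_m1_extremes(self):
        pfc = np.arange(10.0, 100.0, 10.0)
        assert cpl.pfc_m1_so_coupling(pfc, pfc + 0.1).value == 100.0
        assert cpl.pfc_m1_so_coupling(pfc, pfc + 5.0 - 0.5).value == 0.0

    def test_delta_coupling_antisymmetric(self):
        a = cpl.CouplingSummary("m", 30.0, (-1, 1), 50)
        b = cpl.CouplingSummary("m", 22.0, (-1, 1), 50)
        assert cpl.delta_coupling(a, b) == pytest.approx(8.0)
        assert cpl.delta_coupling(a, b) == -cpl.delta_coupling(b, a)
        assert cpl.delta_coupling(a, a) == 0.0

    def test_so_spindle_asymmetric_window(self):
        # spindle 0.8 s after SO nested; 0.8 s before not nested
        assert cpl.so_spindle_coupling([10.0], [10.8]).value == 100.0
        assert cpl.so_spindle_coupling([10.0], [9.2]).value == 0.0


class TestMultiCoupling:
    def test_so_and_spindle_at_peak_counted(self):
        s = cpl.multi_coupling([10.0], [10.0], [10.0])
        assert s.value == 100.0

    def test_missing_spindle_not_counted(self):
        s = cpl.multi_coupling([10.0], [10.5], [20.0])
        assert s.value == 0.0

    def test_quadruple_requires_coupled_so(self):
        s = cpl.multi_coupling([10.0], [10.2], [10.1], mode="quadruple",
                               pfc_m1_coupled_mask=[False])
        assert s.value == 0.0
        s = cpl.multi_coupling([10.0], [10.2], [10.1], mode="quadruple",
                               pfc_m1_coupled_mask=[True])
        assert s.value == 100.0

    def test_independent_trains_match_coverage_oracle(self):
        rng = np.random.default_rng(0)
        T = 5000.0
        nrems = IntervalSet([(0, T)])
        swr = np.sort(rng.uniform(1, T - 1, 400))
        sos = np.sort(rng.uniform(1, T - 1, 600))
        spin = np.sort(rng.uniform(1, T - 1, 300))
        got = cpl.multi_coupling(swr, sos, spin).value / 100.0
        c_so = cpl.window_coverage(sos, (-1, 1), nrems)
        c_sp = cpl.window_coverage(spin, (-1, 1), nrems)
        # independence: coincidence probability is the coverage product
        assert got == pytest.approx(c_so * c_sp, abs=0.06)


class TestCircularNull:
    def test_rotation_preserves_counts_and_interval_multiset(self):
        nrems = IntervalSet([(0, 50), (80, 130)])
        rng = np.random.default_rng(1)
        times = np.sort(nrems.from_concat(rng.uniform(0, 100, 30)))
        shifted = cpl.circular_shift(times, nrems, 37.3)
        assert len(shifted) == len(times)
        assert nrems.contains(shifted).all()
        # inter-event intervals on concatenated time are a rotation
        tc0 = np.sort(nrems.to_concat(times))
        tc1 = np.sort(nrems.to_concat(shifted))
        iei0 = np.diff(np.r_[tc0, tc0[0] + 100.0])
        iei1 = np.diff(np.r_[tc1, tc1[0] + 100.0])
        assert np.allclose(np.sort(iei0), np.sort(iei1), atol=1e-9)

    def test_single_event_analytic_null_mean(self):
        # 1 SO, 1 SWR, 100 s NREMS, +/-0.75 s window -> coverage 1.5 %
        nrems = IntervalSet([(0.0, 100.0)])
        so = np.array([50.0])
        metric = lambda swr: cpl.so_swr_coupling(swr, so)
        null = cpl.circular_null(metric, np.array([20.0]), nrems,
                                 reps=1000, seed=0)
        se = null.sd / np.sqrt(null.reps)
        assert abs(null.mean - 1.5) < 3 * max(se, np.sqrt(1.5 * 98.5 / 1000))

    def test_null_mean_equals_coverage_for_any_configuration(self):
        rng = np.random.default_rng(2)
        nrems = IntervalSet([(0, 40), (60, 90)])
        so = np.sort(nrems.from_concat(rng.uniform(0, 70, 5)))
        swr = np.sort(nrems.from_concat(rng.uniform(0, 70, 12)))
        metric = lambda s: cpl.so_swr_coupling(s, so, (-0.75, 0.75))
        null = cpl.circular_null(metric, swr, nrems, reps=2000, seed=3)
        # oracle: brute-force integration over a fine grid of offsets
        grid = np.linspace(0, 70, 3500, endpoint=False)
        vals = [metric(cpl.circular_shift(swr, nrems, off)).value
                for off in grid]
        assert null.mean == pytest.approx(np.mean(vals), abs=1.0)

    def test_empty_train_errors(self):
        with pytest.raises(ValueError):
            cpl.circular_null(lambda s: None, [], IntervalSet([(0, 10)]))


class TestSubsampledCoupling:
    def test_subsample_equal_to_n_reproduces_full_metric(self):
        rng = np.random.default_rng(4)
        pfc = np.sort(rng.uniform(0, 1000, 100))
        m1 = np.sort(rng.uniform(0, 1000, 80))
        full = cpl.pfc_m1_so_coupling(pfc, m1).value
        null = cpl.subsampled_coupling(pfc, m1, n_sub=100, reps=20, seed=0)
        assert np.allclose(null.values, full)

    def test_subsample_mean_not_above_full_coupling(self):
        rng = np.random.default_rng(5)
        pfc = np.sort(rng.uniform(0, 2000, 400))
        m1 = np.sort(rng.uniform(0, 2000, 150))
        full = cpl.pfc_m1_so_coupling(pfc, m1).value
        null = cpl.subsampled_coupling(pfc, m1, n_sub=100, reps=200, seed=1)
        assert null.mean <= full + 1e-9

    def test_subsample_mean_matches_enumeration_on_tiny_instance(self):
        # n=3 choose 2: enumerate all subsets exactly
        import itertools
        pfc = np.array([10.0, 50.0, 90.0])
        m1 = np.array([10.1, 49.0, 70.0, 90.05])
        exact = np.mean([
            cpl.pfc_m1_so_coupling(np.array(sub), m1).value
            for sub in itertools.combinations(pfc, 2)])
        null = cpl.subsampled_coupling(pfc, m1, n_sub=2, reps=4000, seed=2)
        assert null.mean == pytest.approx(exact, abs=1.5)

    def test_too_few_references_errors(self):
        with pytest.raises(ValueError):
            cpl.subsampled_coupling(np.arange(5.0), np.arange(5.0), n_sub=100)


class TestSwrConditions:
    def test_so_within_following_second_sets_so_plus(self):
        nrems = IntervalSet([(0, 100)])
        lab = cpl.label_swr_conditions([10.0, 40.0], [10.5, 41.5], nrems,
                                       seed=0)
        assert lab.so_plus.tolist() == [True, False]

    def test_minus_epoch_count_matches_and_fits_inside_nrems(self):
        nrems = IntervalSet([(0, 30), (50, 70)])
        swr = np.linspace(1, 28, 17)
        lab = cpl.label_swr_conditions(swr, [5.0], nrems, seed=1)
        assert len(lab.swr_minus_onsets) == len(swr)
        assert nrems.contains(lab.swr_minus_onsets).all()
        assert nrems.contains(lab.swr_minus_onsets + 1.0 - 1e-9).all()

    def test_nrems_too_short_errors(self):
        with pytest.raises(ValueError):
            cpl.label_swr_conditions([1.0], [2.0],
                                     IntervalSet([(0, 0.5)]), seed=0)


def test_coupling_estimator_bias_on_injected_probability():
    """Estimate matches p + (1-p) * c with c the realized coverage."""
    from consolipy import synth
    cfg = synth.SimConfig()
    for p in (0.2, 0.8):
        errs = []
        for rep in range(20):
            gt = synth.simulate_event_trains(cfg, seed=1000 + rep,
                                             duration_s=1200.0, p_pfc_m1=p)
            est = cpl.pfc_m1_so_coupling(gt.so_up["PFC"], gt.so_up["M1"]).value
            c = cpl.window_coverage(gt.so_up["PFC"], (-0.2, 0.2), gt.nrems)
            errs.append(est - 100.0 * (p + (1 - p) * c))
        assert abs(np.mean(errs)) < 3.0
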