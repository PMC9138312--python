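"""Decay-law fitting, alpha moment estimation, jackknife, comparisons."""

import warnings

import numpy as np
import pytest
from scipy import stats

from fibrilfrag import (
    DecaySeries,
    FibrilPopulation,
    FragmentationParams,
    LengthSample,
    compare_fits,
    estimate_alpha,
    fit_fragmentation,
    fit_length_decay,
    jackknife_se,
    mean_length_model,
    rate_law_crossing,
    simulate_fragmentation,
)

SCHEDULE = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 320.0, 640.0])

TABLE_PARAMS = {
    "WT": FragmentationParams(gamma=2.7, alpha=9.1e-4),
    "A30P": FragmentationParams(gamma=4.4, alpha=1.2e-3),
    "A53T": FragmentationParams(gamma=3.4, alpha=4.8e-4),
}


class TestMeanLengthModel:
    def test_decay_branch(self):
        p = FragmentationParams(2.0, 1e-3, C=100.0, t_s=4.0)
        assert mean_length_model(16.0, p) == pytest.approx(25.0)

    def test_plateau_branch(self):
        p = FragmentationParams(2.0, 1e-3, C=100.0, t_s=4.0)
        assert mean_length_model(1.0, p) == pytest.approx(50.0)

    def test_continuity_at_plateau(self):
        p = FragmentationParams(3.0, 1e-3, C=240.0, t_s=20.0)
        eps = 1e-9
        assert mean_length_model(20.0 - eps, p) == pytest.approx(
            mean_length_model(20.0 + eps, p), rel=1e-6
        )

    def test_zero_plateau_zero_time_rejected(self):
        p = FragmentationParams(2.0, 1e-3, C=100.0, t_s=0.0)
        with pytest.raises(ValueError):
            mean_length_model(0.0, p)


class TestFitLengthDecay:
    def test_noiseless_power_law(self):
        series = DecaySeries(SCHEDULE, 200.0 * SCHEDULE ** (-1.0 / 3.0))
        gamma, C, t_s, resid = fit_length_decay(series)
        assert gamma == pytest.approx(3.0, abs=1e-9)
        assert C == pytest.approx(200.0, rel=1e-9)
        assert np.abs(resid).max() < 1e-12

    @pytest.mark.parametrize("gamma_true, ts_true", [(2.5, 20.0), (1.5, 10.0), (5.0, 40.0)])
    def test_plateau_self_consistency(self, gamma_true, ts_true):
        p = FragmentationParams(gamma_true, 1e-3, C=300.0, t_s=ts_true)
        series = DecaySeries(SCHEDULE, mean_length_model(SCHEDULE, p))
        gamma, C, t_s, _ = fit_length_decay(series)
        assert gamma == pytest.approx(gamma_true, abs=1e-6)
        assert C == pytest.approx(300.0, rel=1e-6)
        assert t_s == ts_true

    def test_no_decay_raises(self):
        series = DecaySeries(SCHEDULE, np.full(SCHEDULE.size, 100.0) + SCHEDULE * 0.1)
        with pytest.raises(ValueError, match="no decay"):
            fit_length_decay(series)

    def test_low_count_time_points_excluded(self):
        counts = np.array([500, 500, 500, 500, 500, 500, 3])
        series = DecaySeries(SCHEDULE, 200.0 * SCHEDULE ** (-0.5), counts=counts)
        with pytest.warns(UserWarning, match="fewer than"):
            gamma, *_ = fit_length_decay(series)
        assert gamma == pytest.approx(2.0, abs=1e-9)


class TestEstimateAlpha:
    def test_monodisperse_closed_form(self):
        s = LengthSample(1.0, [100.0], [1.0], [7.0])
        alpha, per_t = estimate_alpha([s], gamma=1.0, t_s=0.0)
        assert alpha == pytest.approx(0.01)
        assert per_t[1.0] == pytest.approx(0.01)

    def test_exponential_distribution_closed_form(self):
        # gamma=2, f exponential with mean m(t) = 100 t^-1/2:
        # M_2 = Gamma(3) m^2 = 2 m^2, so alpha_t = (2t * 2 m^2)^(-1/2) = 5e-3
        # at every t. Verified against numerical integration of the density.
        rng = np.random.default_rng(1)
        samples = []
        for t in [4.0, 16.0, 64.0]:
            m = 100.0 * t**-0.5
            L = rng.exponential(m, 400_000)
            samples.append(LengthSample(t, L, np.ones(L.size), np.full(L.size, 7.0)))
            num = stats.expon(scale=m).moment(2)
            assert num == pytest.approx(2 * m**2, rel=1e-12)
        alpha, per_t = estimate_alpha(samples, gamma=2.0, t_s=0.0)
        assert alpha == pytest.approx(5e-3, rel=0.01)
        vals = np.array(list(per_t.values()))
        assert vals.std() / vals.mean() < 0.02  # time-constant under self-similarity

    def test_pre_plateau_samples_excluded(self):
        s1 = LengthSample(1.0, [100.0], [1.0], [7.0])
        s2 = LengthSample(10.0, [50.0], [1.0], [7.0])
        with pytest.warns(UserWarning, match="excluded"):
            alpha, per_t = estimate_alpha([s1, s2], gamma=1.0, t_s=5.0)
        assert list(per_t) == [10.0]

    def test_empty_set_raises(self):
        s = LengthSample(1.0, [100.0], [1.0], [7.0])
        with pytest.raises(ValueError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            estimate_alpha([s], gamma=1.0, t_s=5.0)


class TestJackknife:
    def test_se_of_mean_closed_form(self):
        # jackknife SE of the mean equals s/sqrt(n)
        assert jackknife_se([1.0, 2.0, 3.0], np.mean) == pytest.approx(1.0 / np.sqrt(3))
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        assert jackknife_se(list(x), np.mean) == pytest.approx(
            x.std(ddof=1) / np.sqrt(25), rel=1e-9
        )

    def test_constant_data_zero_se(self):
        assert jackknife_se([4.0] * 6, np.mean) == 0.0

    def test_exact_line_slope_zero_se(self):
        pts = [(float(i), 2.0 + 3.0 * i) for i in range(8)]

        def slope(subset):
            x, y = np.array(subset).T
            return stats.linregress(x, y).slope

        assert jackknife_se(pts, slope) < 1e-10

    def test_failure_names_index(self):
        def bad(subset):
            if len([s for s in subset if s > 2]) < 2:
                raise ValueError("boom")
            return float(np.mean(subset))

        with pytest.raises(RuntimeError, match="subset"):
            jackknife_se([1.0, 3.0, 4.0], bad)

    def test_too_few_units(self):
        with pytest.raises(ValueError):
            jackknife_se([1.0, 2.0], np.mean)


class TestFullInference:
    def test_recovery_from_simulated_truth(self, wt_params):
        # Fitted gamma within +-15% of truth in >= 80% of seeded runs.
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            L = rng.lognormal(np.log(800), 0.5, 2000)
            pop0 = FibrilPopulation(0.0, L, np.full(2000, 7.8))
            pops = simulate_fragmentation(pop0, wt_params, SCHEDULE, seed=seed)
            samples = [
                LengthSample(p.time, p.lengths, np.ones(len(p)), p.heights) for p in pops
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_fragmentation(samples)
            if abs(fit.params.gamma / wt_params.gamma - 1) < 0.15:
                hits += 1
            assert abs(fit.params.alpha / wt_params.alpha - 1) < 0.35
        assert hits >= 8

    def test_se_shrinks_with_more_time_points(self):
        # On a noiseless-plus-small-noise series, jackknife SEs shrink
        # in expectation as time points are added.
        rng = np.random.default_rng(11)
        times_all = np.geomspace(5, 640, 12)

        def se_for(n_points, trial):
            t = times_all[:n_points]
            mu = 300.0 * t**-0.4 * np.exp(rng.normal(0, 0.01, t.size))
            samples = [
                LengthSample(ti, np.full(50, mi), np.ones(50), np.full(50, 7.0))
                for ti, mi in zip(t, mu)
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fit_fragmentation(samples).se_gamma

        few = np.mean([se_for(6, i) for i in range(8)])
        many = np.mean([se_for(12, i) for i in range(8)])
        assert many < few


class TestCompareFits:
    def test_printed_parameter_ordering_at_100nm(self):
        cmp_ = compare_fits(TABLE_PARAMS, x_range=(50.0, 100.0))
        s = cmp_["summary"]
        assert s.loc["WT", "B100"] > s.loc["A30P", "B100"] > s.loc["A53T", "B100"]
        r = cmp_["ratios"]
        wt_a30p = r.loc[r["pair"] == "WT/A30P", "log10_ratio_at_100nm"].iloc[0]
        assert wt_a30p >= 1.0  # at least one order of magnitude

    def test_identical_fits_tie(self):
        p = FragmentationParams(3.0, 1e-3)
        cmp_ = compare_fits({"a": p, "b": p}, x_range=(10, 1000))
        assert np.allclose(cmp_["ratios"]["log10_ratio_at_100nm"], 0.0)
        tab = cmp_["table"]
        np.testing.assert_allclose(tab["B_a"], tab["B_b"])

    def test_wt_a30p_curves_cross_in_observed_range(self):
        # The steeper mutant law overtakes the least-stable type within
        # the observed 100-1000 nm window (closed-form crossing).
        x_cross = rate_law_crossing(TABLE_PARAMS["WT"], TABLE_PARAMS["A30P"])
        assert 100.0 < x_cross < 1000.0

    def test_higher_gamma_slower_late_decay_at_matched_rate(self):
        # Two laws matched at B(1000 nm): the higher-gamma law gives
        # slower late-time mean-length decay.
        g_lo, g_hi = 2.0, 4.0
        b1000 = 0.05
        a_lo = b1000 ** (1 / g_lo) / 1000.0
        a_hi = b1000 ** (1 / g_hi) / 1000.0
        pop0 = FibrilPopulation(0.0, np.full(500, 1000.0), np.full(500, 7.0))
        mus = {}
        for g, a in [(g_lo, a_lo), (g_hi, a_hi)]:
            runs = [
                simulate_fragmentation(
                    pop0, FragmentationParams(g, a), [640.0], seed=s
                )[0].mean_length
                for s in range(5)
            ]
            mus[g] = np.mean(runs)
        assert mus[g_hi] > mus[g_lo]
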