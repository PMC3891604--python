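"""Growth-curve metrics: smoothing, MaxR, GMR, lag trough, variability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagfit.growth import (
    GrowthCurve,
    crossing_time,
    fitness_variability,
    gmr,
    lag_locus,
    max_rate,
    resample_variability,
    smooth_and_differentiate,
    summarize_curve,
    windowed_mean_rate,
)
from lagfit.synth import DiauxicParams, gen_diauxic_curve


class TestCurveValidation:
    def test_rejects_non_monotone_time(self):
        t = np.arange(12.0)
        t[5] = t[4]
        with pytest.raises(ValueError, match="increasing"):
            GrowthCurve("w", "s", "HG", t, np.full(12, 0.3))

    def test_rejects_nonpositive_od(self):
        t = np.arange(12.0)
        od = np.full(12, 0.3)
        od[3] = 0.0
        with pytest.raises(ValueError, match="positive"):
            GrowthCurve("w", "s", "HG", t, od)

    def test_rejects_short_curve(self):
        with pytest.raises(ValueError, match="10"):
            GrowthCurve("w", "s", "HG", np.arange(5.0), np.full(5, 0.3))


class TestSmoothing:
    def test_pure_exponential_rate_recovered(self, exp_curve):
        prof = smooth_and_differentiate(exp_curve(rate=0.4), smoothing=0.35)
        band = (prof.od_smooth >= 0.15) & (prof.od_smooth <= 0.75)
        assert np.abs(prof.mu[band] - 0.4).max() < 1e-2

    def test_constant_od_gives_zero_rate(self):
        t = np.arange(0.0, 10.0, 0.25)
        curve = GrowthCurve("w", "s", "HG", t, np.full(len(t), 0.3))
        prof = smooth_and_differentiate(curve)
        assert np.abs(prof.mu).max() < 1e-8

    def test_biphasic_shape_recovered(self):
        """Deceleration, local minimum near the injected trough, re-acceleration."""
        params = DiauxicParams(mu1=0.45, mu2=0.20, od_shift=0.30, trough_rate=0.05)
        curve, truth = gen_diauxic_curve(params, seed=0)
        prof = smooth_and_differentiate(curve)
        band = (prof.od_smooth >= 0.15) & (prof.od_smooth <= 0.75)
        mu_band = prof.mu[band]
        od_band = prof.od_smooth[band]
        k = int(np.argmin(mu_band))
        assert 0 < k < len(mu_band) - 1  # interior minimum
        assert abs(od_band[k] - truth.od_trough) < 0.05
        # rates on both sides of the trough exceed the trough rate
        assert mu_band[0] > mu_band[k] and mu_band[-1] > mu_band[k]
        # recovered rate tracks the generator's analytic rate law
        true_mu = params.rate_at_od(od_band)
        assert np.abs(mu_band - true_mu).max() < 0.05

    def test_invalid_smoothing_rejected(self, exp_curve):
        with pytest.raises(ValueError):
            smooth_and_differentiate(exp_curve(), smoothing=0.0)


class TestMaxRate:
    def test_exact_exponential(self, exp_curve):
        assert max_rate(exp_curve(rate=0.5)) == pytest.approx(0.5, abs=1e-9)

    def test_noisy_exponential_within_tolerance(self, exp_curve):
        """1% multiplicative OD noise leaves the regression slope within 0.02."""
        errs = np.array(
            [
                max_rate(exp_curve(rate=0.5, dt=0.25, noise_sd=0.01, seed=s)) - 0.5
                for s in range(100)
            ]
        )
        assert abs(errs.mean()) < 0.005  # unbiased
        assert np.quantile(np.abs(errs), 0.95) < 0.02

    def test_band_never_reached_errors(self):
        t = np.arange(0.0, 5.0, 0.25)
        curve = GrowthCurve("w", "s", "HG", t, np.full(len(t), 0.05))
        with pytest.raises(ValueError, match=r"0\.15"):
            max_rate(curve)


class TestGMR:
    @given(rate=st.floats(0.1, 0.6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_exponential_identity(self, rate):
        """For exact exponential growth, GMR equals the rate for any bounds."""
        t = np.arange(0.0, np.log(0.9 / 0.05) / rate + 1.0, 0.25)
        curve = GrowthCurve("w", "s", "HG", t, 0.05 * np.exp(rate * t))
        assert gmr(curve) == pytest.approx(rate, abs=1e-4)

    def test_definition_from_known_crossings(self):
        # OD = 0.15 * 5**((t-2)/2): crosses 0.15 at t=2 h, 0.75 at t=4 h
        t = np.arange(0.0, 6.01, 0.25)
        od = 0.15 * 5.0 ** ((t - 2.0) / 2.0)
        curve = GrowthCurve("w", "s", "LG", t, od)
        assert gmr(curve) == pytest.approx(np.log(5.0) / 2.0, rel=1e-6)

    def test_biphasic_matches_analytic_crossing_times(self):
        params = DiauxicParams(noise_sd=0.0)
        curve, truth = gen_diauxic_curve(params, seed=0)
        assert gmr(curve) == pytest.approx(truth.gmr, abs=1e-3)

    def test_multiple_crossings_warns_and_uses_first(self):
        t = np.arange(0.0, 10.01, 0.25)
        od = 0.05 * np.exp(0.5 * t)
        od[np.searchsorted(od, 0.2)] = 0.14  # dip back below the lower bound
        curve = GrowthCurve("w", "s", "LG", t, od)
        with pytest.warns(UserWarning, match="first crossing"):
            crossing_time(curve.time_h, curve.od600, 0.15)

    def test_grid_resampling_invariance(self):
        """15-min and 5-min sampling agree within 1e-3 on noiseless curves."""
        p15 = DiauxicParams(sample_every_min=15.0)
        p5 = DiauxicParams(sample_every_min=5.0)
        c15, _ = gen_diauxic_curve(p15, seed=0)
        c5, _ = gen_diauxic_curve(p5, seed=0)
        assert gmr(c15) == pytest.approx(gmr(c5), abs=1e-3)

    def test_gmr_bounded_by_max_rate(self):
        curve, _ = gen_diauxic_curve(DiauxicParams(noise_sd=0.005), seed=3)
        assert gmr(curve) <= max_rate(curve) + 0.01


class TestLagLocus:
    def test_no_trough_flags_upper_bound(self, exp_curve):
        prof = smooth_and_differentiate(exp_curve(rate=0.3, t_max=14.0))
        locus = lag_locus(prof)
        assert locus.no_lag and locus.od_at_min == pytest.approx(0.75)
        assert locus.min_rate == pytest.approx(0.3, abs=0.01)

    def test_monotone_decelerating_curve_flags_no_lag(self):
        # rate falls smoothly with OD but never troughs: minimum sits at 0.75
        t = np.arange(0.0, 40.0, 0.25)
        # logistic growth: mu declines monotonically with OD
        od = 1.0 / (1.0 + (1.0 / 0.05 - 1.0) * np.exp(-0.4 * t))
        prof = smooth_and_differentiate(GrowthCurve("w", "s", "LG", t, od))
        locus = lag_locus(prof)
        assert locus.no_lag and locus.od_at_min == pytest.approx(0.75)

    def test_injected_trough_recovered(self):
        params = DiauxicParams(od_shift=0.30, trough_width=1.0)  # trough at ~0.42
        curve, truth = gen_diauxic_curve(params, seed=1)
        locus = lag_locus(smooth_and_differentiate(curve))
        assert not locus.no_lag
        assert abs(locus.od_at_min - truth.od_trough) < 0.05
        assert locus.min_rate == pytest.approx(truth.trough_rate, abs=0.01)


class TestWindowedMeanRate:
    def test_constant_rate_any_window(self, exp_curve):
        """A flat rate profile returns the constant rate for any window."""
        params = DiauxicParams(mu1=0.3, mu2=0.3, trough_rate=0.3, od_stationary=60.0)
        curve, _ = gen_diauxic_curve(params, seed=0, t_max_h=26.0)
        prof = smooth_and_differentiate(curve)
        for before, after in ((0.5, 0.1), (1.0, 0.0), (0.0, 0.0)):
            assert windowed_mean_rate(prof, before, after) == pytest.approx(0.3, abs=5e-3)

    def test_degenerate_window_returns_min_rate(self):
        curve, _ = gen_diauxic_curve(DiauxicParams(), seed=0)
        prof = smooth_and_differentiate(curve)
        locus = lag_locus(prof)
        assert windowed_mean_rate(prof, 0.0, 0.0) == locus.min_rate

    def test_window_mean_matches_generator_quadrature(self):
        """Window average equals the generator's analytic time-average rate."""
        params = DiauxicParams()
        curve, truth = gen_diauxic_curve(params, seed=0)
        prof = smooth_and_differentiate(curve)
        locus = lag_locus(prof)
        got = windowed_mean_rate(prof, 0.5, 0.1)
        od_l = locus.od_at_min * 2.0**-0.5
        od_r = locus.od_at_min * 2.0**0.1
        expect = np.log(od_r / od_l) / (
            truth.crossing_time(od_r) - truth.crossing_time(od_l)
        )
        assert got == pytest.approx(expect, abs=0.02)
        assert locus.min_rate <= got <= max_rate(curve)


class TestFitnessVariability:
    def test_identical_conditions_give_one(self):
        v = fitness_variability({c: 0.8 for c in ("HG", "LG", "LG+Mal", "LG+Gal")})
        assert v.fitness_variability == pytest.approx(1.0)

    def test_hand_computed_example(self):
        rel = {"HG": 0.9, "LG": 0.3, "LG+Mal": 0.9, "LG+Gal": 0.6}
        expect = 0.9 / (0.3 * 0.9 * 0.6) ** (1.0 / 3.0)  # independent arithmetic
        v = fitness_variability(rel)
        assert v.fitness_variability == pytest.approx(expect, rel=1e-12)
        assert v.fitness_variability > 1  # fitness drops in variable media

    def test_missing_condition_named(self):
        with pytest.raises(ValueError, match="LG\\+Gal"):
            fitness_variability({"HG": 0.9, "LG": 0.5, "LG+Mal": 0.6})

    def test_zero_relative_gmr_rejected(self):
        rel = {"HG": 0.9, "LG": 0.0, "LG+Mal": 0.9, "LG+Gal": 0.6}
        with pytest.raises(ValueError, match="positive"):
            fitness_variability(rel)


class TestResampleVariability:
    def test_single_replicate_zero_sd(self):
        reps = {c: [0.7] for c in ("HG", "LG", "LG+Mal", "LG+Gal")}
        mean, sd = resample_variability(reps, n_resamples=200, seed=0)
        assert sd == 0.0

    def test_matches_exhaustive_enumeration(self):
        """Resampling SD converges to the exact SD over the 16 equally likely
        replicate combinations."""
        import itertools

        reps = {
            "HG": [0.9, 0.8],
            "LG": [0.3, 0.5],
            "LG+Mal": [0.9, 0.7],
            "LG+Gal": [0.6, 0.4],
        }
        vals = []
        for combo in itertools.product(*(reps[c] for c in ("HG", "LG", "LG+Mal", "LG+Gal"))):
            hg, lg, mal, gal = combo
            vals.append(hg / (lg * mal * gal) ** (1.0 / 3.0))
        exact_mean, exact_sd = np.mean(vals), np.std(vals)
        mean, sd = resample_variability(reps, n_resamples=40_000, seed=1)
        assert mean == pytest.approx(exact_mean, abs=3 * exact_sd / np.sqrt(40_000) + 1e-3)
        assert sd == pytest.approx(exact_sd, rel=0.05)

    def test_seeded_reproducibility(self):
        reps = {c: [0.7, 0.9] for c in ("HG", "LG", "LG+Mal", "LG+Gal")}
        assert resample_variability(reps, seed=42) == resample_variability(reps, seed=42)


class TestSummary:
    def test_summary_consistency(self):
        curve, truth = gen_diauxic_curve(DiauxicParams(noise_sd=0.01), seed=5)
        s = summarize_curve(curve)
        assert s.gmr == pytest.approx(truth.gmr, rel=0.03)
        assert s.gmr_norm == pytest.approx(s.gmr / s.max_rate)
        assert 0 < s.gmr <= s.max_rate + 0.02
        assert s.t_lo < s.t_hi
        assert 0.15 <= s.od_at_min <= 0.75

    def test_trough_depth_decreases_gmr_not_maxr(self):
        """Deeper lag troughs strictly decrease GMR while MaxR is untouched."""
        gmrs, maxrs = [], []
        for trough in (0.20, 0.10, 0.05, 0.025):
            params = DiauxicParams(trough_rate=trough, noise_sd=0.0)
            curve, _ = gen_diauxic_curve(params, seed=0)
            gmrs.append(gmr(curve))
            maxrs.append(max_rate(curve))
        assert np.all(np.diff(gmrs) < 0)
        assert np.ptp(maxrs) < 1e-3

    def test_min_rate_correlates_with_gmr_across_panel(self):
        """Strains with deeper troughs have lower GMR (echo of the
        minimal-rate/GMR variance-explained analysis)."""
        from lagfit.synth import strain_panel

        min_rates, gmrs = [], []
        for entry in strain_panel(n_strains=10, seed=2):
            curve, _ = gen_diauxic_curve(entry["diauxic"], seed=7)
            s = summarize_curve(curve)
            min_rates.append(s.min_rate)
            gmrs.append(s.gmr)
        r = np.corrcoef(min_rates, gmrs)[0, 1]
        assert r > 0.5
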