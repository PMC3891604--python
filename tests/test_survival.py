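"""Censored lag statistics: Kaplan-Meier, log-rank, Cox partial likelihood."""

import numpy as np
import pandas as pd
import pytest

from lagfit.simulate import LagSpec
from lagfit.survival import (
    cox_fit,
    escape_curve,
    lag_summary,
    logrank_test,
    validate_lag_table,
)
from lagfit.synth import gen_lag_table


class TestValidation:
    def test_empty_table_rejected(self, lag_table):
        with pytest.raises(ValueError, match="empty"):
            validate_lag_table(pd.DataFrame(columns=["cell_id", "strain", "lag_h", "event"]))

    def test_bad_event_codes_rejected(self, lag_table):
        t = lag_table([1, 2], [1, 1])
        t.loc[0, "event"] = 2
        with pytest.raises(ValueError, match="event"):
            validate_lag_table(t)


class TestEscapeCurve:
    def test_no_censoring_equals_empirical_cdf(self, lag_table):
        curve = escape_curve(lag_table([2, 4, 6], [1, 1, 1]))
        # survival steps 1 -> 2/3 -> 1/3 -> 0 at the event times
        at = dict(zip(curve.time_h, curve.survival))
        assert at[2.0] == pytest.approx(2 / 3)
        assert at[4.0] == pytest.approx(1 / 3)
        assert at[6.0] == pytest.approx(0.0)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.escape[-1] == pytest.approx(1.0)

    def test_all_censored_stays_at_one(self, lag_table):
        curve = escape_curve(lag_table([20, 20, 20], [0, 0, 0]))
        assert np.all(curve.survival == 1.0)

    def test_mixed_table_matches_hand_product_limit(self, lag_table):
        # events at 2,3,5,9; censored at 3 and 7; risk sets enumerated by hand:
        # t=2: 6 at risk, 1 event -> 5/6
        # t=3: 5 at risk, 1 event -> 5/6 * 4/5 = 2/3 (censor at 3 leaves after)
        # t=5: 3 at risk, 1 event -> 2/3 * 2/3 = 4/9
        # t=9: 1 at risk, 1 event -> 0
        curve = escape_curve(lag_table([2, 3, 3, 5, 7, 9], [1, 1, 0, 1, 0, 1]))
        at = dict(zip(curve.time_h, curve.survival))
        assert at[2.0] == pytest.approx(5 / 6)
        assert at[3.0] == pytest.approx(2 / 3)
        assert at[5.0] == pytest.approx(4 / 9)
        assert at[9.0] == pytest.approx(0.0)


class TestLagSummary:
    def test_basic_arithmetic(self, lag_table):
        s = lag_summary(lag_table([1, 2, 3, 4], [1, 1, 1, 1]))
        assert s.mean_lag == pytest.approx(2.5)
        assert s.sd_lag == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
        assert s.noise == pytest.approx(s.sd_lag / 2.5)
        assert s.quartiles[1] == pytest.approx(2.5)
        assert s.frac_resumed == 1.0

    def test_censored_half(self, lag_table):
        lags = [3, 4, 5, 6, 7] + [20] * 5
        events = [1] * 5 + [0] * 5
        s = lag_summary(lag_table(lags, events), horizon_h=20.0)
        assert s.frac_resumed == 0.5
        assert s.n_events == 5

    def test_zero_events_flagged(self, lag_table):
        s = lag_summary(lag_table([20, 20], [0, 0]))
        assert s.frac_resumed == 0.0
        assert np.isnan(s.mean_lag)


def _logrank_by_hand(a, b):
    """Independent O-E/V computation by explicit risk-set enumeration."""
    times = np.concatenate([a["lag_h"], b["lag_h"]])
    events = np.concatenate([a["event"], b["event"]])
    group = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_give_zero(self, lag_table):
        t = lag_table([2, 4, 6, 20], [1, 1, 1, 0])
        res = logrank_test(t, t.copy())
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)
        assert res.df == 1

    def test_matches_hand_risk_set_computation(self, lag_table):
        a = lag_table([1, 3, 5, 8], [1, 1, 0, 1])
        b = lag_table([2, 4, 6, 8], [1, 1, 1, 0])
        res = logrank_test(a, b)
        assert res.chi2 == pytest.approx(_logrank_by_hand(a, b), rel=1e-6)

    def test_invariant_under_time_rescaling(self, lag_table):
        a = lag_table([1, 3, 5, 8, 9], [1, 1, 0, 1, 1])
        b = lag_table([2, 4, 6, 8, 12], [1, 1, 1, 0, 1])
        r1 = logrank_test(a, b)
        a2, b2 = a.copy(), b.copy()
        a2["lag_h"] *= 60.0  # hours -> minutes
        b2["lag_h"] *= 60.0
        r2 = logrank_test(a2, b2)
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-12)

    def test_no_events_rejected(self, lag_table):
        t = lag_table([20, 20], [0, 0])
        with pytest.raises(ValueError, match="events"):
            logrank_test(t, t.copy())


class TestCox:
    def test_constant_covariate_rejected(self, lag_table):
        t = lag_table([1, 2, 3, 4], [1, 1, 1, 1], geno=[1, 1, 1, 1])
        with pytest.raises(ValueError, match="variation"):
            cox_fit(t, "geno")

    def test_agrees_with_partial_likelihood_grid_search(self, lag_table):
        """Two groups, no ties, no censoring: Newton maximum equals an
        exhaustive grid search of the partial likelihood over [-5, 5]."""
        rng = np.random.default_rng(1)
        g = np.repeat([0.0, 1.0], 12)
        lags = rng.exponential(1.0 / (0.3 * np.exp(1.0 * g)))
        lags += np.arange(len(lags)) * 1e-6  # enforce no ties
        t = lag_table(lags, [1] * len(lags), geno=g)
        fit = cox_fit(t, "geno")

        times = t["lag_h"].to_numpy()
        order = np.argsort(times)

        def pl(beta):
            ll = 0.0
            for i, idx in enumerate(order):
                risk = order[i:]
                ll += beta * g[idx] - np.log(np.exp(beta * g[risk]).sum())
            return ll

        grid = np.arange(-5.0, 5.0, 1e-3)
        best = grid[int(np.argmax([pl(b) for b in grid]))]
        assert fit.beta[0] == pytest.approx(best, abs=1e-3)

    def test_breslow_equals_efron_without_ties(self, lag_table):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        lags = rng.exponential(1.0 / (0.3 * np.exp(0.5 * x)))
        t = lag_table(lags, [1] * 60, x=x)
        fb = cox_fit(t, "x", ties="breslow")
        fe = cox_fit(t, "x", ties="efron")
        assert fb.beta[0] == pytest.approx(fe.beta[0], rel=1e-9)

    def test_matches_lifelines_on_tie_free_data(self, lag_table):
        """Independent cross-check against an established implementation."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        x = rng.normal(size=150)
        raw = rng.exponential(1.0 / (0.25 * np.exp(0.7 * x)))
        event = (raw <= 10.0).astype(int)
        t = lag_table(np.minimum(raw, 10.0).clip(1e-9), event, x=x)
        fit = cox_fit(t, "x")
        cph = CoxPHFitter().fit(t[["lag_h", "event", "x"]], "lag_h", "event")
        assert fit.beta[0] == pytest.approx(cph.params_.iloc[0], abs=1e-5)
        assert fit.se_beta[0] == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-5)

    def test_hazard_ratio_exponentiates_beta(self, lag_table):
        """A log-hazard coefficient of 3.26 corresponds to a ~26-fold higher
        chance of resuming growth."""
        from lagfit.survival import CoxResult

        res = CoxResult(
            covariates=["hxk2"],
            beta=np.array([3.26]),
            se_beta=np.array([0.3]),
            p=np.array([1e-11]),
            loglik=0.0,
            n_iter=5,
            ties="breslow",
        )
        assert res.hazard_ratio[0] == pytest.approx(26.0, abs=0.1)

    def test_two_covariate_fit(self, lag_table):
        rng = np.random.default_rng(4)
        x1 = rng.normal(size=200)
        x2 = rng.integers(0, 2, size=200).astype(float)
        lags = rng.exponential(1.0 / (0.2 * np.exp(0.5 * x1 + 0.8 * x2)))
        t = lag_table(lags, [1] * 200, x1=x1, x2=x2)
        fit = cox_fit(t, ["x1", "x2"])
        assert abs(fit.beta[0] - 0.5) < 2.5 * fit.se_beta[0]
        assert abs(fit.beta[1] - 0.8) < 2.5 * fit.se_beta[1]

    def test_beta_recovery_with_censoring(self):
        """Proportional-hazards lag tables from the generator recover the
        true log-hazard ratio within 2 SE most of the time."""
        hits = 0
        for seed in range(40):
            table = gen_lag_table(
                LagSpec("uniform", (0.0, 1.0)),
                n=500,
                horizon_h=0.9,
                seed=seed,
                covariate_name="geno",
                hazard_ratio=float(np.e),
            )
            fit = cox_fit(table, "geno")
            hits += abs(fit.beta[0] - 1.0) <= 2.0 * fit.se_beta[0]
        assert hits / 40 >= 0.9


class TestPanelProperties:
    def test_mean_and_sd_of_lag_positively_correlated(self):
        """Longer-lag synthetic strains also show more lag heterogeneity."""
        from lagfit.synth import strain_panel

        means, sds = [], []
        for entry in strain_panel(n_strains=12, seed=5):
            table = gen_lag_table(entry["lag"], n=400, horizon_h=40.0, seed=11)
            s = lag_summary(table, horizon_h=40.0)
            if s.n_events > 10:
                means.append(s.mean_lag)
                sds.append(s.sd_lag)
        assert np.corrcoef(means, sds)[0, 1] > 0.5
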