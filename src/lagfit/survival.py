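"""Censored single-cell lag-time statistics.

Single-cell lag phases are scored under time-lapse microscopy as the hour
at which a cell transferred from glucose to maltose produces its first bud.
Cells that never bud before the recording horizon (20 h by default) are
right-censored, not discarded, so every population summary and test here is
a survival-analysis estimator:

* escape curves — Kaplan–Meier product-limit estimates of the probability
  of still lagging at time t (the "escape fraction" is its complement);
* log-rank tests for pairwise strain comparisons;
* Cox proportional-hazards fits relating lag escape to population-level
  covariates (GMR, fitness variability, genotype indicators).

A lag table is a pandas DataFrame with columns ``cell_id``, ``strain``,
``lag_h`` (event or censoring time, hours), ``event`` (1 = budded,
0 = censored) and any number of covariate columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import chi2 as _chi2

__all__ = [
    "REQUIRED_COLUMNS",
    "DEFAULT_HORIZON_H",
    "LagSummary",
    "SurvivalCurve",
    "LogRankResult",
    "CoxResult",
    "validate_lag_table",
    "escape_curve",
    "lag_summary",
    "logrank_test",
    "cox_fit",
]

REQUIRED_COLUMNS = ("cell_id", "strain", "lag_h", "event")

#: Microscopy recording window in hours; cells not budded by then are censored.
DEFAULT_HORIZON_H = 20.0


@dataclass
class LagSummary:
    """Moments and quartiles of observed lags plus the escape fraction.

    Moments are computed over event (budded) rows only — censored lag times
    are unknown — while ``frac_resumed`` carries the censoring information:
    the fraction of all cells that budded within the horizon.  ``noise`` is
    the coefficient of variation sd/mean.  With zero events the moment
    fields are NaN and ``frac_resumed`` is 0.
    """

    n: int
    n_events: int
    mean_lag: float
    sd_lag: float
    min_lag: float
    quartiles: tuple[float, float, float]
    noise: float
    frac_resumed: float


@dataclass
class SurvivalCurve:
    """Kaplan–Meier estimate of P(still lagging at t) with at-risk counts."""

    time_h: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    @property
    def escape(self) -> np.ndarray:
        """Cumulative fraction of the population that has escaped the lag."""
        return 1.0 - self.survival


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass
class CoxResult:
    """Cox proportional-hazards fit for one (or two) covariates.

    ``beta`` is the log-hazard change per covariate unit; positive beta
    means faster lag escape.  ``hazard_ratio = exp(beta)``; for a binary
    covariate it is the fold change in the instantaneous budding rate.
    """

    covariates: list[str]
    beta: np.ndarray
    se_beta: np.ndarray
    p: np.ndarray
    loglik: float
    n_iter: int
    ties: str
    separation_flag: bool = False

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.beta)


def validate_lag_table(table: pd.DataFrame, horizon_h: float | None = None) -> pd.DataFrame:
    """Check the lag-table contract and return the validated frame."""
    if len(table) == 0:
        raise ValueError("lag table is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"lag table missing column(s): {', '.join(missing)}")
    lag = table["lag_h"].to_numpy(dtype=float)
    if np.any(lag <= 0) or np.any(~np.isfinite(lag)):
        raise ValueError("lag_h must be positive and finite")
    ev = table["event"].to_numpy()
    if not np.isin(ev, (0, 1)).all():
        raise ValueError("event must be 0 (censored) or 1 (budded)")
    if horizon_h is not None and np.any(lag > horizon_h + 1e-9):
        raise ValueError(f"lag_h exceeds the observation horizon {horizon_h} h")
    return table


def escape_curve(table: pd.DataFrame) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate honouring censoring.

    Returns the survival function P(lag > t) with at-risk counts; the
    escape fraction of the population is ``1 - survival``.
    """
    validate_lag_table(table)
    kmf = KaplanMeierFitter()
    kmf.fit(table["lag_h"], event_observed=table["event"])
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
    )
    return SurvivalCurve(time_h=times, survival=surv, at_risk=at_risk)


def lag_summary(table: pd.DataFrame, horizon_h: float = DEFAULT_HORIZON_H) -> LagSummary:
    """Per-population lag summary (see :class:`LagSummary` for conventions)."""
    validate_lag_table(table)
    events = table.loc[table["event"] == 1, "lag_h"].to_numpy(dtype=float)
    n = len(table)
    n_resumed = int(np.sum((table["event"] == 1) & (table["lag_h"] <= horizon_h)))
    if len(events) == 0:
        nan = float("nan")
        return LagSummary(n, 0, nan, nan, nan, (nan, nan, nan), nan, 0.0)
    mean = float(events.mean())
    sd = float(events.std(ddof=1)) if len(events) > 1 else 0.0
    q1, q2, q3 = np.percentile(events, [25, 50, 75])
    return LagSummary(
        n=n,
        n_events=len(events),
        mean_lag=mean,
        sd_lag=sd,
        min_lag=float(events.min()),
        quartiles=(float(q1), float(q2), float(q3)),
        noise=sd / mean,
        frac_resumed=n_resumed / n,
    )


def logrank_test(a: pd.DataFrame, b: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test of equal lag-escape hazards (df = 1)."""
    validate_lag_table(a)
    validate_lag_table(b)
    if a["event"].sum() == 0 and b["event"].sum() == 0:
        raise ValueError("no budding events in either group; log-rank undefined")
    res = _ll_logrank(
        a["lag_h"], b["lag_h"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return LogRankResult(chi2=float(res.test_statistic), df=1, p=float(res.p_value))


# ---------------------------------------------------------------------------
# Cox partial likelihood


def _cox_loglik(beta, times, events, X, ties):
    """Cox partial log-likelihood, gradient and Hessian (Breslow or Efron)."""
    eta = X @ beta
    # risk set at an event time t: all subjects with time >= t.  Sort
    # descending so the risk set is a prefix cumulative sum.
    order = np.argsort(-times, kind="stable")
    t_s, e_s, X_s = times[order], events[order], X[order]
    w = np.exp(eta[order])
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * X_s, axis=0)
    cum_wxx = np.cumsum(w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :]), axis=0)

    ll = 0.0
    grad = np.zeros(X.shape[1])
    hess = np.zeros((X.shape[1], X.shape[1]))
    # iterate over distinct event times (group ties)
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        idx = np.arange(i, j)
        ev = idx[e_s[idx] == 1]
        d = len(ev)
        if d:
            S0 = cum_w[j - 1]
            S1 = cum_wx[j - 1]
            S2 = cum_wxx[j - 1]
            sx = X_s[ev].sum(axis=0)
            ll += float(sx @ beta)
            grad += sx
            if ties == "breslow" or d == 1:
                ll -= d * np.log(S0)
                grad -= d * S1 / S0
                hess -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
            else:  # efron
                wd = w[ev].sum()
                wdx = (w[ev, None] * X_s[ev]).sum(axis=0)
                wdxx = (w[ev, None, None] * (X_s[ev, :, None] * X_s[ev, None, :])).sum(axis=0)
                for r in range(d):
                    f = r / d
                    S0r = S0 - f * wd
                    S1r = S1 - f * wdx
                    S2r = S2 - f * wdxx
                    ll -= np.log(S0r)
                    grad -= S1r / S0r
                    hess -= S2r / S0r - np.outer(S1r, S1r) / S0r**2
        i = j
    return ll, grad, hess


def cox_fit(
    table: pd.DataFrame,
    covariate: "str | list[str]",
    ties: str = "breslow",
    tol: float = 1e-6,
    max_iter: int = 50,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton iteration.

    At most two covariates are supported (single- and paired-covariate
    analyses).  Ties are handled with the Breslow approximation by default;
    ``ties="efron"`` selects the Efron correction.  Standard errors come
    from the observed information at the maximum; p-values are two-sided
    Wald tests.  Likely complete separation (|beta| drifting beyond 20) is
    flagged rather than silently reported.
    """
    validate_lag_table(table)
    names = [covariate] if isinstance(covariate, str) else list(covariate)
    if not 1 <= len(names) <= 2:
        raise ValueError("cox_fit supports one or two covariates")
    for name in names:
        if name not in table.columns:
            raise ValueError(f"covariate {name!r} not in table")
        if table[name].isna().any():
            raise ValueError(f"covariate {name!r} has missing values")
        if table[name].nunique() < 2:
            raise ValueError(f"covariate {name!r} has no variation")
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    if table["event"].sum() == 0:
        raise ValueError("no events; partial likelihood undefined")

    times = table["lag_h"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    X = table[names].to_numpy(dtype=float)
    # centre covariates for numerical stability; beta is unaffected
    X = X - X.mean(axis=0)

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _cox_loglik(beta, times, events, X, ties)
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(hess, grad)
        new_beta = beta - step
        new_ll, new_grad, new_hess = _cox_loglik(new_beta, times, events, X, ties)
        # step-halving keeps Newton ascending
        halves = 0
        while new_ll < ll - 1e-12 and halves < 30:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _cox_loglik(new_beta, times, events, X, ties)
            halves += 1
        stalled = np.linalg.norm(new_beta - beta) < 1e-12
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.linalg.norm(grad) < tol or stalled:
            break
    else:
        raise RuntimeError(
            f"Cox Newton did not converge in {max_iter} iterations "
            f"(gradient norm {np.linalg.norm(grad):.3g})"
        )
    separation = bool(np.any(np.abs(beta) > 20))
    info = -hess
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta / se
    p = 2.0 * _chi2.sf(z**2, df=1)
    return CoxResult(
        covariates=names,
        beta=beta,
        se_beta=se,
        p=p,
        loglik=float(ll),
        n_iter=it,
        ties=ties,
        separation_flag=separation,
    )
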