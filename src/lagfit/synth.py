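"""Synthetic data with known ground truth for every pipeline input.

The generators emulate the shapes of the study system — biphasic diauxic
OD curves, heterogeneous censored single-cell lag tables with a nonviable
fraction, labelled two-strain competition counts under alternating carbon
segments, and per-generation ON/OFF switching series — so every estimator
in the package has a recovery test against exact ground truth without any
external data.

Diauxic curves are generated from a specific growth rate defined as a
function of OD (rate-versus-population-size space, where the lag metrics
live): constant ``mu1`` below ``od_shift``, a smooth cosine dip down to
``trough_rate`` over ``trough_width`` doublings, recovery to ``mu2``, and a
sharp logistic roll-off at the stationary plateau.  Because ``mu`` depends
on OD alone, crossing times of any OD level have the closed quadrature form
``t(OD) = ln 2 * \\int dx / mu(2**x)`` (x = log2 OD), which the generator
returns as analytic ground truth for MaxR, GMR and the trough position.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad, solve_ivp

from .competition import ErrorRates, confusion_forward
from .growth import GrowthCurve
from .simulate import (
    EnvSchedule,
    LagSpec,
    SimConfig,
    SimResult,
    StrainParams,
    simulate_schedule,
)
from .switching import OnFractionSeries

__all__ = [
    "DiauxicParams",
    "DiauxicTruth",
    "gen_diauxic_curve",
    "gen_lag_table",
    "gen_competition_counts",
    "gen_on_fraction",
    "archetype_pair",
    "strain_panel",
]


@dataclass
class DiauxicParams:
    """Ground-truth shape of a biphasic growth curve.

    Rates in 1/h, ODs dimensionless.  ``od_shift`` is where deceleration
    begins; the rate dips to ``trough_rate`` and recovers to ``mu2`` over
    ``trough_width`` doublings of OD; growth rolls off logistically at
    ``od_stationary``.  Setting ``trough_rate = mu2 = mu1`` yields a pure
    exponential.  ``noise_sd`` is relative (lognormal) OD noise.
    """

    od0: float = 0.05
    mu1: float = 0.45
    mu2: float = 0.20
    od_shift: float = 0.30
    trough_rate: float = 0.05
    trough_width: float = 1.0
    od_stationary: float = 1.5
    noise_sd: float = 0.0
    sample_every_min: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.od0 < self.od_shift < self.od_stationary):
            raise ValueError("need 0 < od0 < od_shift < od_stationary")
        if min(self.mu1, self.mu2, self.trough_rate) <= 0:
            raise ValueError("rates must be positive")
        if self.trough_width <= 0:
            raise ValueError("trough_width must be positive")
        if self.noise_sd < 0 or self.sample_every_min <= 0:
            raise ValueError("invalid noise or sampling settings")

    # -- the rate law ------------------------------------------------------
    def rate_at_od(self, od: "float | np.ndarray") -> "float | np.ndarray":
        """Specific growth rate mu(OD), the generator's ground truth."""
        od = np.asarray(od, dtype=float)
        x = np.log2(od)
        x_shift = np.log2(self.od_shift)
        w = self.trough_width
        base = np.where(x < x_shift, self.mu1, self.mu2)
        # cosine dip: mu1 -> trough over the first half-window, trough -> mu2
        # over the second half
        u = (x - x_shift) / w
        in_dip = (u >= 0) & (u <= 1)
        first = u <= 0.5
        # both halves reach trough_rate at u = 0.5 with zero slope
        shape = 0.5 * (1 + np.cos(2 * np.pi * u))
        dip = np.where(
            first,
            self.trough_rate + (self.mu1 - self.trough_rate) * shape,
            self.trough_rate + (self.mu2 - self.trough_rate) * shape,
        )
        mu = np.where(in_dip, dip, base)
        rolloff = 1.0 / (1.0 + (od / self.od_stationary) ** 40)
        out = mu * rolloff
        return float(out) if out.ndim == 0 else out

    @property
    def od_trough(self) -> float:
        """OD at the injected rate minimum (centre of the dip)."""
        return float(self.od_shift * 2.0 ** (self.trough_width / 2.0))

    def crossing_time(self, od: float) -> float:
        """Analytic time at which the noiseless curve reaches ``od``.

        ``t = ln 2 * \\int_{log2 od0}^{log2 od} dx / mu(2**x)`` by adaptive
        quadrature; exact in rate-versus-OD space.
        """
        x0, x1 = np.log2(self.od0), np.log2(od)
        val, _ = quad(lambda x: 1.0 / self.rate_at_od(2.0**x), x0, x1, limit=200)
        return float(np.log(2.0) * val)

    def true_gmr(self, od_lo: float = 0.15, od_hi: float = 0.75) -> float:
        return float(
            np.log(od_hi / od_lo) / (self.crossing_time(od_hi) - self.crossing_time(od_lo))
        )


@dataclass
class DiauxicTruth:
    """Analytic ground truth shipped alongside a generated curve."""

    params: DiauxicParams
    max_rate: float
    gmr: float
    od_trough: float
    trough_rate: float
    crossing_time: Callable[[float], float] = field(repr=False, default=None)


def gen_diauxic_curve(
    params: DiauxicParams,
    seed: int | None = None,
    well_id: str = "synthetic",
    strain: str = "synthetic",
    condition: str = "LG",
    t_max_h: float | None = None,
) -> tuple[GrowthCurve, DiauxicTruth]:
    """Generate one plate-reader curve plus its analytic ground truth.

    Integrates ``d log2(OD)/dt = mu(OD)/ln 2`` with dense output, samples
    every ``sample_every_min`` minutes until the curve settles near the
    stationary plateau, and multiplies by mean-one lognormal noise.
    """
    rng = np.random.default_rng(seed)
    if t_max_h is None:
        # time to get within half a percent of the plateau, plus margin
        t_max_h = params.crossing_time(0.995 * params.od_stationary) * 1.15 + 2.0

    def rhs(_t, x):
        return [params.rate_at_od(2.0 ** x[0]) / np.log(2.0)]

    sol = solve_ivp(
        rhs,
        (0.0, t_max_h),
        [np.log2(params.od0)],
        dense_output=True,
        rtol=1e-10,
        atol=1e-12,
        max_step=0.05,
    )
    dt = params.sample_every_min / 60.0
    t = np.arange(0.0, t_max_h + 1e-9, dt)
    od = 2.0 ** sol.sol(t)[0]
    if params.noise_sd > 0:
        sigma = np.sqrt(np.log1p(params.noise_sd**2))
        od = od * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=len(od))
    curve = GrowthCurve(
        well_id=well_id, strain=strain, condition=condition, time_h=t, od600=od
    )
    truth = DiauxicTruth(
        params=params,
        max_rate=params.mu1,
        gmr=params.true_gmr(),
        od_trough=params.od_trough,
        trough_rate=params.trough_rate,
        crossing_time=params.crossing_time,
    )
    return curve, truth


# ---------------------------------------------------------------------------
# censored lag tables


def gen_lag_table(
    spec: LagSpec,
    n: int,
    horizon_h: float = 20.0,
    seed: int | None = None,
    strain: str = "synthetic",
    covariate_name: str | None = None,
    hazard_ratio: float = 1.0,
    covariate_frac: float = 0.5,
) -> pd.DataFrame:
    """Censored single-cell lag table with known generating distribution.

    Viable cells draw a lag from ``spec``; lags beyond ``horizon_h`` and
    non-viable cells (share ``1 - spec.viable_frac``) are emitted censored
    at the horizon.  When ``covariate_name`` is given, a binary covariate
    is attached and carrier cells (share ``covariate_frac``) have their
    lags transformed to satisfy proportional hazards with the given hazard
    ratio, ``S1(t) = S0(t)**hazard_ratio`` — the exact ground truth for Cox
    recovery tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    group = np.zeros(n, dtype=int)
    if covariate_name is not None:
        group = (rng.random(n) < covariate_frac).astype(int)
        # inverse-CDF under proportional hazards: S(t) = S0(t)**HR
        u_eff = np.where(group == 1, 1.0 - (1.0 - u) ** (1.0 / hazard_ratio), u)
    else:
        u_eff = u
    tau = spec.ppf(u_eff)
    viable = rng.random(n) < spec.viable_frac
    event = viable & (tau <= horizon_h)
    lag = np.where(event, tau, horizon_h)
    lag = np.maximum(lag, 1e-6)  # lag_h must be strictly positive
    table = pd.DataFrame(
        {
            "cell_id": [f"{strain}_{i:05d}" for i in range(n)],
            "strain": strain,
            "lag_h": lag,
            "event": event.astype(int),
        }
    )
    if covariate_name is not None:
        table[covariate_name] = group
    return table


# ---------------------------------------------------------------------------
# competition counts


def gen_competition_counts(
    strains: Sequence[StrainParams],
    schedule: EnvSchedule,
    init_props: Sequence[float],
    error_rates: ErrorRates | None = None,
    n_events: int | None = 50_000,
    observe_every_h: float = 4.0,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimResult]:
    """Labelled count table sampled from a simulated two-strain competition.

    Runs :func:`simulate_schedule`, then at each observation time draws
    ``n_events`` label counts multinomially from the true proportions,
    pushes them through the forward misclassification model, and attaches
    the true total population size as plating density.  ``n_events=None``
    is the infinite-event limit: expected (real-valued) counts with no
    sampling noise.  Returns the table and the underlying simulation.
    """
    if len(strains) != 2:
        raise ValueError("count tables are defined for two competitors")
    if config is None:
        config = SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    sim = simulate_schedule(strains, schedule, init_props, config)
    obs_times = np.arange(0.0, sim.time_h[-1] + 1e-9, observe_every_h)
    rows = []
    scale = 50_000 if n_events is None else n_events
    for t_obs in obs_times:
        i = int(np.argmin(np.abs(sim.time_h - t_obs)))
        p_q = float(sim.p[i, 0])
        if n_events is None:
            q, r = scale * p_q, scale * (1.0 - p_q)
        else:
            q = float(rng.binomial(n_events, p_q))
            r = float(n_events - q)
        if error_rates is not None:
            if n_events is None:
                q, r = confusion_forward(q, r, error_rates)
            else:
                # each true event misclassified independently
                q_flip = rng.binomial(int(q), error_rates.e_rq)
                r_flip = rng.binomial(int(r), error_rates.e_qr)
                q, r = q - q_flip + r_flip, r - r_flip + q_flip
        rows.append(
            {
                "time_h": float(sim.time_h[i]),
                "count_query": q,
                "count_reference": r,
                "total_density": float(sim.N[i].sum()),
            }
        )
    return pd.DataFrame(rows), sim


# ---------------------------------------------------------------------------
# ON/OFF switching series


def gen_on_fraction(
    a: float,
    b: float,
    f0_on: float = 0.95,
    f0_off: float = 0.05,
    generations: int = 10,
    n_cells: int | None = 10_000,
    seed: int | None = None,
) -> tuple[OnFractionSeries, OnFractionSeries]:
    """Paired hysteresis series from the two-state switching chain.

    Iterates ``f <- f(1-a) + (1-f)b`` per generation from both starting
    conditions.  With finite ``n_cells`` each generation's realised ON
    fraction is a binomial draw (measurement + population sampling noise);
    ``n_cells=None`` returns the deterministic chain.
    """
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise ValueError("a and b must be probabilities")
    rng = np.random.default_rng(seed)
    series = []
    for label, f0 in (("ON-pregrown", f0_on), ("OFF-pregrown", f0_off)):
        f = np.empty(generations + 1)
        f[0] = f0
        for t in range(generations):
            target = f[t] * (1.0 - a) + (1.0 - f[t]) * b
            f[t + 1] = (
                target if n_cells is None else rng.binomial(n_cells, target) / n_cells
            )
        series.append(
            OnFractionSeries(
                initial_condition=label,
                generations=np.arange(generations + 1, dtype=float),
                frac_on=f,
            )
        )
    return series[0], series[1]


# ---------------------------------------------------------------------------
# archetype strains and panels


def archetype_pair() -> tuple[StrainParams, StrainParams]:
    """Illustrative generalist/specialist competitor pair.

    A short-lag "carbon generalist" (normal lags around 2.5 h) versus a
    glucose "specialist" growing ~28% faster in glucose but entering
    maltose with long, heterogeneous uniform lags.  The parameters are
    archetypes chosen to span the observed phenotype space; they are not a
    fit to any particular strain.
    """
    generalist = StrainParams(
        name="generalist",
        mu_glucose=0.35,
        mu_maltose=0.30,
        lag=LagSpec("normal", (2.5, 1.0), viable_frac=0.97),
    )
    specialist = StrainParams(
        name="specialist",
        mu_glucose=0.45,  # ~28% faster than the generalist in glucose
        mu_maltose=0.30,
        lag=LagSpec("uniform", (2.0, 24.0), viable_frac=0.92),
    )
    return generalist, specialist


def strain_panel(
    n_strains: int = 18, seed: int | None = 0
) -> list[dict]:
    """Panel of synthetic strains spanning the lag/MaxR trade-off.

    Strains interpolate from short-lag/low-MaxR generalists to
    long-lag/high-MaxR specialists, with lag-time SD increasing with mean
    lag (heterogeneity grows with lag length) and deeper/longer growth-rate
    troughs for longer-lag strains.  Each entry carries a name, per-well
    :class:`DiauxicParams` for the variable-media condition, a
    :class:`LagSpec` and the viable fraction — enough to generate every
    input type for property tests.
    """
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_strains):
        s = i / max(n_strains - 1, 1)  # 0 = generalist .. 1 = specialist
        mean_lag = 1.5 + 14.0 * s + rng.normal(0, 0.4)
        mean_lag = max(mean_lag, 0.5)
        sd_lag = 0.25 * mean_lag + rng.normal(0, 0.15)
        sd_lag = max(sd_lag, 0.1)
        mu1 = 0.35 + 0.15 * s + rng.normal(0, 0.01)
        trough = max(0.015, mu1 * (0.55 - 0.5 * s))
        params = DiauxicParams(
            od0=0.05,
            mu1=mu1,
            mu2=max(0.12, mu1 * 0.5),
            od_shift=0.30,
            trough_rate=trough,
            trough_width=0.6 + 0.9 * s,
            od_stationary=1.5,
            noise_sd=0.01,
        )
        panel.append(
            {
                "name": f"syn{i:02d}",
                "diauxic": params,
                "lag": LagSpec("normal", (mean_lag, sd_lag), viable_frac=1.0 - 0.25 * s),
            }
        )
    return panel
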