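"""ON/OFF expression-state dynamics: hysteresis, switching rates, production.

Maltose-gene (MAL) expression in a glucose/maltose mixture is bistable:
whether a culture is induced depends on its history.  A population is
summarised by its fraction of ON cells, which evolves per generation as a
two-state Markov chain with switching probabilities ``a`` (ON -> OFF) and
``b`` (OFF -> ON):

    f[t+1] = f[t] * (1 - a) + (1 - f[t]) * b

whose closed form is ``f(g) = f_inf + (f0 - f_inf) * lam**g`` with
stationary fraction ``f_inf = b / (a + b)`` and per-generation memory
``lam = 1 - a - b``.  Two cultures started from opposite histories
(ON-pregrown versus OFF-pregrown) measured at a common generation count
give two equations that identify ``(a, b)``.

The module also provides the dilution null for per-cell protein signal —
``f0 * 2**-g``, the decay expected from growth dilution alone with zero
synthesis — and the net protein production per generation in excess of
that null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "OnFractionSeries",
    "SwitchRates",
    "dilution_null",
    "production_rate",
    "estimate_switch_rates",
    "fit_switch_rates_lsq",
    "forward_on_fraction",
    "switch_rate_se",
]


@dataclass
class OnFractionSeries:
    """ON-cell fraction versus generations for one starting condition.

    ``initial_condition`` is ``"ON-pregrown"`` or ``"OFF-pregrown"``;
    ``generations`` must be increasing and start at 0 (the measurement at
    mixing time), fractions in [0, 1].
    """

    initial_condition: str
    generations: np.ndarray
    frac_on: np.ndarray

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.frac_on = np.asarray(self.frac_on, dtype=float)
        if self.generations.shape != self.frac_on.shape or self.generations.ndim != 1:
            raise ValueError("generations and frac_on must be 1-D and equally long")
        if len(self.generations) < 1 or np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must be increasing")
        if self.generations[0] != 0:
            raise ValueError("series must include the initial point at generation 0")
        if np.any((self.frac_on < 0) | (self.frac_on > 1)):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SwitchRates:
    """Per-generation switching probabilities and derived quantities."""

    a: float  # ON -> OFF
    b: float  # OFF -> ON
    residual: float = 0.0

    @property
    def lam(self) -> float:
        """Per-generation memory 1 - a - b (eigenvalue of the chain)."""
        return 1.0 - self.a - self.b

    @property
    def f_stationary(self) -> float:
        if self.a + self.b == 0:
            return float("nan")
        return self.b / (self.a + self.b)


def dilution_null(f0: float, g: "float | np.ndarray") -> "float | np.ndarray":
    """Signal expected from pure growth dilution: ``f0 * 2**-g``.

    The null model for a culture that had its genes ON and then switched
    them fully OFF: per-cell protein halves every generation with no new
    synthesis.
    """
    if np.any(np.asarray(f0) < 0) or np.any(np.asarray(g) < 0):
        raise ValueError("signal and generations must be non-negative")
    return f0 * 2.0 ** (-np.asarray(g, dtype=float)) if np.ndim(g) else f0 * 2.0 ** (-g)


def production_rate(series: pd.DataFrame) -> float:
    """Protein produced per generation over the final two time points.

    ``series`` has columns ``generations`` and ``mean_signal``.  With the
    final two points (g1, F1), (g2, F2), production is the observed signal
    minus the dilution-null expectation, per generation:
    ``(F2 - F1 * 2**-(g2-g1)) / (g2 - g1)``.  Zero means synthesis exactly
    absent; a constant signal across one generation implies production F/2
    (synthesis exactly balancing dilution).
    """
    if len(series) < 2:
        raise ValueError("need at least two time points")
    tail = series.sort_values("generations").iloc[-2:]
    (g1, f1), (g2, f2) = tail[["generations", "mean_signal"]].to_numpy(dtype=float)
    if g2 == g1:
        raise ValueError("final two points share the same generation count")
    return float((f2 - f1 * 2.0 ** (-(g2 - g1))) / (g2 - g1))


def forward_on_fraction(a: float, b: float, f0: float, generations: int) -> np.ndarray:
    """Iterate the two-state chain; returns fractions at g = 0..generations."""
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise ValueError("a and b must be probabilities")
    f = np.empty(generations + 1)
    f[0] = f0
    for t in range(generations):
        f[t + 1] = f[t] * (1.0 - a) + (1.0 - f[t]) * b
    return f


def _endpoints(series: OnFractionSeries) -> tuple[float, float, float]:
    return float(series.frac_on[0]), float(series.frac_on[-1]), float(series.generations[-1])


def estimate_switch_rates(
    on_series: OnFractionSeries, off_series: OnFractionSeries
) -> SwitchRates:
    """Identify (a, b) from a paired hysteresis experiment.

    Uses only the initial and final points of each series, which must share
    the final generation count g.  From the closed form, the gap between
    the two trajectories decays as ``lam**g``, so

        lam = (gap_g / gap_0) ** (1/g)

    and the stationary fraction follows from either trajectory; then
    ``a = (1 - lam) * (1 - f_inf)`` and ``b = (1 - lam) * f_inf``, clipped
    to [0, 1].  If both series are flat the chain is frozen (a = b = 0).
    """
    f0_on, fg_on, g_on = _endpoints(on_series)
    f0_off, fg_off, g_off = _endpoints(off_series)
    if g_on != g_off:
        raise ValueError("series must share a common final generation count")
    g = g_on
    if g == 0:
        raise ValueError("final generation count must be positive")
    gap0 = f0_on - f0_off
    gapg = fg_on - fg_off
    if abs(gap0) < 1e-12:
        if abs(fg_on - f0_on) < 1e-12 and abs(fg_off - f0_off) < 1e-12:
            return SwitchRates(a=0.0, b=0.0)
        raise ValueError("initial conditions coincide; (a, b) not identifiable")
    ratio = gapg / gap0
    if abs(fg_on - f0_on) < 1e-12 and abs(fg_off - f0_off) < 1e-12:
        return SwitchRates(a=0.0, b=0.0)
    if ratio <= 0:
        raise ValueError(
            f"trajectory gap ratio {ratio:.3g} admits no memory lam in (0, 1]; "
            "series are inconsistent with a two-state chain"
        )
    lam = ratio ** (1.0 / g)
    if lam > 1.0 + 1e-9:
        raise ValueError(
            f"implied lam = {lam:.4f} > 1: the hysteresis gap grows with "
            "generations, inconsistent with a two-state chain"
        )
    lam = min(lam, 1.0)
    lam_g = lam**g
    if abs(1.0 - lam_g) < 1e-12:
        return SwitchRates(a=0.0, b=0.0)
    f_inf = (fg_on - f0_on * lam_g) / (1.0 - lam_g)
    a = (1.0 - lam) * (1.0 - f_inf)
    b = (1.0 - lam) * f_inf
    a_c, b_c = float(np.clip(a, 0.0, 1.0)), float(np.clip(b, 0.0, 1.0))
    # residual: how far the fitted closed form misses the OFF-start endpoint
    pred_off = f_inf + (f0_off - f_inf) * lam_g
    return SwitchRates(a=a_c, b=b_c, residual=float(abs(pred_off - fg_off)))


def fit_switch_rates_lsq(
    on_series: OnFractionSeries, off_series: OnFractionSeries
) -> SwitchRates:
    """Least-squares (a, b) fit using every point of both series.

    Minimises squared residuals of the closed form
    ``f(g) = f_inf + (f0 - f_inf) * lam**g`` across all measurements;
    useful when more than two time points per series exist.
    """

    def resid(theta: np.ndarray) -> np.ndarray:
        a, b = theta
        lam = 1.0 - a - b
        s = a + b
        out = []
        for series in (on_series, off_series):
            f0 = series.frac_on[0]
            f_inf = b / s if s > 0 else f0
            pred = f_inf + (f0 - f_inf) * np.sign(lam) * np.abs(lam) ** series.generations
            out.append(series.frac_on - pred)
        return np.concatenate(out)

    start = estimate_switch_rates(on_series, off_series)
    x0 = np.clip([start.a, start.b], 1e-6, 1 - 1e-6)
    sol = least_squares(resid, x0=x0, bounds=([0.0, 0.0], [1.0, 1.0]))
    return SwitchRates(
        a=float(sol.x[0]), b=float(sol.x[1]), residual=float(np.sqrt(2 * sol.cost))
    )


def switch_rate_se(
    rates: SwitchRates,
    f0_on: float,
    f0_off: float,
    g: float,
    n_cells: int,
    per_generation_sampling: bool = True,
) -> tuple[float, float]:
    """Delta-method standard errors of (a, b) under binomial sampling.

    With ``per_generation_sampling`` (the forward model of the synthetic
    generator: a binomial draw of the realised ON fraction every
    generation), the variance of the final fraction accumulates along the
    chain, ``V_{t+1} = lam**2 V_t + f_t (1 - f_t) / n``; otherwise each
    measured fraction carries a single binomial variance
    ``f (1 - f) / n``.  The SEs propagate those variances through the
    endpoint estimator by numerical differentiation.  The generation-0
    fractions are the known starting conditions and carry no noise under
    per-generation sampling.
    """
    a, b, lam = rates.a, rates.b, rates.lam
    lam_g = lam**g

    def _path_var(f0: float) -> tuple[float, float]:
        f, var = f0, 0.0
        for _ in range(int(round(g))):
            f_next = f * (1.0 - a) + (1.0 - f) * b
            var = lam**2 * var + f_next * (1.0 - f_next) / n_cells
            f = f_next
        return f, var

    fg_on, v_on = _path_var(f0_on)
    fg_off, v_off = _path_var(f0_off)
    x = np.array([f0_on, fg_on, f0_off, fg_off])

    def est(xv: np.ndarray) -> np.ndarray:
        on = OnFractionSeries("ON-pregrown", [0.0, g], [xv[0], xv[1]])
        off = OnFractionSeries("OFF-pregrown", [0.0, g], [xv[2], xv[3]])
        r = estimate_switch_rates(on, off)
        return np.array([r.a, r.b])

    jac = np.empty((2, 4))
    h = 1e-6
    for k in range(4):
        xp, xm = x.copy(), x.copy()
        xp[k] = min(xp[k] + h, 1.0)
        xm[k] = max(xm[k] - h, 0.0)
        jac[:, k] = (est(xp) - est(xm)) / (xp[k] - xm[k])
    if per_generation_sampling:
        var_x = np.array([0.0, v_on, 0.0, v_off])
    else:
        var_x = x * (1.0 - x) / n_cells
    var_ab = jac**2 @ var_x
    return float(np.sqrt(var_ab[0])), float(np.sqrt(var_ab[1]))
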