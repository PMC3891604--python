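"""Population-level fitness metrics from plate-reader OD600 growth curves.

A microbial culture shifting from glucose to a less-preferred carbon source
(maltose, galactose) shows biphasic ("diauxic") growth: fast exponential
growth on glucose, a deceleration as glucose runs out, a growth-rate trough
(the population-level lag phase), and re-acceleration on the second carbon
source.  This module quantifies that trajectory with four metrics:

* **MaxR** — maximal specific growth rate on glucose: the slope of an
  ordinary least-squares fit of ln(OD) versus time over the early OD band
  (0.15–0.30 by default).
* **GMR** — geometric-mean growth rate across the shift: ``ln(od_hi/od_lo)``
  divided by the interpolated time the culture spends between the OD bounds
  (0.15–0.75 by default), i.e. the average specific growth rate over the
  interval that spans the whole carbon transition.
* **minimal growth rate** and the OD at which it occurs — the depth and
  position of the lag trough on the rate-versus-OD profile.  A minimum
  sitting at the upper OD bound flags "no lag phase".
* **fitness variability** — the MaxR-normalised GMR in stable glucose
  divided by the geometric mean of the normalised GMRs in the three
  variable-media conditions; a generalist-versus-specialist index (> 1
  means fitness drops in variable media).

Rates are per hour throughout; OD is dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import BSpline, PchipInterpolator, make_smoothing_spline
from scipy.optimize import brentq
from scipy.stats import linregress

__all__ = [
    "GrowthCurve",
    "RateProfile",
    "GrowthSummary",
    "VariabilityMetrics",
    "LagLocus",
    "smooth_and_differentiate",
    "max_rate",
    "gmr",
    "crossing_time",
    "lag_locus",
    "windowed_mean_rate",
    "summarize_curve",
    "fitness_variability",
    "resample_variability",
    "CONDITIONS",
]

#: Condition labels of the four-medium panel: high glucose (stable) and the
#: three variable media that force a diauxic shift.
CONDITIONS = ("HG", "LG", "LG+Mal", "LG+Gal")

_VARIABLE_CONDITIONS = ("LG", "LG+Mal", "LG+Gal")


@dataclass
class GrowthCurve:
    """One well's OD600 time series.

    Parameters
    ----------
    well_id, strain, condition
        Labels; ``condition`` is conventionally one of ``HG``, ``LG``,
        ``LG+Mal``, ``LG+Gal`` but free text is accepted.
    time_h
        Strictly increasing sampling times in hours.
    od600
        Positive optical densities, same length as ``time_h``.
    calibration
        Optional affine OD -> density calibration ``(slope, intercept)``
        applied on access through :meth:`density`; metrics operate on raw OD.
    """

    well_id: str
    strain: str
    condition: str
    time_h: np.ndarray
    od600: np.ndarray
    calibration: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.time_h.ndim != 1 or self.time_h.shape != self.od600.shape:
            raise ValueError("time_h and od600 must be 1-D and equally long")
        if len(self.time_h) < 10:
            raise ValueError("growth curve needs at least 10 samples")
        if not np.all(np.diff(self.time_h) > 0):
            raise ValueError("time_h must be strictly increasing")
        if not np.all(self.od600 > 0):
            raise ValueError("od600 must be positive everywhere")

    def density(self) -> np.ndarray:
        """OD mapped through the affine calibration (identity if none)."""
        if self.calibration is None:
            return self.od600.copy()
        a, b = self.calibration
        return a * self.od600 + b


@dataclass
class RateProfile:
    """Smoothed OD and instantaneous specific growth rate on the time grid.

    ``mu`` is d ln(od_smooth)/dt in 1/h, evaluated analytically from the
    smoothing-spline interpolant.
    """

    time_h: np.ndarray
    od_smooth: np.ndarray
    mu: np.ndarray


@dataclass
class LagLocus:
    """Depth and position of the growth-rate trough.

    ``no_lag`` is set when the minimum sits at the upper OD bound, i.e. the
    rate profile is monotone over the analysis band and no trough exists.
    """

    min_rate: float
    od_at_min: float
    no_lag: bool = False

    def __iter__(self):  # allow tuple unpacking
        return iter((self.min_rate, self.od_at_min))


@dataclass
class GrowthSummary:
    """Per-well growth metrics (see module docstring for definitions)."""

    max_rate: float
    gmr: float
    gmr_norm: float
    t_lo: float
    t_hi: float
    min_rate: float
    od_at_min: float
    window_rates: dict[tuple[float, float], float] = field(default_factory=dict)


@dataclass
class VariabilityMetrics:
    """Fitness-variability statistic and its resampling spread."""

    per_condition_rel_gmr: dict[str, float]
    fitness_variability: float
    fitness_variability_sd: float | None = None


# ---------------------------------------------------------------------------
# smoothing


def _spar_to_lam(spar: float, x: np.ndarray) -> float:
    """Map a (0, 1] smoothing parameter to a roughness-penalty weight.

    Uses the classic smoothing-spline convention: with abscissae scaled to
    [0, 1], ``lam = r * 256**(3*spar - 1)`` where ``r`` balances the traces
    of the data-fit and roughness Gram matrices of the cubic B-spline basis
    with knots at the data points.  ``spar`` near 0 interpolates; near 1
    smooths heavily.
    """
    n = len(x)
    # B-spline basis with knots at every point, clamped cubic boundary
    t = np.concatenate(([x[0]] * 4, x[1:-1], [x[-1]] * 4))
    design = BSpline.design_matrix(x, t, 3)
    tr_xtx = design.power(2).sum()
    # tr(Omega): sum over basis functions of the integral of (B_i'')^2.
    # B'' is piecewise linear, so 2-point Gauss-Legendre per knot interval
    # integrates it exactly.
    nb = len(t) - 4
    gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    lo, hi = x[:-1], x[1:]
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    pts = (mid[:, None] + half[:, None] * gl_x[None, :]).ravel()
    w = np.repeat(half, 2)
    coef = np.eye(nb)
    d2 = np.empty((len(pts), nb))
    for i in range(nb):
        d2[:, i] = BSpline(t, coef[i], 3).derivative(2)(pts)
    tr_omega = float(np.sum(w[:, None] * d2**2))
    r = tr_xtx / max(tr_omega, 1e-300)
    return float(r * 256.0 ** (3.0 * spar - 1.0))


def smooth_and_differentiate(curve: GrowthCurve, smoothing: float = 0.35) -> RateProfile:
    """Smooth OD versus time and differentiate the log of the smooth fit.

    A cubic smoothing spline is fitted to OD versus time (abscissae scaled
    to [0, 1]); the specific growth rate is the analytic derivative of the
    interpolant divided by the smoothed OD, ``mu = od'(t) / od(t)``, which
    equals d ln(od)/dt.

    Parameters
    ----------
    curve
        Validated growth curve.
    smoothing
        Smoothing parameter in (0, 1]; 0.35 is the plate-reader default
        (moderate smoothing that leaves a noiseless exponential unbiased).

    Returns
    -------
    RateProfile
        Smoothed OD and instantaneous rate on the curve's own time grid.
    """
    if not (0.0 < smoothing <= 1.0):
        raise ValueError("smoothing parameter must be in (0, 1]")
    t = curve.time_h
    span = t[-1] - t[0]
    s = (t - t[0]) / span  # scale-free abscissa
    lam = _spar_to_lam(smoothing, s)
    spl = make_smoothing_spline(s, curve.od600, lam=lam)
    od_smooth = spl(s)
    if np.any(od_smooth <= 0):
        raise ValueError("smoothed OD non-positive; reduce smoothing")
    mu = spl.derivative()(s) / od_smooth / span
    return RateProfile(time_h=t.copy(), od_smooth=od_smooth, mu=mu)


# ---------------------------------------------------------------------------
# band metrics


def max_rate(curve: GrowthCurve, od_lo: float = 0.15, od_hi: float = 0.30) -> float:
    """Maximal specific growth rate (MaxR), in 1/h.

    Ordinary least-squares slope of ln(OD) versus time over all raw samples
    with ``od_lo <= OD <= od_hi`` (the early, glucose-fuelled OD band).
    """
    mask = (curve.od600 >= od_lo) & (curve.od600 <= od_hi)
    if mask.sum() < 3:
        raise ValueError(
            f"fewer than 3 samples in OD band [{od_lo}, {od_hi}]; "
            "cannot fit MaxR regression"
        )
    res = linregress(curve.time_h[mask], np.log(curve.od600[mask]))
    return float(res.slope)


def crossing_time(
    time_h: np.ndarray, od: np.ndarray, bound: float, window: int = 3
) -> float:
    """Interpolated time at which OD first crosses ``bound`` upward.

    Uses monotone piecewise-cubic (PCHIP) interpolation restricted to a
    bracketing window of ``window`` samples either side of the crossing,
    which is robust to non-monotone plateau noise.  If OD crosses the bound
    upward more than once (settling/evaporation artifacts) the first
    crossing is used and a warning issued.
    """
    time_h = np.asarray(time_h, dtype=float)
    od = np.asarray(od, dtype=float)
    up = np.flatnonzero((od[:-1] < bound) & (od[1:] >= bound))
    if len(up) == 0:
        if od[0] >= bound:
            raise ValueError(f"curve starts above OD bound {bound}")
        raise ValueError(f"curve never reaches OD bound {bound}")
    if len(up) > 1:
        warnings.warn(
            f"OD crosses {bound} upward {len(up)} times; using first crossing",
            stacklevel=2,
        )
    i = int(up[0])
    lo = max(0, i - window + 1)
    hi = min(len(od), i + window + 1)
    seg_t, seg_od = time_h[lo:hi], od[lo:hi]
    # PCHIP needs strictly increasing ordinates only on the abscissa (time),
    # which the curve guarantees.
    interp = PchipInterpolator(seg_t, seg_od)
    if abs(od[i] - bound) < 1e-15:
        return float(time_h[i])
    if abs(od[i + 1] - bound) < 1e-15:
        return float(time_h[i + 1])
    return float(brentq(lambda x: float(interp(x)) - bound, time_h[i], time_h[i + 1]))


def gmr(
    curve: GrowthCurve,
    od_lo: float = 0.15,
    od_hi: float = 0.75,
    od: np.ndarray | None = None,
) -> float:
    """Geometric-mean growth rate ``ln(od_hi/od_lo) / (t_hi - t_lo)``, in 1/h.

    ``t_lo`` and ``t_hi`` are the interpolated first upward crossings of the
    two OD bounds.  Pass ``od`` (e.g. the smoothed OD from
    :func:`smooth_and_differentiate`) to locate crossings on a denoised
    trace; by default the raw readings are used.
    """
    series = curve.od600 if od is None else np.asarray(od, dtype=float)
    t_lo = crossing_time(curve.time_h, series, od_lo)
    t_hi = crossing_time(curve.time_h, series, od_hi)
    if t_hi <= t_lo:
        raise ValueError("upper OD bound crossed before lower bound")
    return float(np.log(od_hi / od_lo) / (t_hi - t_lo))


def lag_locus(
    profile: RateProfile, od_lo: float = 0.15, od_hi: float = 0.75
) -> LagLocus:
    """Minimal specific growth rate over the OD band and the OD where it sits.

    A minimum located at the upper bound means the rate profile is monotone
    across the band — there is no lag trough — and is flagged ``no_lag``
    with ``od_at_min`` reported as ``od_hi``.
    """
    mask = (profile.od_smooth >= od_lo) & (profile.od_smooth <= od_hi)
    if mask.sum() < 3:
        raise ValueError(f"rate profile does not span OD band [{od_lo}, {od_hi}]")
    od_band = profile.od_smooth[mask]
    mu_band = profile.mu[mask]
    k = int(np.argmin(mu_band))
    min_rate = float(mu_band[k])
    od_at_min = float(od_band[k])
    # no trough when the minimum sits on the band's upper edge (monotone
    # deceleration) or is not meaningfully below the rate at the upper bound
    # (flat profile, e.g. pure exponential growth)
    at_edge = k == len(mu_band) - 1 or od_at_min >= od_hi * 0.999
    flat = min_rate >= 0.95 * float(mu_band[-1]) - 1e-3
    no_lag = at_edge or flat
    if no_lag:
        od_at_min = od_hi
    return LagLocus(min_rate=min_rate, od_at_min=od_at_min, no_lag=no_lag)


def windowed_mean_rate(
    profile: RateProfile,
    doublings_before: float,
    doublings_after: float,
    od_lo: float = 0.15,
    od_hi: float = 0.75,
) -> float:
    """Average specific growth rate over a window centred on the lag trough.

    The window is the OD interval ``[od_min * 2**-doublings_before,
    od_min * 2**doublings_after]`` clipped to the analysis band, where
    ``od_min`` is the OD at the minimal growth rate.  The average is the
    time-average of mu between the interpolated window-endpoint times, i.e.
    ``ln(od_right/od_left) / (t_right - t_left)`` — the GMR restricted to
    the window.  The degenerate zero-width window returns the minimal rate
    itself.  When no trough exists the locus sits at the band's upper bound
    and the window extends downward from there.
    """
    locus = lag_locus(profile, od_lo=od_lo, od_hi=od_hi)
    if doublings_before == 0 and doublings_after == 0:
        return locus.min_rate
    od_left = max(locus.od_at_min * 2.0 ** (-doublings_before), od_lo)
    od_right = min(locus.od_at_min * 2.0 ** (doublings_after), od_hi)
    in_window = (profile.od_smooth >= od_left) & (profile.od_smooth <= od_right)
    if in_window.sum() < 2:
        raise ValueError(
            f"window OD [{od_left:.3g}, {od_right:.3g}] holds fewer than 2 samples"
        )
    t_left = crossing_time(profile.time_h, profile.od_smooth, od_left)
    t_right = crossing_time(profile.time_h, profile.od_smooth, od_right)
    return float(np.log(od_right / od_left) / (t_right - t_left))


_DEFAULT_WINDOWS = ((0.1, 0.1), (0.5, 0.1), (1.0, 0.1))


def summarize_curve(
    curve: GrowthCurve,
    smoothing: float = 0.35,
    maxr_band: tuple[float, float] = (0.15, 0.30),
    gmr_band: tuple[float, float] = (0.15, 0.75),
    windows: Sequence[tuple[float, float]] = _DEFAULT_WINDOWS,
) -> GrowthSummary:
    """Compute all per-well metrics in one pass.

    Crossing times for the GMR are located on the smoothed OD trace.
    Window rates that are undefined (no trough, or too-narrow window) are
    reported as NaN rather than raising.
    """
    profile = smooth_and_differentiate(curve, smoothing=smoothing)
    mr = max_rate(curve, *maxr_band)
    lo, hi = gmr_band
    t_lo = crossing_time(curve.time_h, profile.od_smooth, lo)
    t_hi = crossing_time(curve.time_h, profile.od_smooth, hi)
    g = float(np.log(hi / lo) / (t_hi - t_lo))
    locus = lag_locus(profile, lo, hi)
    window_rates: dict[tuple[float, float], float] = {}
    for before, after in windows:
        try:
            window_rates[(before, after)] = windowed_mean_rate(
                profile, before, after, lo, hi
            )
        except ValueError:
            window_rates[(before, after)] = float("nan")
    return GrowthSummary(
        max_rate=mr,
        gmr=g,
        gmr_norm=g / mr,
        t_lo=t_lo,
        t_hi=t_hi,
        min_rate=locus.min_rate,
        od_at_min=locus.od_at_min,
        window_rates=window_rates,
    )


# ---------------------------------------------------------------------------
# fitness variability


def _rel_gmr(value) -> float:
    return float(value.gmr_norm) if isinstance(value, GrowthSummary) else float(value)


def fitness_variability(summaries: Mapping[str, "GrowthSummary | float"]) -> VariabilityMetrics:
    """Generalist-versus-specialist index from the four-condition panel.

    The statistic is the MaxR-normalised GMR (``gmr_norm``) in stable
    glucose (HG) divided by the geometric mean of the normalised GMRs in
    the three variable media (LG, LG+Mal, LG+Gal).  Values above 1 mean the
    strain's fitness drops in variable media.  ``summaries`` maps condition
    labels to either :class:`GrowthSummary` objects or bare relative-GMR
    numbers.
    """
    missing = [c for c in CONDITIONS if c not in summaries]
    if missing:
        raise ValueError(f"missing condition(s): {', '.join(missing)}")
    rel = {c: _rel_gmr(summaries[c]) for c in CONDITIONS}
    if any(v <= 0 for v in rel.values()):
        bad = [c for c, v in rel.items() if v <= 0]
        raise ValueError(
            f"relative GMR must be positive for a geometric mean; got <= 0 in {bad}"
        )
    geo = float(np.exp(np.mean([np.log(rel[c]) for c in _VARIABLE_CONDITIONS])))
    return VariabilityMetrics(
        per_condition_rel_gmr=rel, fitness_variability=rel["HG"] / geo
    )


def resample_variability(
    replicates: Mapping[str, Sequence["GrowthSummary | float"]],
    n_resamples: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Resampling mean and SD of the fitness-variability statistic.

    Each resample draws one biological replicate uniformly at random per
    condition and recomputes :func:`fitness_variability`; the mean and
    standard deviation over ``n_resamples`` draws quantify how replicate
    scatter propagates into the statistic.
    """
    missing = [c for c in CONDITIONS if c not in replicates or not len(replicates[c])]
    if missing:
        raise ValueError(f"missing replicate(s) for condition(s): {', '.join(missing)}")
    rng = np.random.default_rng(seed)
    pools = {c: [_rel_gmr(v) for v in replicates[c]] for c in CONDITIONS}
    values = np.empty(n_resamples)
    for i in range(n_resamples):
        draw = {c: pools[c][rng.integers(len(pools[c]))] for c in CONDITIONS}
        values[i] = fitness_variability(draw).fitness_variability
    return float(values.mean()), float(values.std(ddof=0))
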