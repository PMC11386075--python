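"""Time-of-wetness growth kinetics.

The time-of-wetness (ToW) framework models microbial growth in dust under a
daily relative-humidity cycle: the substrate spends ``wet_hours_per_day``
hours above an 80% equilibrium-relative-humidity (ERH) threshold and the
remainder below it. Growth under constant wet exposure proceeds at an
intrinsic exponential rate ``k`` (day⁻¹); under cycling, the effective rate
``R`` depends on how the organism responds to re-wetting and drying:

* **activation-limited** — each re-wetting incurs a lag ``t_act`` hours
  before growth resumes, so R/k falls below proportionality to ToW;
* **deactivation-limited** — growth persists ``t_deact`` hours into each dry
  period, so R/k exceeds proportionality;
* **proportional** — R/k equals the wet time fraction.

The daily effective growing hours are

    g = t_w                                        if t_w = 24 (no cycling)
    g = 0                                          if max(0, t_w − t_act) = 0
    g = min(24, (t_w − t_act) + min(24 − t_w, t_deact))   otherwise

so that R = k·g/24 and the constant (24 h/day) condition always realises its
own k. The activation lag is only paid when the substrate actually re-wets
each day, and dry-period persistence requires that growth activated at all.

The one-parameter model families fitted to observed (t_w, R/k) points are

    activation:    R/k = max(0, t_w − t_a) / 24
    deactivation:  R/k = min(24, t_w + t_d) / 24

with the parameter bounded to [0, 24] hours; the family with the smaller sum
of squared residuals is reported, and a fit with both optima essentially at
zero collapses to the proportional line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _spstats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "ERHSchedule",
    "GrowthParams",
    "GrowthRateEstimate",
    "TowPoint",
    "TowModelFit",
    "time_of_wetness_fraction",
    "effective_growing_hours",
    "simulate_growth",
    "estimate_growth_rate",
    "relative_growth_rate",
    "build_tow_curve",
    "fit_tow_model",
]

DEFAULT_THRESHOLD_ERH = 80.0


@dataclass(frozen=True)
class ERHSchedule:
    """One daily relative-humidity cycle.

    ``wet_erh`` holds for ``wet_hours_per_day`` hours, ``dry_erh`` for the
    rest of the day; wetness means ERH strictly above ``threshold_erh``.
    """

    wet_erh: float
    wet_hours_per_day: float
    dry_erh: float = 50.0
    threshold_erh: float = DEFAULT_THRESHOLD_ERH

    def __post_init__(self):
        if not 0.0 <= self.wet_hours_per_day <= 24.0:
            raise ValidationError("wet_hours_per_day must lie in [0, 24]")
        for name in ("wet_erh", "dry_erh"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} must lie in [0, 100]")


@dataclass(frozen=True)
class GrowthParams:
    """Kinetic parameters for one organism group under one moisture regime.

    ``k`` is the intrinsic growth rate under constant wet exposure (day⁻¹);
    ``t_act``/``t_deact`` are the activation lag and deactivation
    persistence in hours per daily cycle; ``c0`` the initial concentration
    per mg dust; ``carrying_capacity`` an optional cap.
    """

    k: float
    c0: float
    t_act: float = 0.0
    t_deact: float = 0.0
    carrying_capacity: float | None = None

    def __post_init__(self):
        if self.c0 <= 0:
            raise ValidationError("c0 must be positive")
        if self.t_act < 0 or self.t_deact < 0:
            raise ValidationError("t_act and t_deact must be >= 0")
        if self.carrying_capacity is not None and self.carrying_capacity < self.c0:
            raise ValidationError("carrying_capacity must be >= c0")


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Log-linear fitted exponential rate with its uncertainty."""

    rate: float
    stderr: float
    r_squared: float
    n_points: int
    day_window: tuple[float, float]
    n_excluded_zero: int = 0


@dataclass(frozen=True)
class TowPoint:
    """One (time elevated, relative growth) observation."""

    time_elevated: float
    relative_growth: float
    bag_id: str = "averaged"
    stderr: float = float("nan")


@dataclass(frozen=True)
class TowModelFit:
    model: str  # activation_limited | deactivation_limited | proportional | no_model
    parameter_hours: float
    sse: float
    predictions: dict = field(default_factory=dict)


def time_of_wetness_fraction(schedule: ERHSchedule) -> float:
    """Fraction of each day spent above the wetness threshold."""
    wet_above = schedule.wet_erh > schedule.threshold_erh
    dry_above = schedule.dry_erh > schedule.threshold_erh
    if wet_above and dry_above:
        return 1.0
    if not wet_above and not dry_above:
        return 0.0
    if wet_above:
        return schedule.wet_hours_per_day / 24.0
    # only the "dry" phase is above threshold
    return (24.0 - schedule.wet_hours_per_day) / 24.0


def effective_growing_hours(params: GrowthParams, schedule: ERHSchedule) -> float:
    """Growing hours per daily cycle under the activation/deactivation model."""
    t_w = 24.0 * time_of_wetness_fraction(schedule)
    if t_w <= 0.0:
        return 0.0
    if t_w >= 24.0:
        # constant wetness: no daily re-wetting, so no recurring lag
        return 24.0
    wet_g = max(0.0, t_w - params.t_act)
    if wet_g == 0.0:
        return 0.0
    dry_g = min(24.0 - t_w, params.t_deact)
    return min(24.0, wet_g + dry_g)


def effective_daily_rate(params: GrowthParams, schedule: ERHSchedule) -> float:
    """Effective exponential rate R = k·g/24 under the daily cycle (day⁻¹)."""
    return params.k * effective_growing_hours(params, schedule) / 24.0


def simulate_growth(
    params: GrowthParams,
    schedule: ERHSchedule,
    days: float,
    sample_days=None,
):
    """Deterministic piecewise-exponential trajectory under a daily ERH cycle.

    Returns a list of ``(day, concentration)`` at ``sample_days`` (default:
    integer days 0..days). Concentration is capped at the carrying capacity
    when one is set.
    """
    if days <= 0:
        raise ValidationError("days must be positive")
    if sample_days is None:
        sample_days = list(range(int(days) + 1))
    sample_days = [float(d) for d in sample_days]
    if any(d < 0 or d > days for d in sample_days):
        raise ValidationError("sample_days must lie within [0, days]")
    r = effective_daily_rate(params, schedule)
    out = []
    for d in sample_days:
        c = params.c0 * math.exp(r * d)
        if params.carrying_capacity is not None:
            c = min(c, params.carrying_capacity)
        out.append((d, c))
    return out


def estimate_growth_rate(
    series, day_window=None, trim_plateau: bool = False, trim_margin: float = 0.02
) -> GrowthRateEstimate:
    """Ordinary least squares of ln(concentration) on day.

    Zero (or negative) concentrations cannot enter the log fit; they are
    excluded and counted in ``n_excluded_zero``. With ``trim_plateau``,
    trailing days are dropped (down to 3 points) while doing so improves r²
    by at least ``trim_margin`` — populations that have reached a carrying
    capacity flatten late in the series and would bias the exponential-phase
    rate downward.
    """
    days = np.asarray([d for d, _ in series], dtype=float)
    conc = np.asarray([c for _, c in series], dtype=float)
    if day_window is not None:
        lo, hi = day_window
        keep = (days >= lo) & (days <= hi)
        days, conc = days[keep], conc[keep]
    positive = conc > 0
    n_excluded = int(np.sum(~positive))
    days, conc = days[positive], conc[positive]
    if days.size < 2 or np.unique(days).size < 2:
        raise InsufficientDataError(
            "estimate_growth_rate needs >= 2 positive points at distinct days"
        )
    order = np.argsort(days, kind="mergesort")
    days, conc = days[order], conc[order]

    def _fit(d, c):
        res = _spstats.linregress(d, np.log(c))
        r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
        se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        return float(res.slope), se, r2

    slope, stderr, r2 = _fit(days, conc)
    if trim_plateau:
        while days.size > 3 and np.unique(days[:-1]).size >= 2:
            # saturation shows as a final point below the fitted line
            last_resid = math.log(conc[-1]) - (
                np.log(conc).mean() + slope * (days[-1] - days.mean())
            )
            if last_resid >= 0:
                break
            s2, se2, r2b = _fit(days[:-1], conc[:-1])
            if r2b >= r2 + trim_margin:
                days, conc = days[:-1], conc[:-1]
                slope, stderr, r2 = s2, se2, r2b
            else:
                break
    return GrowthRateEstimate(
        rate=slope,
        stderr=stderr,
        r_squared=r2,
        n_points=int(days.size),
        day_window=(float(days.min()), float(days.max())),
        n_excluded_zero=n_excluded,
    )


def relative_growth_rate(
    effective: GrowthRateEstimate, constant: GrowthRateEstimate
) -> float:
    """R/k with negative effective rates clamped to zero.

    A negative fitted R has no interpretation on the ToW curve (growth
    cannot be negative in this framework); the raw value remains available
    on the estimate itself.
    """
    if constant.rate <= 0:
        raise ValidationError("constant-condition rate k must be positive")
    if effective.rate < 0:
        return 0.0
    return effective.rate / constant.rate


def build_tow_curve(per_bag_points: dict) -> list[TowPoint]:
    """Average per-bag R/k values at each time-elevated level.

    Returns one ``TowPoint`` per level with the across-bag arithmetic mean
    and standard error (sd/√n); a level observed in a single bag carries an
    undefined (NaN) standard error.
    """
    if not per_bag_points:
        raise ValidationError("per_bag_points must not be empty")
    by_level: dict[float, list[float]] = {}
    for _, points in per_bag_points.items():
        for p in points:
            by_level.setdefault(float(p.time_elevated), []).append(p.relative_growth)
    out = []
    for level in sorted(by_level):
        vals = np.asarray(by_level[level], dtype=float)
        se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else float("nan")
        out.append(
            TowPoint(time_elevated=level, relative_growth=float(vals.mean()),
                     bag_id="averaged", stderr=se)
        )
    return out


def _predict(model: str, t_w: np.ndarray, param: float) -> np.ndarray:
    if model == "activation_limited":
        return np.maximum(0.0, t_w - param) / 24.0
    if model == "deactivation_limited":
        return np.minimum(24.0, t_w + param) / 24.0
    raise ValueError(model)


def _best_param(model: str, t_w: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact 1-D least squares over the piecewise-linear family.

    Within each interval between sorted breakpoints the predictor is linear
    in the parameter, so the SSE is quadratic there and the interval optimum
    is closed-form; the global optimum is the best over intervals.
    """
    if model == "activation_limited":
        knots = sorted({0.0, 24.0, *[float(t) for t in t_w]})
    else:
        knots = sorted({0.0, 24.0, *[float(24.0 - t) for t in t_w]})
    best = (math.inf, 0.0)
    for lo, hi in zip(knots[:-1], knots[1:]):
        candidates = {lo, hi}
        # interior stationary point of the quadratic SSE on [lo, hi]
        mid = 0.5 * (lo + hi)
        pred_mid = _predict(model, t_w, mid)
        active = (
            (t_w > mid) if model == "activation_limited" else (t_w + mid < 24.0)
        )
        n_act = int(np.sum(active))
        if n_act:
            # d(pred)/d(param) = -1/24 (activation) or +1/24 (deactivation)
            # on the active set, 0 elsewhere
            resid_mid = y - pred_mid
            slope = (-1.0 / 24.0) if model == "activation_limited" else (1.0 / 24.0)
            # SSE'(p) = -2 * slope * sum_active(resid(p)); resid linear in p
            # resid_i(p) = resid_mid_i - slope*(p - mid) on active set
            p_star = mid + float(np.sum(resid_mid[active])) / (n_act * slope)
            if lo < p_star < hi:
                candidates.add(p_star)
        for p in candidates:
            sse = float(np.sum((y - _predict(model, t_w, p)) ** 2))
            if sse < best[0] - 1e-15:
                best = (sse, p)
    return best[1], best[0]


def fit_tow_model(
    points, tie_tolerance_hours: float = 0.5, no_model_sse: float | None = None
) -> TowModelFit:
    """Classify a ToW curve as activation- or deactivation-limited.

    Fits both one-parameter families by least squares; the family with the
    lower SSE wins. If both optimal parameters fall below
    ``tie_tolerance_hours`` the curve is proportional. When
    ``no_model_sse`` is given and the winning SSE exceeds it, the
    classification is ``"no_model"`` (used for organisms the framework does
    not describe, e.g. the bacterial fraction).
    """
    t_w = np.asarray([p.time_elevated for p in points], dtype=float)
    y = np.asarray([p.relative_growth for p in points], dtype=float)
    if np.unique(t_w).size < 2:
        raise ValidationError("fit_tow_model needs >= 2 distinct time_elevated values")
    p_act, sse_act = _best_param("activation_limited", t_w, y)
    p_deact, sse_deact = _best_param("deactivation_limited", t_w, y)
    if p_act < tie_tolerance_hours and p_deact < tie_tolerance_hours:
        model, param = "proportional", 0.0
        sse = float(np.sum((y - t_w / 24.0) ** 2))
    elif sse_act <= sse_deact:
        model, param, sse = "activation_limited", p_act, sse_act
    else:
        model, param, sse = "deactivation_limited", p_deact, sse_deact
    if no_model_sse is not None and sse > no_model_sse:
        model = "no_model"
    if model in ("proportional", "no_model"):
        pred = {float(t): float(t / 24.0) for t in sorted(set(t_w))}
    else:
        pred = {
            float(t): float(_predict(model, np.asarray([t]), param)[0])
            for t in sorted(set(t_w))
        }
    return TowModelFit(model=model, parameter_hours=float(param), sse=float(sse),
                       predictions=pred)
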