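"""Equilibrium channel geometry and a steady Manning rating curve.

Two pieces of the chain live here:

1. A downstream hydraulic-geometry ("regime") relation W = a·Q^b fitted by
   ordinary least squares on the log-log scale to surveyed bankfull widths
   and a formative discharge (here the bankfull proxy Q10). Prediction at a
   new discharge carries a log-space Student-t interval, so equilibrium
   width for a candidate reach comes with an uncertainty band.
2. A single-cross-section normal-depth rating curve: Manning's equation is
   evaluated on a surveyed station–elevation polyline and inverted by
   bisection to map discharge to stage. This stands in for a full 1D
   step-backwater model when all the chain needs is the downstream
   stage–discharge relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RegimeFit", "GeometryPrediction", "CrossSection", "RatingCurve",
    "fit_regime", "predict_width", "manning_discharge", "build_rating_curve",
]


@dataclass(frozen=True)
class RegimeFit:
    """OLS fit of ln W = ln a + b ln Q.

    ``resid_sd`` is the residual standard deviation on the log scale
    (ddof = 2); ``se_b`` the standard error of the exponent; ``x_mean`` and
    ``x_ss`` the mean and centred sum of squares of ln Q, retained so
    prediction intervals can include the leverage term.
    """

    a: float
    b: float
    r2: float
    resid_sd: float
    n: int
    se_b: float = float("nan")
    x_mean: float = float("nan")
    x_ss: float = float("nan")

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("coefficient a must be positive")
        if self.n < 3:
            raise ValueError("need at least 3 reaches")
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError("r2 out of [0, 1]")

    def exponent_ci(self, level: float = 0.90) -> tuple[float, float]:
        """Two-sided confidence interval for the exponent b."""
        t = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return self.b - t * self.se_b, self.b + t * self.se_b


@dataclass(frozen=True)
class GeometryPrediction:
    width: float
    pi_low: float
    pi_high: float
    level: float

    def __post_init__(self):
        if not (0 < self.pi_low <= self.width <= self.pi_high):
            raise ValueError("interval must bracket the width and be positive")


def fit_regime(widths: Sequence[float], discharges: Sequence[float]) -> RegimeFit:
    """Fit the width regime equation W = a·Q^b by log-log OLS."""
    w = np.asarray(widths, dtype=float)
    q = np.asarray(discharges, dtype=float)
    if w.shape != q.shape:
        raise ValueError("widths and discharges must have equal length")
    if w.size < 3:
        raise ValueError("need at least 3 reaches")
    if np.any(w <= 0) or np.any(q <= 0):
        raise ValueError("widths and discharges must be positive")
    x, y = np.log(q), np.log(w)
    if np.ptp(x) == 0:
        raise ValueError("all discharges equal: regime slope is undetermined")
    n = x.size
    x_mean = x.mean()
    sxx = float(np.sum((x - x_mean) ** 2))
    b = float(np.sum((x - x_mean) * (y - y.mean())) / sxx)
    lna = float(y.mean() - b * x_mean)
    resid = y - (lna + b * x)
    sse = float(np.sum(resid ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    s = math.sqrt(sse / (n - 2))
    return RegimeFit(
        a=math.exp(lna), b=b,
        r2=1.0 if sst == 0 else 1.0 - sse / sst,
        resid_sd=s, n=n,
        se_b=s / math.sqrt(sxx), x_mean=x_mean, x_ss=sxx,
    )


def predict_width(fit: RegimeFit | tuple, q10: float, level: float = 0.90,
                  interval: str = "prediction") -> GeometryPrediction:
    """Equilibrium width at a formative discharge, with a log-space interval.

    ``fit`` may be a :class:`RegimeFit` or a bare ``(a, b, resid_sd, n)``
    tuple (``resid_sd`` may be None, collapsing the interval to the point).
    ``interval`` selects "prediction" (new reach; includes residual
    variance) or "mean" (mean response).
    """
    if q10 <= 0:
        raise ValueError("discharge must be positive")
    if isinstance(fit, RegimeFit):
        a, b, s, n = fit.a, fit.b, fit.resid_sd, fit.n
        x_mean, x_ss = fit.x_mean, fit.x_ss
    else:
        a, b, s, n = fit
        x_mean = x_ss = float("nan")
    width = a * q10 ** b
    if s is None or (isinstance(s, float) and not s > 0):
        return GeometryPrediction(width, width, width, level)
    lev = 1.0 / n
    if math.isfinite(x_ss) and x_ss > 0:
        lev += (math.log(q10) - x_mean) ** 2 / x_ss
    var = lev if interval == "mean" else 1.0 + lev
    half = stats.t.ppf(0.5 + level / 2, n - 2) * s * math.sqrt(var)
    lw = math.log(width)
    return GeometryPrediction(width, math.exp(lw - half), math.exp(lw + half), level)


@dataclass(frozen=True)
class CrossSection:
    """Surveyed station–elevation polyline with roughness and energy slope.

    Stations must be non-decreasing (equal adjacent stations describe a
    vertical bank, which contributes wetted perimeter but no area).
    """

    stations: np.ndarray
    elevations: np.ndarray
    n_manning: float
    slope: float

    def __post_init__(self):
        st = np.asarray(self.stations, dtype=float)
        el = np.asarray(self.elevations, dtype=float)
        if st.size != el.size or st.size < 3:
            raise ValueError("need at least 3 station-elevation points")
        if np.any(np.diff(st) < 0):
            raise ValueError("stations must be non-decreasing")
        if np.ptp(st) <= 0:
            raise ValueError("cross-section has zero width")
        if self.n_manning <= 0 or self.slope <= 0:
            raise ValueError("Manning n and slope must be positive")
        object.__setattr__(self, "stations", st)
        object.__setattr__(self, "elevations", el)

    @property
    def thalweg(self) -> float:
        return float(self.elevations.min())

    @property
    def bank_top(self) -> float:
        return float(min(self.elevations[0], self.elevations[-1]))


def _wetted_geometry(xs: CrossSection, stage: float,
                     extend_walls: bool) -> tuple[float, float]:
    """Wetted area and perimeter of the polyline below ``stage``."""
    st, el = xs.stations, xs.elevations
    area = 0.0
    perim = 0.0
    for i in range(st.size - 1):
        x1, x2, z1, z2 = st[i], st[i + 1], el[i], el[i + 1]
        if z1 >= stage and z2 >= stage:
            continue
        # clip the segment to the part below the water surface
        if z1 < stage <= z2:
            frac = (stage - z1) / (z2 - z1)
            x2, z2 = x1 + frac * (x2 - x1), stage
        elif z2 < stage <= z1:
            frac = (stage - z1) / (z2 - z1)
            x1, z1 = x1 + frac * (x2 - x1), stage
        area += (stage - 0.5 * (z1 + z2)) * (x2 - x1)
        perim += math.hypot(x2 - x1, z2 - z1)
    for z_end in (el[0], el[-1]):
        if stage > z_end:
            if not extend_walls:
                raise ValueError(
                    "stage exceeds a section endpoint (overbank); "
                    "pass extend_walls=True to extend vertical walls")
            perim += stage - z_end
    return area, perim


def manning_discharge(xs: CrossSection, stage: float,
                      extend_walls: bool = False) -> float:
    """Steady uniform-flow discharge for a stage, Q = A·R^{2/3}·√S / n."""
    if stage <= xs.thalweg:
        return 0.0
    area, perim = _wetted_geometry(xs, stage, extend_walls)
    if area <= 0 or perim <= 0:
        return 0.0
    radius = area / perim
    return area * radius ** (2.0 / 3.0) * math.sqrt(xs.slope) / xs.n_manning


@dataclass(frozen=True)
class RatingCurve:
    """Monotone stage–discharge pairs at a section."""

    q: np.ndarray
    stage: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        s = np.asarray(self.stage, dtype=float)
        if q.size != s.size or q.size == 0:
            raise ValueError("q and stage must be nonempty and equal length")
        if np.any(np.diff(q) <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("rating curve must be strictly increasing")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "stage", s)

    def stage_at(self, q: float) -> float:
        return float(np.interp(q, self.q, self.stage))


def invert_stage(xs: CrossSection, q: float, extend_walls: bool = False,
                 tol: float = 1e-4) -> float:
    """Stage whose Manning discharge equals ``q``, by bisection to ``tol`` m.

    The default 0.1 mm stage tolerance keeps the round-trip discharge error
    well below 0.1% even at shallow stages.
    """
    if q <= 0:
        raise ValueError("discharge must be positive")
    lo = xs.thalweg
    hi = xs.bank_top
    if manning_discharge(xs, hi, extend_walls) < q:
        if not extend_walls:
            raise ValueError(
                f"discharge {q:g} exceeds bank-top capacity; "
                "pass extend_walls=True to extend vertical walls")
        while manning_discharge(xs, hi, True) < q:
            hi += max(hi - xs.thalweg, 1.0)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if manning_discharge(xs, mid, extend_walls) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_rating_curve(xs: CrossSection, q_values: Sequence[float],
                       extend_walls: bool = False) -> RatingCurve:
    """Invert the Manning relation at each discharge (bisection, 1 mm)."""
    q = np.asarray(q_values, dtype=float)
    if np.any(q <= 0):
        raise ValueError("discharges must be positive")
    if np.any(np.diff(q) <= 0):
        raise ValueError("discharges must be sorted strictly increasing")
    stages = np.array([invert_stage(xs, qi, extend_walls) for qi in q])
    return RatingCurve(q=q, stage=stages)
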