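"""Fickian diffusion-coefficient estimation from release asymptotics.

For one-dimensional diffusion out of a plane sheet with constant D,
the fractional release f(t) = Mt/M∞ obeys two classical asymptotic
regimes (L is the half-thickness of the sheet):

* short time (f ≲ 0.6):   f = (2/L)·√(D·t/π)
* long time  (f ≳ 0.4):   1 − f = (8/π²)·exp(−π²·D·t / (4·L²))

Each regime linearizes into a regression — f against √t through the
origin, or ln(1 − f) against t — whose slope gives D.  Times are
stored in hours and converted to seconds internally, so with L in cm
the estimates come out in cm²/s.

The total releasable amount M∞ must be supplied in the same percent
scale as the curve; :func:`resolve_m_inf` implements the two usual
policies (Gompertz-fitted plateau, or the last observed point).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .curves import ReleaseCurve
from .kinetics import ReleaseKinetics, r_squared

__all__ = [
    "DiffusionEstimate",
    "DiffusionResults",
    "PlaneSheetDiffusion",
    "estimate_D_short",
    "estimate_D_long",
    "resolve_m_inf",
]

_SECONDS_PER_HOUR = 3600.0
#: intercept of the long-time linearization for an ideal plane sheet
LONG_TIME_INTERCEPT = math.log(8.0 / math.pi**2)


@dataclass(frozen=True)
class DiffusionEstimate:
    """Diffusion coefficient from one asymptotic regime.

    ``D`` is in ``units`` (default cm²/s).  ``slope``/``intercept`` are
    the diagnostics of the underlying linear regression in seconds;
    for the long-time regime the intercept should sit near
    ln(8/π²) ≈ −0.21 if the plane-sheet model holds.
    """

    D: float
    regime: str  # "short_time" | "long_time"
    half_thickness_cm: float
    slope: float
    intercept: float
    n_points_used: int
    r2_fit: float
    m_inf_pct: float
    m_inf_source: str = "value"
    units: str = "cm^2/s"
    physical: bool = True

    def to_dict(self) -> dict:
        return {
            "D": self.D, "units": self.units, "regime": self.regime,
            "half_thickness_cm": self.half_thickness_cm,
            "slope": self.slope, "intercept": self.intercept,
            "n_points_used": self.n_points_used, "r2_fit": self.r2_fit,
            "m_inf_pct": self.m_inf_pct, "m_inf_source": self.m_inf_source,
            "physical": self.physical,
        }


def resolve_m_inf(curve: ReleaseCurve, policy="gompertz"):
    """Determine the total releasable amount M∞ (percent).

    ``policy`` may be a number (used verbatim), ``"gompertz"`` (the
    fitted Gompertz plateau Qmax — the default, since the plateau of a
    saturating curve estimates M∞ better than any single point) or
    ``"last"`` (the final observed q_pct).

    Returns ``(m_inf_pct, source_label)``.
    """
    if isinstance(policy, (int, float)):
        if policy <= 0:
            raise ValueError("m_inf must be positive")
        return float(policy), "value"
    if policy == "last":
        return float(curve.q_pct[-1]), "last"
    if policy == "gompertz":
        res = ReleaseKinetics(curve, model="gompertz").fit()
        return float(res.params["Qmax"]), "gompertz"
    raise ValueError(f"unknown m_inf policy {policy!r}")


def estimate_D_short(curve: ReleaseCurve, half_thickness_cm: float,
                     m_inf_pct: float, cutoff: float = 0.6) -> DiffusionEstimate:
    """Estimate D from the short-time √t regime.

    Points with Mt/M∞ ≤ ``cutoff`` (default 0.6, the standard validity
    range of the square-root law) are regressed against √t through the
    origin; the slope s gives D = π·(s·L/2)².
    """
    if half_thickness_cm <= 0:
        raise ValueError("half_thickness_cm must be positive")
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    f = curve.fraction_of(m_inf_pct)
    t_s = curve.time_h * _SECONDS_PER_HOUR
    keep = (f <= cutoff) & (t_s > 0)
    if np.sum(keep) < 2:
        raise ValueError(
            "no short-time regime: fewer than 2 points with "
            f"Mt/M_inf <= {cutoff} at t > 0"
        )
    ts, fs = t_s[keep], f[keep]
    root = np.sqrt(ts)
    slope = float(fs @ root / (root @ root))  # through-origin LS
    physical = slope > 0
    if not physical:
        warnings.warn("non-physical (nonpositive) short-time slope",
                      stacklevel=2)
    D = math.pi * (slope * half_thickness_cm / 2.0) ** 2 if physical else 0.0
    r2 = r_squared(fs, slope * root) if np.ptp(fs) > 0 else float("nan")
    return DiffusionEstimate(
        D=D, regime="short_time", half_thickness_cm=half_thickness_cm,
        slope=slope, intercept=0.0, n_points_used=int(np.sum(keep)),
        r2_fit=r2, m_inf_pct=float(m_inf_pct), physical=physical,
    )


def estimate_D_long(curve: ReleaseCurve, half_thickness_cm: float,
                    m_inf_pct: float, floor: float = 0.4) -> DiffusionEstimate:
    """Estimate D from the long-time exponential approach to M∞.

    Points with ``floor`` ≤ Mt/M∞ < 1 are regressed as ln(1 − Mt/M∞)
    against t; the slope m gives D = −4·L²·m/π².  Points at or above
    M∞ are dropped with a warning (the log is undefined there).
    """
    if half_thickness_cm <= 0:
        raise ValueError("half_thickness_cm must be positive")
    if not 0 <= floor < 1:
        raise ValueError("floor must be in [0, 1)")
    f = curve.fraction_of(m_inf_pct)
    n_clipped = int(np.sum(f >= 1))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} point(s) at or above M_inf excluded from the "
            "long-time regression", stacklevel=2,
        )
    keep = (f >= floor) & (f < 1)
    if np.sum(keep) < 2:
        raise ValueError(
            "no long-time regime: fewer than 2 points with "
            f"{floor} <= Mt/M_inf < 1"
        )
    ts = curve.time_h[keep] * _SECONDS_PER_HOUR
    y = np.log(1.0 - f[keep])
    fit = stats.linregress(ts, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    physical = slope < 0
    if not physical:
        warnings.warn("non-physical (nonnegative) long-time slope",
                      stacklevel=2)
    D = -4.0 * half_thickness_cm**2 * slope / math.pi**2 if physical else 0.0
    r2 = float(fit.rvalue**2) if np.ptp(y) > 0 else float("nan")
    return DiffusionEstimate(
        D=D, regime="long_time", half_thickness_cm=half_thickness_cm,
        slope=slope, intercept=intercept, n_points_used=int(np.sum(keep)),
        r2_fit=r2, m_inf_pct=float(m_inf_pct), physical=physical,
    )


class PlaneSheetDiffusion:
    """Plane-sheet diffusion model for a release curve.

    Parameters
    ----------
    curve : ReleaseCurve
        Cumulative release series (percent vs hours).
    half_thickness_cm : float
        Half-thickness L of the membrane in cm.  If the measured value
        is the full mat thickness, divide by two before passing it.
    m_inf : float or {"gompertz", "last"}, default "gompertz"
        Total releasable amount policy, see :func:`resolve_m_inf`.
    """

    def __init__(self, curve: ReleaseCurve, half_thickness_cm: float,
                 m_inf="gompertz"):
        self.curve = curve
        self.half_thickness_cm = float(half_thickness_cm)
        self.m_inf_pct, self.m_inf_source = resolve_m_inf(curve, m_inf)

    def fit(self, regime: str = "both", cutoff: float = 0.6,
            floor: float = 0.4) -> "DiffusionResults":
        """Estimate D in the requested regime(s)."""
        short = long = None
        if regime in ("short", "both"):
            short = estimate_D_short(self.curve, self.half_thickness_cm,
                                     self.m_inf_pct, cutoff=cutoff)
        if regime in ("long", "both"):
            long = estimate_D_long(self.curve, self.half_thickness_cm,
                                   self.m_inf_pct, floor=floor)
        if short is None and long is None:
            raise ValueError("regime must be 'short', 'long' or 'both'")
        return DiffusionResults(short=short, long=long,
                                m_inf_source=self.m_inf_source)


@dataclass
class DiffusionResults:
    """Short- and/or long-time diffusion estimates for one curve."""

    short: DiffusionEstimate | None
    long: DiffusionEstimate | None
    m_inf_source: str = "value"

    def summary(self) -> str:
        lines = ["Plane-Sheet Diffusion Estimates", "=" * 52]
        for est in (self.short, self.long):
            if est is None:
                continue
            lines += [
                f"Regime:            {est.regime}",
                f"D:                 {est.D:.4g} {est.units}",
                f"half-thickness L:  {est.half_thickness_cm:.4g} cm",
                f"M_inf:             {est.m_inf_pct:.4g} % "
                f"({self.m_inf_source})",
                f"points used:       {est.n_points_used}",
                f"regression R2:     {est.r2_fit:.4f}",
            ]
            if est.regime == "long_time":
                lines.append(
                    f"intercept:         {est.intercept:.4f} "
                    f"(ideal ln(8/pi^2) = {LONG_TIME_INTERCEPT:.4f})"
                )
            if not est.physical:
                lines.append("WARNING: non-physical slope, D not estimable")
            lines.append("-" * 52)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "m_inf_source": self.m_inf_source,
            "short_time": self.short.to_dict() if self.short else None,
            "long_time": self.long.to_dict() if self.long else None,
        }
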