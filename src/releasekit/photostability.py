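"""Power-law modeling of UV photodegradation of the releasable drug.

The 24-h released fraction Q after an irradiation time t_irr follows

    Q(t_irr) = Qmax · (1 + t_irr)^b

with Qmax the amount released by the unirradiated sample and b ≤ 0 the
degradation exponent (b = 0 means perfectly photostable).  The shift
by 1 h keeps the law finite at t_irr = 0, where Q equals Qmax exactly.

Fitting is a closed-form linear regression of log Q on log(1 + t_irr),
so results are deterministic; an optional nonlinear refinement in the
original coordinates is available for heteroscedastic data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .curves import IrradiationSeries
from .kinetics import r_squared

__all__ = [
    "photolaw_q",
    "PhotolysisPowerLaw",
    "PhotolysisResults",
    "fit_photolaw",
    "loss_at",
    "relative_loss_at",
]


def photolaw_q(t_irr, qmax: float, b: float):
    """Released fraction after irradiation: Qmax·(1 + t_irr)^b."""
    t = np.asarray(t_irr, dtype=float)
    if np.any(t < 0):
        raise ValueError("irradiation time must be nonnegative")
    out = qmax * np.power(1.0 + t, b)
    return float(out) if out.ndim == 0 else out


class PhotolysisPowerLaw:
    """Power-law photodegradation model for an irradiation series."""

    def __init__(self, series: IrradiationSeries):
        if len(series) < 2:
            raise ValueError("need at least 2 irradiation points to fit")
        if np.any(series.q24_pct <= 0):
            raise ValueError("released fractions must be positive to fit "
                             "the power law (log taken)")
        self.series = series

    @classmethod
    def from_dataframe(cls, df, *, t_col="t_irr_h", q_col="q24_pct"):
        return cls(IrradiationSeries(df[t_col].to_numpy(),
                                     df[q_col].to_numpy()))

    def fit(self, refine: bool = False) -> "PhotolysisResults":
        """Closed-form log–log least squares; optional nonlinear refinement.

        With exactly two points the fit interpolates them exactly.
        ``refine=True`` runs an extra least-squares pass in the linear
        (percent) coordinates starting from the log–log solution.
        """
        t = self.series.t_irr_h
        q = self.series.q24_pct
        x = np.log1p(t)
        y = np.log(q)
        if np.ptp(x) == 0:
            raise ValueError("all irradiation times identical")
        if np.ptp(y) == 0:
            # constant series: the law degenerates to b = 0, qmax = Q
            qmax, b = float(q[0]), 0.0
        else:
            reg = stats.linregress(x, y)
            qmax, b = math.exp(reg.intercept), float(reg.slope)
        if refine:
            res = least_squares(
                lambda p: photolaw_q(t, p[0], p[1]) - q,
                x0=[qmax, b], method="lm",
            )
            qmax, b = float(res.x[0]), float(res.x[1])
        pred = photolaw_q(t, qmax, b)
        r2 = r_squared(q, pred) if np.ptp(q) > 0 else 1.0
        return PhotolysisResults(qmax=qmax, b=b, rsquared=r2,
                                 series=self.series, refined=refine)


@dataclass
class PhotolysisResults:
    """Fitted photodegradation law: Qmax (percent) and exponent b."""

    qmax: float
    b: float
    rsquared: float
    series: IrradiationSeries | None = None
    refined: bool = False

    def predict(self, t_irr):
        return photolaw_q(t_irr, self.qmax, self.b)

    def loss_at(self, t_irr) -> float:
        """Absolute loss Qmax − Q(t_irr), in percentage points.

        For the usual b ≤ 0 this is nonnegative and grows with
        irradiation time; it is the "points of release lost" reading
        of photodegradation (e.g. 82% → 57% is a 25-point loss).
        """
        return self.qmax - self.predict(t_irr)

    def relative_loss_at(self, t_irr) -> float:
        """Fractional loss (Qmax − Q)/Qmax, in percent of the initial
        releasable amount — the alternative reading of "percent lost"."""
        return 100.0 * self.loss_at(t_irr) / self.qmax

    def summary(self) -> str:
        return "\n".join([
            "UV Photodegradation Power-Law Fit",
            "=" * 40,
            f"Qmax:       {self.qmax:.4f} %",
            f"b:          {self.b:.6f}",
            f"R-squared:  {self.rsquared:.4f}",
            f"refined:    {self.refined}",
            "=" * 40,
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.series is not None:
            ax.plot(self.series.t_irr_h, self.series.q24_pct, "o",
                    label="observed")
            grid = np.linspace(0, self.series.t_irr_h[-1], 200)
        else:
            grid = np.linspace(0, 10, 200)
        ax.plot(grid, self.predict(grid), "-",
                label=f"Qmax(1+t)^b, b={self.b:.3f}")
        ax.set_xlabel("irradiation time [h]")
        ax.set_ylabel("24-h release [%]")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {"qmax": self.qmax, "b": self.b, "r2": self.rsquared,
                "refined": self.refined}


def fit_photolaw(series: IrradiationSeries, refine: bool = False
                 ) -> PhotolysisResults:
    """Functional shorthand for ``PhotolysisPowerLaw(series).fit()``."""
    return PhotolysisPowerLaw(series).fit(refine=refine)


def loss_at(fit: PhotolysisResults, t_irr) -> float:
    """Absolute release loss (percentage points) at ``t_irr`` hours."""
    return fit.loss_at(t_irr)


def relative_loss_at(fit: PhotolysisResults, t_irr) -> float:
    """Relative release loss (percent of Qmax) at ``t_irr`` hours."""
    return fit.relative_loss_at(t_irr)
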