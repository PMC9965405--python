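"""Dissolution-kinetics models and least-squares model comparison.

Four classical release laws are implemented for cumulative percent
released Q(t):

=================  =======================================  ==========
model              equation                                 parameters
=================  =======================================  ==========
zero order         Q = K0·t                                 K0 [%/h]
Higuchi            Q = KH·√t                                KH [%/h^0.5]
Korsmeyer–Peppas   Q = KR·t^n                               KR [%/h^n], n [-]
Gompertz           Q = Qmax·exp(−α·exp(β·log10 t))          Qmax [%], α, β [-]
=================  =======================================  ==========

The Gompertz log is base-10, the convention of the dissolution
literature.  A release exponent n ≤ 0.5 in the Korsmeyer–Peppas fit
indicates Fickian diffusion from a thin film.

Fitting follows the statsmodels idiom: build :class:`ReleaseKinetics`
from a :class:`~releasekit.curves.ReleaseCurve`, call :meth:`fit`, and
read estimates off the returned :class:`ReleaseKineticsResults`.
Goodness of fit is the coefficient of determination R² against the
mean-of-observed baseline, which can be negative for a model worse
than a flat line — expected for zero-order and Higuchi fits to
burst-then-plateau curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .curves import ReleaseCurve

__all__ = [
    "FICKIAN_EXPONENT_MAX",
    "KineticModelSpec",
    "MODELS",
    "ReleaseKinetics",
    "ReleaseKineticsResults",
    "ModelComparison",
    "zero_order_q",
    "higuchi_q",
    "korsmeyer_peppas_q",
    "gompertz_q",
    "fit_release_model",
    "compare_models",
    "r_squared",
]

#: Korsmeyer–Peppas exponent at or below which release from a thin film
#: is classified as Fickian diffusion.
FICKIAN_EXPONENT_MAX = 0.5


# ---------------------------------------------------------------------------
# model equations


def _check_time(t, allow_zero: bool = True):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if not allow_zero and np.any(t <= 0):
        raise ValueError("time must be strictly positive for this model")
    return t


def zero_order_q(t, k0: float):
    """Zero-order release Q = K0·t (constant release rate)."""
    t = _check_time(t)
    out = k0 * t
    return float(out) if out.ndim == 0 else out


def higuchi_q(t, kH: float):
    """Higuchi square-root law Q = KH·√t for matrix diffusion."""
    t = _check_time(t)
    out = kH * np.sqrt(t)
    return float(out) if out.ndim == 0 else out


def korsmeyer_peppas_q(t, kR: float, n: float):
    """Korsmeyer–Peppas power law Q = KR·tⁿ.

    The exponent must be positive; ``t = 0`` evaluates to 0.  Exponents
    at or below 0.5 are interpreted by callers as Fickian transport
    (see :data:`FICKIAN_EXPONENT_MAX`).
    """
    if n <= 0:
        raise ValueError("release exponent n must be positive")
    t = _check_time(t)
    out = kR * np.power(t, n)
    return float(out) if out.ndim == 0 else out


def gompertz_q(t, qmax: float, alpha: float, beta: float):
    """Gompertz dissolution profile Q = Qmax·exp(−α·exp(β·log10 t)).

    ``qmax`` is the plateau (percent released), ``α`` locates the
    inflection and ``β`` is the dissolution-rate shape parameter —
    negative for the usual sigmoid rising to ``qmax`` as t → ∞.
    The logarithm is base 10.
    """
    if qmax <= 0:
        raise ValueError("qmax must be positive")
    t = _check_time(t, allow_zero=False)
    out = qmax * np.exp(-alpha * np.exp(beta * np.log10(t)))
    return float(out) if out.ndim == 0 else out


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 − SSres/SStot.

    SStot is taken about the observed mean regardless of the model, so
    a fit worse than the flat mean line yields a negative value.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values are all identical (SStot = 0)")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# model registry


@dataclass(frozen=True)
class KineticModelSpec:
    """Static description of one kinetic model: names, bounds, equation."""

    name: str
    param_names: tuple
    lower: tuple
    upper: tuple
    requires_positive_time: bool

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def evaluate(self, t, params) -> np.ndarray:
        fn = _MODEL_FUNCS[self.name]
        return fn(t, *params)


_MODEL_FUNCS = {
    "zero_order": zero_order_q,
    "higuchi": higuchi_q,
    "korsmeyer_peppas": korsmeyer_peppas_q,
    "gompertz": gompertz_q,
}

# Bounds: rate constants positive; Qmax capped at 110% for headroom
# above a noisy plateau; n in (0, 1] spans Fickian through Case-II
# transport; beta unconstrained in sign.
MODELS: dict[str, KineticModelSpec] = {
    "zero_order": KineticModelSpec(
        "zero_order", ("K0",), (0.0,), (np.inf,), False
    ),
    "higuchi": KineticModelSpec(
        "higuchi", ("KH",), (0.0,), (np.inf,), False
    ),
    "korsmeyer_peppas": KineticModelSpec(
        "korsmeyer_peppas", ("KR", "n"), (1e-12, 1e-9), (np.inf, 1.0), True
    ),
    "gompertz": KineticModelSpec(
        "gompertz", ("Qmax", "alpha", "beta"),
        (1e-9, 1e-9, -np.inf), (110.0, np.inf, np.inf), True
    ),
}


def get_model(name) -> KineticModelSpec:
    if isinstance(name, KineticModelSpec):
        return name
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown kinetic model {name!r}; choose from {sorted(MODELS)}"
        ) from None


# ---------------------------------------------------------------------------
# fitting


class InsufficientDataError(ValueError):
    """Raised when a curve has too few usable points for the model."""


class DegenerateDataError(ValueError):
    """Raised when a curve carries no information for the model (flat q)."""


class ReleaseKinetics:
    """Least-squares fit of one kinetic model to a release curve.

    Parameters
    ----------
    curve : ReleaseCurve
        Observed cumulative release series.
    model : str or KineticModelSpec, default ``"gompertz"``
        Which release law to fit.

    Notes
    -----
    Initialization is deterministic (no random restarts): the plateau
    starts at max(q), α from the earliest positive-time point, β at −1,
    rate constants from through-origin linear regression in the model's
    transformed coordinate, and n at 0.5.  t = 0 points are excluded
    for the log-domain models (Gompertz, Korsmeyer–Peppas) and kept for
    the others; the exclusion is recorded on the results.
    """

    def __init__(self, curve: ReleaseCurve, model="gompertz"):
        self.curve = curve
        self.spec = get_model(model)

    @classmethod
    def from_dataframe(cls, df, model="gompertz", *, time_col="time_h",
                       q_col="q_pct", medium_label=""):
        """Build from a DataFrame with time/percent-released columns."""
        curve = ReleaseCurve(df[time_col].to_numpy(), df[q_col].to_numpy(),
                             medium_label=medium_label)
        return cls(curve, model=model)

    # internal: usable (t, q) under the model's domain
    def _data(self):
        t = self.curve.time_h
        q = self.curve.q_pct
        dropped = 0
        if self.spec.requires_positive_time:
            keep = t > 0
            dropped = int(np.sum(~keep))
            t, q = t[keep], q[keep]
        return t, q, dropped

    def _initial_params(self, t, q):
        name = self.spec.name
        if name == "zero_order":
            return np.array([max(float(q @ t / (t @ t)), 1e-12)])
        if name == "higuchi":
            s = np.sqrt(t)
            return np.array([max(float(q @ s / (s @ s)), 1e-12)])
        if name == "korsmeyer_peppas":
            s = np.sqrt(t)
            k0 = max(float(q @ s / (s @ s)), 1e-9)
            return np.array([k0, 0.5])
        # gompertz
        qmax0 = max(float(np.max(q)), 1e-6)
        ratio = min(max(float(q[0]) / qmax0, 1e-9), 1.0 - 1e-9)
        alpha0 = max(-math.log(ratio), 1e-6)
        return np.array([qmax0, alpha0, -1.0])

    def fit(self, *, ftol: float = 1e-12, xtol: float = 1e-12,
            max_nfev: int = 5000) -> "ReleaseKineticsResults":
        """Fit by (bounded) least squares and return the results object."""
        spec = self.spec
        t, q, dropped = self._data()
        if t.size < spec.n_params + 1:
            raise InsufficientDataError(
                f"{spec.name} needs at least {spec.n_params + 1} usable "
                f"points, got {t.size}"
            )
        if spec.n_params >= 2 and np.ptp(q) == 0:
            raise DegenerateDataError(
                f"all q_pct identical: {spec.name} is unidentifiable"
            )

        if spec.name in ("zero_order", "higuchi"):
            # closed-form through-origin least squares, always converged
            f = t if spec.name == "zero_order" else np.sqrt(t)
            k = float(q @ f / (f @ f))
            params = np.array([k])
            converged, message = True, "closed-form linear least squares"
        else:
            x0 = self._initial_params(t, q)
            res = least_squares(
                lambda p: spec.evaluate(t, p) - q,
                x0=x0,
                bounds=(spec.lower, spec.upper),
                method="trf",
                ftol=ftol, xtol=xtol, gtol=1e-12, max_nfev=max_nfev,
            )
            params = res.x
            converged = bool(res.success)
            message = res.message

        pred = spec.evaluate(t, params)
        resid = q - pred
        try:
            r2 = r_squared(q, pred)
        except ValueError:  # flat observed q for a 1-parameter model
            r2 = float("nan")
        return ReleaseKineticsResults(
            model=spec,
            params=dict(zip(spec.param_names, (float(p) for p in params))),
            rsquared=r2,
            resid=resid,
            nobs=int(t.size),
            converged=converged,
            message=message,
            times_used=t,
            observed=q,
            n_dropped_t0=dropped,
            medium_label=self.curve.medium_label,
        )


@dataclass
class ReleaseKineticsResults:
    """Fit of one kinetic model: estimates, residuals and diagnostics.

    ``params`` maps parameter names to values; ``rsquared`` is computed
    against the mean of the observed points actually used in the fit
    (``times_used``).  ``converged`` False flags a solver failure — the
    last iterate is still reported, alongside ``message``.
    """

    model: KineticModelSpec
    params: dict
    rsquared: float
    resid: np.ndarray
    nobs: int
    converged: bool
    message: str
    times_used: np.ndarray
    observed: np.ndarray
    n_dropped_t0: int = 0
    medium_label: str = ""

    def predict(self, t) -> np.ndarray:
        """Evaluate the fitted model at times ``t`` (hours)."""
        return self.model.evaluate(t, list(self.params.values()))

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.times_used)

    @property
    def is_fickian(self) -> bool | None:
        """For a Korsmeyer–Peppas fit, whether n indicates Fickian diffusion."""
        if self.model.name != "korsmeyer_peppas":
            return None
        return self.params["n"] <= FICKIAN_EXPONENT_MAX

    def summary(self) -> str:
        lines = [
            "Release Kinetics Fit",
            "=" * 44,
            f"Model:         {self.model.name}",
            f"Medium:        {self.medium_label or '-'}",
            f"No. obs:       {self.nobs}"
            + (f"  ({self.n_dropped_t0} t=0 point(s) excluded)"
               if self.n_dropped_t0 else ""),
            f"R-squared:     {self.rsquared:.4f}",
            f"Converged:     {self.converged}",
            "-" * 44,
        ]
        for name, value in self.params.items():
            lines.append(f"{name:>12s}  {value: .6g}")
        if self.is_fickian is not None:
            mech = "Fickian diffusion" if self.is_fickian else "anomalous transport"
            lines.append(f"{'mechanism':>12s}  {mech} (n"
                         f"{'<=' if self.is_fickian else '>'}0.5)")
        lines.append("=" * 44)
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        """Plot observed points and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.times_used
        grid = np.linspace(max(t.min(), 1e-6), t.max(), n_grid)
        ax.plot(t, self.observed, "o", label="observed")
        ax.plot(grid, self.predict(grid), "-",
                label=f"{self.model.name} (R²={self.rsquared:.3f})")
        ax.set_xlabel("time [h]")
        ax.set_ylabel("cumulative release [%]")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "medium": self.medium_label,
            "params": dict(self.params),
            "r2": self.rsquared,
            "n_obs": self.nobs,
            "n_dropped_t0": self.n_dropped_t0,
            "converged": self.converged,
            "message": self.message,
        }


def fit_release_model(curve: ReleaseCurve, model="gompertz",
                      **kwargs) -> ReleaseKineticsResults:
    """Functional shorthand for ``ReleaseKinetics(curve, model).fit()``."""
    return ReleaseKinetics(curve, model=model).fit(**kwargs)


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelComparison:
    """Ranked fits of several kinetic models to one curve.

    ``fits`` holds the successful results ranked by R² (descending;
    ties broken by fewer parameters, then model name).  ``failures``
    maps model names to the error message that prevented a fit.
    """

    fits: list
    failures: dict = field(default_factory=dict)

    @property
    def best(self) -> ReleaseKineticsResults:
        if not self.fits:
            raise ValueError("no model could be fitted")
        return self.fits[0]

    def to_frame(self):
        import pandas as pd

        rows = []
        for rank, res in enumerate(self.fits, start=1):
            row = {"rank": rank, "model": res.model.name,
                   "r2": res.rsquared, "converged": res.converged}
            row.update(res.params)
            rows.append(row)
        for name, err in self.failures.items():
            rows.append({"rank": None, "model": name, "r2": float("nan"),
                         "converged": False, "error": err})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Kinetic Model Comparison", "=" * 60]
        lines.append(f"{'rank':>4s} {'model':<18s} {'R2':>9s}  parameters")
        for rank, res in enumerate(self.fits, start=1):
            pstr = ", ".join(f"{k}={v:.4g}" for k, v in res.params.items())
            lines.append(f"{rank:>4d} {res.model.name:<18s} "
                         f"{res.rsquared:>9.4f}  {pstr}")
        for name, err in self.failures.items():
            lines.append(f"{'-':>4s} {name:<18s} {'failed':>9s}  {err}")
        lines.append("=" * 60)
        return "\n".join(lines)


def compare_models(curve: ReleaseCurve, models=None, **kwargs) -> ModelComparison:
    """Fit each requested model and rank by R².

    A model that fails (too few points, degenerate data, domain error)
    is recorded under ``failures`` without aborting the other fits.
    """
    if models is None:
        models = list(MODELS)
    if not models:
        raise ValueError("at least one model must be requested")
    fits, failures = [], {}
    for m in models:
        spec = get_model(m)
        try:
            fits.append(ReleaseKinetics(curve, model=spec).fit(**kwargs))
        except Exception as exc:  # noqa: BLE001 - isolate per-model failure
            failures[spec.name] = str(exc)
    fits.sort(key=lambda r: (math.isnan(r.rsquared),
                             -r.rsquared if not math.isnan(r.rsquared) else 0.0,
                             r.model.n_params, r.model.name))
    return ModelComparison(fits=fits, failures=failures)
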