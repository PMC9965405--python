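"""MTT-plate viability normalization.

Formazan absorbance at 595 nm is background-corrected by subtracting
the 655 nm reading of the same well.  Viability of a treated group is
the ratio of mean corrected signals, treated over untreated controls,
expressed in percent, with a delta-method standard error propagated
from the replicate variances.  Normalization is per timepoint: each
treatment group is compared against the untreated wells measured at
the same time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "corrected_signal",
    "ViabilityEstimate",
    "percent_viability",
    "viability_table",
]

PLATE_COLUMNS = ("well_id", "group", "timepoint_h", "a595", "a655")


def corrected_signal(a595: float, a655: float) -> float:
    """Background-corrected absorbance, A595 − A655.

    Both readings must be nonnegative.  A negative difference (the
    background exceeding the signal) is returned but flagged with a
    warning — it usually marks an empty or failed well.
    """
    if a595 < 0 or a655 < 0:
        raise ValueError("absorbances must be nonnegative")
    corrected = a595 - a655
    if corrected < 0:
        warnings.warn(
            f"background exceeds signal (A595={a595}, A655={a655}): "
            "corrected absorbance is negative", stacklevel=2,
        )
    return corrected


@dataclass(frozen=True)
class ViabilityEstimate:
    """Percent residual viability with its standard error."""

    pct: float
    se: float
    n_treated: int
    n_untreated: int

    def __str__(self) -> str:
        se = f"{self.se:.1f}" if math.isfinite(self.se) else "nan"
        return f"{self.pct:.1f} % +/- {se}"


def percent_viability(treated, untreated) -> ViabilityEstimate:
    """Residual viability of treated wells relative to untreated controls.

    Parameters are per-well *corrected* absorbances.  The estimate is
    100·mean(treated)/mean(untreated); the SE combines the standard
    errors of the two group means by the delta method for a ratio.
    Groups with fewer than two replicates get SE = NaN.
    """
    t = np.asarray(treated, dtype=float)
    u = np.asarray(untreated, dtype=float)
    if t.size == 0 or u.size == 0:
        raise ValueError("both groups must be nonempty")
    mu_u = u.mean()
    if mu_u <= 0:
        raise ValueError("untreated mean corrected absorbance must be positive")
    mu_t = t.mean()
    pct = 100.0 * mu_t / mu_u
    if t.size >= 2 and u.size >= 2:
        se_t = t.std(ddof=1) / math.sqrt(t.size)
        se_u = u.std(ddof=1) / math.sqrt(u.size)
        se = 100.0 * math.sqrt(se_t**2 / mu_u**2
                               + mu_t**2 * se_u**2 / mu_u**4)
    else:
        se = float("nan")
    return ViabilityEstimate(pct=pct, se=se,
                             n_treated=int(t.size), n_untreated=int(u.size))


def viability_table(plate: pd.DataFrame, control_group: str = "untreated"
                    ) -> pd.DataFrame:
    """Per-group, per-timepoint viability from a plate record table.

    ``plate`` needs columns ``well_id, group, timepoint_h, a595, a655``.
    Each non-control group at each timepoint is normalized against the
    control wells of the same timepoint.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    df = plate.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-well negatives summarized below
        df["corrected"] = df["a595"] - df["a655"]
    if (df["a595"] < 0).any() or (df["a655"] < 0).any():
        raise ValueError("absorbances must be nonnegative")
    n_neg = int((df["corrected"] < 0).sum())
    if n_neg:
        warnings.warn(f"{n_neg} well(s) with negative corrected absorbance",
                      stacklevel=2)
    rows = []
    for tp, sub in df.groupby("timepoint_h"):
        controls = sub.loc[sub["group"] == control_group, "corrected"]
        if controls.empty:
            raise ValueError(f"no {control_group!r} wells at timepoint {tp}")
        for group, wells in sub.groupby("group"):
            if group == control_group:
                continue
            est = percent_viability(wells["corrected"], controls)
            rows.append({
                "timepoint_h": tp, "group": group,
                "viability_pct": est.pct, "se_pct": est.se,
                "n_wells": est.n_treated, "n_control": est.n_untreated,
            })
    return pd.DataFrame(rows)
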