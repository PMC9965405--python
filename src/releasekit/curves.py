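"""Core measurement containers.

The central object is :class:`ReleaseCurve` — a cumulative drug-release
time series (hours vs. percent of loaded drug released).  Companion
containers hold UV-irradiation series and sampled surface profiles.
All containers validate their invariants on construction and store data
as immutable NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReleaseCurve", "IrradiationSeries", "SurfaceProfile"]


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class ReleaseCurve:
    """Cumulative release time series.

    Parameters
    ----------
    time_h : array_like
        Sampling times in hours, nonnegative and strictly increasing.
    q_pct : array_like
        Cumulative percent of the loaded drug released at each time.
        Values are on the 0–100 scale (plateaus slightly above 100 are
        tolerated as measurement noise).
    medium_label : str, optional
        Release medium, e.g. ``"PBS"`` or ``"pH3"``.
    replicate_id : int, optional
        Replicate index when the curve is one of several repeats.
    """

    time_h: np.ndarray
    q_pct: np.ndarray
    medium_label: str = ""
    replicate_id: int | None = None

    def __post_init__(self):
        t = _as_float_array(self.time_h, "time_h")
        q = _as_float_array(self.q_pct, "q_pct")
        if t.size != q.size:
            raise ValueError("time_h and q_pct must have the same length")
        if t.size and t[0] < 0:
            raise ValueError("time_h must be nonnegative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time_h must be strictly increasing")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "q_pct", q)

    def __len__(self) -> int:
        return self.time_h.size

    def validate_cumulative(self, tol_pct: float = 1.5) -> bool:
        """Check that the curve is non-decreasing within ``tol_pct`` points.

        A cumulative-release measurement may dip slightly between
        samplings because of assay noise; dips larger than the tolerance
        indicate a non-cumulative series (or a data problem).
        """
        if len(self) < 2:
            return True
        return bool(np.all(np.diff(self.q_pct) >= -tol_pct))

    def fraction_of(self, m_inf_pct: float) -> np.ndarray:
        """Return Mt/M∞ given the total releasable amount in percent."""
        if m_inf_pct <= 0:
            raise ValueError("m_inf_pct must be positive")
        return self.q_pct / m_inf_pct


@dataclass(frozen=True)
class IrradiationSeries:
    """24-h released fraction versus UV irradiation time.

    The first entry must be the unirradiated sample (``t_irr_h == 0``):
    it anchors the maximum releasable amount of intact drug.
    """

    t_irr_h: np.ndarray
    q24_pct: np.ndarray

    def __post_init__(self):
        t = _as_float_array(self.t_irr_h, "t_irr_h")
        q = _as_float_array(self.q24_pct, "q24_pct")
        if t.size != q.size:
            raise ValueError("t_irr_h and q24_pct must have the same length")
        if t.size == 0 or t[0] != 0:
            raise ValueError("series must start at t_irr_h = 0 (unirradiated anchor)")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("t_irr_h must be strictly increasing")
        object.__setattr__(self, "t_irr_h", t)
        object.__setattr__(self, "q24_pct", q)

    def __len__(self) -> int:
        return self.t_irr_h.size


@dataclass(frozen=True)
class SurfaceProfile:
    """Uniformly sampled surface height/intensity trace.

    ``x`` is the sampled position (pixels or micrometres), ``z`` the
    height — gray levels 0–255 when derived from an image row.  Spacing
    must be uniform because the roughness metrics use an equal-weight
    discrete mean over the evaluation length.
    """

    x: np.ndarray
    z: np.ndarray

    _REL_SPACING_TOL = 1e-9

    def __post_init__(self):
        x = _as_float_array(self.x, "x")
        z = _as_float_array(self.z, "z")
        if x.size != z.size:
            raise ValueError("x and z must have the same length")
        if x.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        dx = np.diff(x)
        if not np.all(dx > 0):
            raise ValueError("x must be strictly increasing")
        step = dx[0]
        if np.max(np.abs(dx - step)) > self._REL_SPACING_TOL * max(abs(step), 1.0):
            raise ValueError("x must be uniformly spaced")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return self.x.size

    @property
    def evaluation_length(self) -> float:
        """Total span L of the profile (x_last − x_first)."""
        return float(self.x[-1] - self.x[0])
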