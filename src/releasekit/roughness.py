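"""Mean-line surface roughness metrics Ra and RMS.

Both metrics are computed over the profile's deviations from its mean
line: Ra is the arithmetic mean of |Z − mean| and RMS the quadratic
mean, evaluated as equal-weight discrete means on the uniform sample
grid (equivalent to a midpoint-rule integral over the evaluation
length).  The power-mean inequality guarantees RMS ≥ Ra.

Profiles can be built directly or extracted from a grayscale image as
the column-wise mean intensity of a horizontal band — the
"plot profile" reading of a micrograph, with gray level standing in
for height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import SurfaceProfile

__all__ = ["RoughnessResult", "roughness", "profile_from_image_row"]


@dataclass(frozen=True)
class RoughnessResult:
    """Roughness metrics in the units of the profile height."""

    ra: float
    rms: float
    mean_line: float

    def to_dict(self) -> dict:
        return {"ra": self.ra, "rms": self.rms, "mean_line": self.mean_line}


def roughness(profile: SurfaceProfile) -> RoughnessResult:
    """Compute Ra, RMS and the mean line of a uniform profile."""
    z = profile.z
    mean_line = float(z.mean())
    dev = z - mean_line
    ra = float(np.mean(np.abs(dev)))
    rms = float(np.sqrt(np.mean(dev**2)))
    return RoughnessResult(ra=ra, rms=rms, mean_line=mean_line)


def profile_from_image_row(gray_matrix, row_band) -> SurfaceProfile:
    """Extract an intensity profile from a band of image rows.

    Parameters
    ----------
    gray_matrix : 2-D array_like
        Grayscale image, rows × columns, gray levels 0–255.
    row_band : int, slice or (start, stop) tuple
        Rows to average.  A single index selects that row verbatim.

    Returns
    -------
    SurfaceProfile
        x = column indices, z = column-wise mean gray level of the band.
    """
    img = np.asarray(gray_matrix, dtype=float)
    if img.ndim != 2:
        raise ValueError("gray_matrix must be two-dimensional")
    if isinstance(row_band, tuple):
        row_band = slice(*row_band)
    elif isinstance(row_band, (int, np.integer)):
        row_band = slice(row_band, row_band + 1)
    band = img[row_band]
    if band.size == 0:
        raise ValueError("row band selects no rows")
    z = band.mean(axis=0)
    return SurfaceProfile(x=np.arange(img.shape[1], dtype=float), z=z)
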