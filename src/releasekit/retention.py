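"""Gravimetric liquid retention and contact-angle summaries.

Retention compares the dry mass M0 of a membrane with its mass Meq
after equilibration in a liquid.  The signed-uptake convention is used
throughout: q = (Meq − M0)/M0 × 100, so a swelling membrane reports a
positive percentage and a dissolving/leaching one a negative value.
The opposite sign convention, (M0 − Meq)/M0 × 100, is kept available
as :func:`retention_mass_loss` for comparison with sources that quote
retention as a loss.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

__all__ = [
    "retention_signed",
    "retention_mass_loss",
    "AngleSummary",
    "summarize_angles",
]


def _check_masses(m0: float, meq: float):
    if m0 <= 0:
        raise ValueError("dry mass m0 must be positive")
    if meq < 0:
        raise ValueError("equilibrated mass meq must be nonnegative")


def retention_signed(m0: float, meq: float) -> float:
    """Signed liquid retention, percent of dry mass.

    Positive = liquid uptake (swelling), negative = net mass loss.
    """
    _check_masses(m0, meq)
    return (meq - m0) / m0 * 100.0


def retention_mass_loss(m0: float, meq: float) -> float:
    """Retention under the literal mass-loss convention, (M0 − Meq)/M0 × 100."""
    _check_masses(m0, meq)
    return (m0 - meq) / m0 * 100.0


@dataclass(frozen=True)
class AngleSummary:
    """Replicate contact-angle readings with mean ± SD, in degrees.

    A mean above 90° flags the surface as hydrophobic.
    """

    readings: tuple
    mean: float
    sd: float

    @property
    def hydrophobic(self) -> bool:
        return self.mean > 90.0

    def __str__(self) -> str:
        tag = "hydrophobic" if self.hydrophobic else "hydrophilic"
        return (f"{self.mean:.1f} deg +/- {self.sd:.1f} "
                f"(n={len(self.readings)}, {tag})")


def summarize_angles(readings) -> AngleSummary:
    """Mean and sample SD of contact-angle replicates.

    Each reading must lie in the open interval (0, 180) degrees.
    A single reading yields SD = 0.
    """
    readings = tuple(float(r) for r in readings)
    if not readings:
        raise ValueError("need at least one contact-angle reading")
    for r in readings:
        if not 0.0 < r < 180.0:
            raise ValueError(f"contact angle {r} out of range (0, 180)")
    mean = statistics.fmean(readings)
    sd = statistics.stdev(readings) if len(readings) > 1 else 0.0
    return AngleSummary(readings=readings, mean=mean, sd=sd)
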