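"""Seeded synthetic-data generators for every input the analyses consume.

The generators emulate the measurement campaign the analyses expect:

* burst-then-plateau release curves from any of the four kinetic laws,
  with additive (and optionally proportional) Gaussian noise in
  percentage points, truncated at physical bounds;
* exact fractional-release series for diffusion out of a plane sheet,
  from the full eigenfunction expansion — the ground truth against
  which the asymptotic D estimators are checked;
* rough surface profiles with an exactly prescribed Ra;
* power-law photodegradation series;
* MTT plate absorbances with a 655 nm background.

Every generator is a deterministic function of its configuration and
seed: the same call reproduces the same data bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .curves import IrradiationSeries, ReleaseCurve, SurfaceProfile
from .kinetics import get_model
from .photostability import photolaw_q
from .roughness import roughness

__all__ = [
    "GeneratorConfig",
    "time_grid",
    "generate_release_curve",
    "fickian_fraction",
    "generate_fickian_series_curve",
    "generate_surface_profile",
    "generate_irradiation_series",
    "generate_plate",
]

_SECONDS_PER_HOUR = 3600.0

#: default release-curve horizon, hours (matches a week-long release test)
DEFAULT_T_RANGE = (0.5, 170.0)
#: default irradiation horizon, hours
DEFAULT_IRRADIATION_TIMES = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0)


def time_grid(n: int, t_range=DEFAULT_T_RANGE, spacing: str = "log"
              ) -> np.ndarray:
    """Sampling grid of ``n`` times, linear or logarithmic."""
    lo, hi = t_range
    if n < 2 or hi <= lo:
        raise ValueError("need n >= 2 and t_range increasing")
    if spacing == "log":
        if lo <= 0:
            raise ValueError("log spacing needs a positive start time")
        return np.geomspace(lo, hi, n)
    if spacing == "linear":
        return np.linspace(lo, hi, n)
    raise ValueError(f"unknown spacing {spacing!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Release-curve generator settings.

    ``sigma_pct`` is the additive Gaussian noise SD in percentage
    points (default 2, a typical assay repeatability); ``sigma_rel``
    adds a term proportional to the signal for heteroscedastic noise.
    ``clip`` truncates the noisy values to the physical band
    [0, 105] % — slightly above 100 to allow plateau noise.
    """

    model: str = "gompertz"
    params: dict = field(default_factory=lambda: {
        "Qmax": 83.0, "alpha": 0.83, "beta": -2.7})
    n_times: int = 12
    t_range: tuple = DEFAULT_T_RANGE
    spacing: str = "log"
    sigma_pct: float = 2.0
    sigma_rel: float = 0.0
    clip: tuple | None = (0.0, 105.0)
    seed: int = 0
    replicates: int = 1
    medium_label: str = ""

    def __post_init__(self):
        if self.sigma_pct < 0 or self.sigma_rel < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        get_model(self.model)  # validate the name early


def generate_release_curve(config: GeneratorConfig):
    """Generate seeded noisy release curve(s) from a kinetic law.

    Returns a single :class:`ReleaseCurve` when ``replicates == 1``,
    else a list of curves (replicate seeds are derived from the config
    seed, so the whole batch is reproducible).
    """
    spec = get_model(config.model)
    t = time_grid(config.n_times, config.t_range, config.spacing)
    if spec.requires_positive_time and t[0] <= 0:
        raise ValueError(f"{spec.name} needs strictly positive times")
    params = [config.params[name] for name in spec.param_names]
    clean = np.asarray(spec.evaluate(t, params), dtype=float)

    curves = []
    seeds = np.random.SeedSequence(config.seed).spawn(config.replicates)
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        sd = config.sigma_pct + config.sigma_rel * np.abs(clean)
        q = clean + rng.normal(0.0, 1.0, size=t.size) * sd
        if config.clip is not None:
            q = np.clip(q, *config.clip)
        curves.append(ReleaseCurve(
            t, q, medium_label=config.medium_label,
            replicate_id=i if config.replicates > 1 else None,
        ))
    return curves[0] if config.replicates == 1 else curves


def fickian_fraction(t_h, D: float, half_thickness_cm: float,
                     n_terms: int = 200, tail_tol: float = 1e-10
                     ) -> np.ndarray:
    """Exact fractional release Mt/M∞ from a plane sheet.

    Evaluates the eigenfunction series

        Mt/M∞ = 1 − Σ_m 8/((2m+1)²π²) · exp(−(2m+1)²π²Dt/(4L²)),

    whose leading term is the long-time exponential law.  Terms are
    added (doubling from ``n_terms``) until the first dropped term is
    below ``tail_tol``; t = 0 returns exactly 0.
    """
    if D <= 0 or half_thickness_cm <= 0:
        raise ValueError("D and half_thickness_cm must be positive")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    t = np.atleast_1d(np.asarray(t_h, dtype=float)) * _SECONDS_PER_HOUR
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    out = np.zeros_like(t)
    pos = t > 0
    if np.any(pos):
        tau = D * t[pos] / half_thickness_cm**2  # dimensionless time
        m = n_terms
        while True:
            k = 2 * np.arange(m)[:, None] + 1  # odd integers
            terms = (8.0 / (k**2 * math.pi**2)
                     * np.exp(-(k**2) * math.pi**2 * tau[None, :] / 4.0))
            # tail bound: sum_{j>=m} 1/(2j+1)^2 <= 1/(4m), times the
            # slowest-decaying dropped exponential over evaluated times
            k_next = 2 * m + 1
            dropped = (8.0 / math.pi**2 / (4.0 * m)
                       * math.exp(-(k_next**2) * math.pi**2
                                  * float(tau.min()) / 4.0))
            if dropped <= tail_tol or m >= 200_000:
                break
            m *= 2
        out[pos] = 1.0 - terms.sum(axis=0)
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(t_h) else out[0]


def generate_fickian_series_curve(D: float, half_thickness_cm: float,
                                  times_h, n_terms: int = 200,
                                  medium_label: str = "") -> ReleaseCurve:
    """Noiseless plane-sheet release curve in percent (M∞ = 100%)."""
    times_h = np.asarray(times_h, dtype=float)
    frac = fickian_fraction(times_h, D, half_thickness_cm, n_terms=n_terms)
    return ReleaseCurve(times_h, 100.0 * frac, medium_label=medium_label)


def generate_surface_profile(target_ra: float, n: int, seed: int = 0,
                             correlation_length: float = 10.0,
                             mean_level: float = 128.0) -> SurfaceProfile:
    """Random rough profile with an exactly prescribed Ra.

    A white Gaussian field is smoothed with a Gaussian kernel of the
    given correlation length (samples), mean-centred, then rescaled so
    that the computed Ra equals ``target_ra`` (to within rounding),
    and offset to ``mean_level`` gray levels.
    """
    if target_ra < 0:
        raise ValueError("target_ra must be nonnegative")
    if n < 2:
        raise ValueError("need at least 2 samples")
    x = np.arange(n, dtype=float)
    if target_ra == 0:
        return SurfaceProfile(x, np.full(n, mean_level))
    rng = np.random.default_rng(seed)
    z = gaussian_filter1d(rng.normal(size=n), correlation_length,
                          mode="wrap")
    z -= z.mean()
    ra = np.mean(np.abs(z))
    if ra == 0:  # pathological draw; fall back to unsmoothed noise
        z = rng.normal(size=n)
        z -= z.mean()
        ra = np.mean(np.abs(z))
    z *= target_ra / ra
    profile = SurfaceProfile(x, z + mean_level)
    assert abs(roughness(profile).ra - target_ra) <= 1e-6 * max(target_ra, 1)
    return profile


def generate_irradiation_series(qmax: float, b: float,
                                times_h=DEFAULT_IRRADIATION_TIMES,
                                sigma_pct: float = 0.0,
                                seed: int = 0) -> IrradiationSeries:
    """Seeded noisy power-law photodegradation series."""
    t = np.asarray(times_h, dtype=float)
    q = np.asarray(photolaw_q(t, qmax, b), dtype=float)
    if sigma_pct > 0:
        rng = np.random.default_rng(seed)
        q = np.clip(q + rng.normal(0.0, sigma_pct, size=t.size), 0.0, None)
    return IrradiationSeries(t, q)


def generate_plate(effects: dict, n_wells: int = 3, seed: int = 0,
                   timepoints_h=(24.0,), baseline_a595: float = 0.70,
                   background_a655: float = 0.05,
                   sigma_a595: float = 0.03, sigma_a655: float = 0.005):
    """Simulate an MTT plate as a DataFrame of well records.

    ``effects`` maps group name to the viability fraction in [0, 1.2]
    relative to the untreated baseline (an ``untreated`` group at
    effect 1.0 is added automatically if absent).  Corrected signals
    scale with the effect, so ``percent_viability`` recovers roughly
    ``100 × effect``.
    """
    import pandas as pd

    for g, e in effects.items():
        if not 0.0 <= e <= 1.2:
            raise ValueError(f"effect for {g!r} outside [0, 1.2]")
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    groups = dict(effects)
    groups.setdefault("untreated", 1.0)
    rng = np.random.default_rng(seed)
    rows = []
    for tp in timepoints_h:
        for group, effect in groups.items():
            for w in range(n_wells):
                signal = effect * (baseline_a595 - background_a655)
                a655 = max(background_a655
                           + rng.normal(0.0, sigma_a655), 0.0)
                a595 = max(a655 + signal + rng.normal(0.0, sigma_a595), 0.0)
                rows.append({
                    "well_id": f"{group}-{tp:g}h-{w + 1}",
                    "group": group, "timepoint_h": float(tp),
                    "a595": a595, "a655": a655,
                })
    return pd.DataFrame(rows)
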