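# Methods

This note documents the models, numerical choices and limitations of
releasekit, in the spirit of a statistical package's model
documentation. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from
external measurements.

## Release-kinetics fitting

The cumulative release Q(t) is in percent of the loaded drug
(0–100 scale; fractions must be converted on input). Four laws are
fitted: zero order Q = K₀t, Higuchi Q = K_H√t, Korsmeyer–Peppas
Q = K_Rtⁿ and Gompertz Q = Qmax·exp(−α·exp(β·log₁₀t)).

**Log convention.** The Gompertz log is base 10. With the PBS-like
parameter set (Qmax 83 %, α 0.83, β −2.7) the base-10 form evaluates
to 82.3 % at 50 h — a plateau that rounds to 82 % — whereas the
natural-log form would be essentially at Qmax (83.0) by then. Base 10
is also the common convention in the dissolution literature, so it is
adopted and tested.

**Estimation.** The one-parameter laws are linear through the origin
in a transformed coordinate (t or √t), so their least-squares solution
is closed form and always "converged". The two nonlinear laws use
bounded trust-region least squares (`scipy.optimize.least_squares`,
TRF, ftol = xtol = gtol = 1e−12) with a deterministic initialization —
no random restarts, so fits are reproducible bit for bit:

* Qmax₀ = max(q); α₀ = −ln(q₁/Qmax₀) at the earliest positive time
  (clipped into (0, ∞)); β₀ = −1;
* K₀, K_H and the Korsmeyer–Peppas prefactor from through-origin
  regression in the transformed coordinate; n₀ = 0.5.

Bounds encode physics: rate constants ≥ 0; 0 < Qmax ≤ 110 (headroom
above 100 % for noisy plateaus); α > 0; β unconstrained in sign;
0 < n ≤ 1, spanning Fickian (n ≤ 0.5) through Case-II (n = 1)
transport. Noiseless self-recovery of all four models is tested to
1e−4 relative.

**Domain handling.** t = 0 points are excluded from the Gompertz and
Korsmeyer–Peppas fits (log/power undefined or degenerate) and retained
for the other models; the number of excluded points is recorded on the
results object. Curves with all-identical q are rejected for the
multi-parameter models as unidentifiable. Solver non-convergence is
reported via `converged=False` plus the solver message — parameters
are never silently NaN.

**Goodness of fit and ranking.** R² = 1 − SSres/SStot with SStot about
the mean of the observed points used in the fit, for every model
including the no-intercept ones. This convention is what makes
negative R² values reproducible for the zero-order and Higuchi laws on
saturating curves. `compare_models` ranks by R² descending, breaking
ties by fewer parameters and then model name.

## Diffusion-coefficient estimation

The plane-sheet asymptotics apply with L the **half-thickness** of the
mat (the classical solution for a sheet releasing from both faces);
a measured full thickness must be halved, and the pipeline/CLI do this
when given `--thickness-cm`. Times are converted from hours to seconds
internally so D defaults to cm²/s.

* Short time: points with Mt/M∞ ≤ 0.6 (the standard validity range of
  the √t law) regressed through the origin against √t; slope s gives
  D = π(sL/2)².
* Long time: points with 0.4 ≤ Mt/M∞ < 1 regressed as ln(1 − Mt/M∞)
  against t; slope m gives D = −4L²m/π². The intercept is reported for
  comparison with the ideal ln(8/π²) ≈ −0.2100 as a model-adequacy
  diagnostic.

Both cutoffs are exposed as parameters. Points at or above M∞ are
excluded with a warning; nonpositive (short) or nonnegative (long)
slopes are flagged non-physical and D is not reported as a number in
that case. On data from the exact eigenfunction series both estimators
recover the generating D within 5 % and agree with each other within
10 %, and D scales exactly as L².

**M∞ policy.** How the total releasable amount is fixed is genuinely
open; the default is the Gompertz-fitted plateau Qmax (the plateau of
a saturating curve estimates M∞ better than any single observation),
with `"last"` (final observed point) and an explicit numeric value as
alternatives. The choice is recorded in every estimate.

## Photodegradation power law

Q(t_irr) = Qmax(1 + t_irr)^b is linear in log Q vs log(1 + t_irr), so
the default fit is the closed-form regression — deterministic and
exact on noiseless data (a two-point series is interpolated exactly).
An optional nonlinear refinement in the original coordinates
(`refine=True`) exists for strongly heteroscedastic data and is off by
default. A constant series yields b = 0 exactly.

"Loss" is reported two ways, because the phrase *x % lost* is
ambiguous: `loss_at` is the absolute difference Qmax − Q(t) in
percentage points (82 → 57 is a 25-point loss), and
`relative_loss_at` is that difference as a percent of Qmax
(≈ 30.5 % for the same endpoints). Both are monotone non-decreasing
for b ≤ 0.

## Surface roughness

Ra is the arithmetic mean and RMS the quadratic mean of the profile's
deviations from its mean line, computed as equal-weight discrete means
on the uniform sample grid (midpoint rule — no windowing, filtering or
end-effect correction). The mean line is subtracted first; integrating
the raw profile instead would assign a flat but offset profile a
nonzero Ra, which contradicts the definition of roughness. RMS ≥ Ra
by the power-mean inequality and both metrics are offset-invariant and
scale linearly — all property-tested. Image-derived profiles treat
gray level (0–255) as height; no physical height calibration is
attempted, so image Ra values are dimensionless gray levels.

## Retention and viability

Retention uses the signed-uptake convention
q = (Meq − M0)/M0 × 100: positive = liquid uptake, negative = net mass
loss. The opposite (mass-loss) convention is available as
`retention_mass_loss` for comparison with sources that define
retention as (M0 − Meq)/M0. Contact-angle replicates are summarized
as mean ± sample SD with a hydrophobicity flag at mean > 90°.

MTT viability subtracts the 655 nm background from the 595 nm signal
per well, then normalizes group means to the untreated controls **of
the same timepoint** (per-timepoint normalization; a single shared
baseline is not assumed). The standard error combines the two group
means' standard errors by the delta method for a ratio. Negative
corrected signals are kept but flagged — they usually mark failed
wells. Significance testing is deliberately out of scope; the tabular
layout exports cleanly to any statistics tool.

## Synthetic-data generators

The generators produce the study conditions the analyses assume:

* **Release curves**: any of the four laws plus Gaussian noise,
  additive SD 2 percentage points by default (a typical repeatability
  for UV–Vis release assays; no replicate SDs were available to
  calibrate against), with an optional proportional term for
  heteroscedasticity, truncated to [0, 105] %. Default grid: 12
  log-spaced times over 0.5–170 h, mirroring a week-long release
  experiment with dense early sampling.
* **Plane-sheet series**: Mt/M∞ = 1 − Σ 8/((2m+1)²π²)·
  exp(−(2m+1)²π²Dt/4L²), terms doubled until the dropped tail is below
  1e−10 (bound: Σ_{j≥m}(2j+1)⁻² ≤ 1/4m times the slowest dropped
  exponential); t = 0 returns exactly 0. Note the equilibrium approach
  is exponential, not instant: at dimensionless time Dt/L² = 5 the
  residual is ≈ 3.6e−6 of M∞, so "equals 100 %" holds to 1e−3
  percentage points there and to 1e−6 only by Dt/L² ≈ 10.
* **Surface profiles**: smoothed Gaussian field (Gaussian kernel,
  correlation length 10 samples, wrapped boundary), mean-centred and
  rescaled so the realized Ra equals the target exactly, offset to a
  mid-gray mean of 128.
* **Irradiation series** and **MTT plates**: the power law plus
  truncated Gaussian noise; plates use an untreated corrected signal
  of 0.65 AU (0.70 at 595 nm over a 0.05 AU background, SDs 0.03 and
  0.005 AU) scaled per group by a viability fraction in [0, 1.2].

Every generator is a pure function of (configuration, seed) via
`numpy.random.default_rng`; replicate batches derive child seeds with
`SeedSequence.spawn` so whole batches are reproducible.

What the generators do **not** emulate: within-curve autocorrelation
of assay errors, medium-withdrawal/replenishment artifacts, drug
degradation during the release test itself, inter-batch membrane
variability, and optical nonlinearity of plate readers. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to every artifact of real
release data.

## Pipeline and provenance

`run_pipeline` isolates stage failures (a failing stage is recorded in
the report's `errors` block; later stages still run) and embeds seed,
package version and a SHA-256 configuration hash in every report. No
wall-clock timestamp is written into the report itself so that
re-running the same configuration on the same inputs reproduces the
bundle bit-exactly; run times belong to the log stream instead.

## Known limitations

* Model selection is by R² only (by design); information criteria and
  bootstrap/profile-likelihood uncertainty for the kinetic parameters
  are out of scope.
* The diffusion estimators assume constant D, plane-sheet geometry and
  perfect sink conditions; cylindrical/spherical geometries are not
  implemented.
* The Gompertz Qmax is always fitted freely (bounded at 110 %); there
  is no option to pin it, which can matter for very short curves that
  never approach their plateau.
* Fits on fewer than ~8 points spanning less than two decades of time
  can leave β poorly identified even when the solver converges; the
  reported R² will not necessarily reveal this.
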