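# releasekit

Analysis toolkit for the release behaviour of drug-loaded electrospun
membranes: dissolution-model fitting and comparison, Fickian
diffusion-coefficient estimation, UV-photodegradation modeling, and the
supporting characterization metrics (surface roughness, liquid
retention, MTT viability), together with seeded synthetic-data
generators for all of them.

It is aimed at formulation and membrane scientists who measure
cumulative drug release Q(t) (percent of loaded drug vs. time) from
fibrous mats or films and want reproducible, scriptable versions of the
standard analyses rather than spreadsheet fits.

## Models

**Release kinetics.** Four classical laws are fitted to a release curve
by least squares and ranked by the coefficient of determination
R² = 1 − SSres/SStot (SStot about the observed mean, so R² < 0 means
"worse than a flat line"):

| model            | equation                               | parameters            |
|------------------|----------------------------------------|-----------------------|
| zero order       | Q = K₀·t                               | K₀ [%/h]              |
| Higuchi          | Q = K_H·√t                             | K_H [%/h^0.5]         |
| Korsmeyer–Peppas | Q = K_R·tⁿ                             | K_R [%/hⁿ], n [–]     |
| Gompertz         | Q = Qmax·exp(−α·exp(β·log₁₀ t))        | Qmax [%], α, β [–]    |

A Korsmeyer–Peppas exponent n ≤ 0.5 flags Fickian diffusion from a thin
film; the Gompertz β (negative) is the dissolution-rate shape parameter
and Qmax the plateau.

**Diffusion.** For a plane sheet of half-thickness L with constant
diffusivity D, fractional release f = Mt/M∞ follows
f = (2/L)·√(Dt/π) at short times and
1 − f = (8/π²)·exp(−π²Dt/4L²) at long times. Each regime linearizes
into a regression whose slope yields D (cm²/s when L is in cm; hours
are converted to seconds internally). The exact eigenfunction series is
available as a simulator and serves as the ground truth for testing the
asymptotic estimators.

**Photostability.** The 24-h released fraction after an irradiation
time t_irr is modeled as Q = Qmax·(1 + t_irr)^b, fitted in closed form
in log–log coordinates; b < 0 quantifies photodegradation of the
active compound.

## Worked example

Simulate one noisy burst-then-plateau release curve (Gompertz with
Qmax = 83 %, α = 0.83, β = −2.7; additive noise SD 2 points) and
compare all four models:

```python
from releasekit import GeneratorConfig, generate_release_curve, compare_models

curve = generate_release_curve(GeneratorConfig(seed=42, medium_label="PBS"))
print(compare_models(curve).summary())
```

```
Kinetic Model Comparison
============================================================
rank model                     R2  parameters
   1 gompertz              0.9921  Qmax=82.94, alpha=0.8128, beta=-2.647
   2 korsmeyer_peppas      0.6551  KR=47.24, n=0.1385
   3 higuchi              -1.5849  KH=10.2
   4 zero_order           -4.4471  K0=0.7669
============================================================
```

The sigmoidal Gompertz law recovers the generating parameters and wins
the ranking; the exponent n ≈ 0.14 ≤ 0.5 of the power law indicates
Fickian transport; the two non-saturating laws are worse than a flat
mean line (negative R²), as expected for a curve with a strong initial
burst and a plateau.

Diffusion coefficients from a plane-sheet release series
(D = 1e−8 cm²/s, L = 0.01 cm):

```python
import numpy as np
from releasekit import PlaneSheetDiffusion, generate_fickian_series_curve

curve = generate_fickian_series_curve(1e-8, 0.01, np.geomspace(0.05, 15, 30))
print(PlaneSheetDiffusion(curve, 0.01, m_inf=100.0).fit().summary())
```

reports `D: 9.967e-09 cm^2/s` (short-time regime) and
`D: 1e-08 cm^2/s` (long-time regime), with the long-time intercept
−0.2083 against the ideal ln(8/π²) = −0.2100 — both estimators recover
the generating D to within a few tenths of a percent on exact data.

Photodegradation from the two anchored endpoints (82 % unirradiated,
57 % after 10 h of UV):

```python
from releasekit import IrradiationSeries, fit_photolaw

fit = fit_photolaw(IrradiationSeries([0, 10], [82.0, 57.0]))
print(fit.qmax, fit.b, fit.loss_at(10))   # 82.0  -0.151661  25.0
```

i.e. a 25-percentage-point loss of releasable drug after 10 h.

A command-line front end mirrors the library
(`releasekit fit|compare|diffusion|photostab|roughness|retention|viability|simulate|run`);
`releasekit run --config config.yaml` executes the full pipeline and
writes a JSON + CSV report bundle.

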