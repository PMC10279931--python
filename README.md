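# tmflow

Tools for quantifying **segmental aqueous outflow** in the trabecular
meshwork (TM) of the mouse eye, and how fast its spatial pattern turns over.

Aqueous humour does not drain uniformly around the TM circumference: at any
moment only patches are filtration-active. Infusing two fluorescent tracer
colours separated by an interval Δt labels the active pattern at two time
points in the same eye. `tmflow` turns the resulting two-channel flat-mount
images into numbers:

1. **preprocess** — subtract background (mean of three 200×200 px ROIs in
   cornea/sclera) and restrict analysis to user-drawn TM polygons (outside →
   NaN).
2. **straighten** — resample each TM region along its piecewise-linear
   centreline (unit arc-length steps × unit normal offsets, bilinear
   interpolation) and concatenate the four regions into one rectangle
   covering the full circumference.
3. **profile** — cut the band into circumferential bins of ≈212 µm, take
   NaN-excluded per-bin means for both tracers, rescale the blue channel by
   the least-squares factor *s* = ΣRᵢBᵢ/ΣBᵢ², and label quadrants
   (nasal/temporal/superior/inferior, anchored at the corneal puncture site).
4. **stats** — per-eye Pearson *r* between the two binned profiles, then a
   cohort-level fit of

   &nbsp;&nbsp;&nbsp;&nbsp;*r*(Δt) = exp(−λ·Δt),&nbsp;&nbsp; τ = ln2/λ,

   where the half-life τ is the interval at which two outflow patterns lose
   half their spatial correlation. 95% CIs come from a bootstrap over eyes.
   One- and two-sample t-tests compare groups (ages, in vivo vs ex vivo).
5. **synthetic** — a generator with exact ground truth: Gaussian random
   fields on the circle (squared-exponential covariance, spectral synthesis)
   evolved by the stationary AR(1) update f₂ = ρf₁ + √(1−ρ²)ε with
   ρ = exp(−ln2·Δt/τ), rendered into annular flat-mount images or emitted
   directly as binned profiles.

## Worked example

Simulate a cohort with the standard design (Δt ∈ {0, 2, 7, 14} days, 5–6
eyes each) at a generating half-life of 5 days, analyse every eye and fit
the decay:

```python
import numpy as np
import tmflow as tf
from tmflow import synthetic as syn
from tmflow.pipeline import analyse_profile

groups = tuple(syn.CohortGroup(f"dt{d:02d}", float(d), n)
               for d, n in [(0, 5), (2, 5), (7, 5), (14, 6)])
design = syn.CohortDesign(groups=groups, seed=42,
                          model=syn.FieldModel(half_life_days=5.0))
records, table = syn.generate_cohort(design)
dts, rs = [], []
for rec in records:
    a = analyse_profile(rec.profile, side=rec.side, delta_t_days=rec.delta_t_days)
    dts.append(rec.delta_t_days); rs.append(a.correlation.r)
res = tf.ExponentialDecayModel(dts, rs).fit(n_boot=2000, seed=0)
print(res.summary())
```

```
Exponential decay of tracer-pattern correlation
===============================================
model form        r = exp(-lambda*dt)
n eyes            21
half-life (days)  3.92
rate (1/day)      0.1769
95% CI (days)     [2.63, 5.63]  (bootstrap, 2000 resamples)
amplitude         1
residual SSE      0.6245
converged         True
```

The group-mean correlations for this cohort were 1.000, 0.643, 0.332 and
0.083 at Δt = 0, 2, 7 and 14 days: simultaneous tracers are perfectly
correlated, and the correlation halves roughly every 4–5 days. The fitted
half-life (3.92 d, CI [2.63, 5.63]) brackets the generating value of 5 d —
with ~21 eyes and ~15–20 effectively independent pattern patches per
circumference, this spread is what a real cohort of this size delivers.

The same analysis runs from the shell:

```
tmflow simulate --out cohort --seed 42
tmflow analyse  --cohort cohort --out analysis
tmflow fit      --eyes analysis/eyes.csv --out fit
```

## Layout

| module | contents |
| --- | --- |
| `tmflow.preprocess` | `FlatMountImage`, background correction, TM masking |
| `tmflow.straighten` | polyline straightening, region concatenation |
| `tmflow.profile` | binning, NaN-excluded means, channel scaling, quadrants |
| `tmflow.stats` | `ExponentialDecayModel`/`Results`, Pearson/pooled r, t-tests, difference images |
| `tmflow.synthetic` | circular Gaussian fields, AR(1) evolution, rendering, cohorts |
| `tmflow.pipeline` | per-eye and per-cohort orchestration |
| `tmflow.cli` | `tmflow simulate / analyse / fit` |

See `docs/methods.md` for the model, parameter choices and limitations.
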