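# Methods

## The measurement and its model

Two tracer colours infused Δt days apart deposit in whichever TM segments
were filtration-active at each infusion. After flat mounting, each eye gives
two registered fluorescence channels over the same tissue. The analysis
reduces each channel to a circumferential *tracer intensity profile* (per-bin
mean intensity versus position along the TM) and summarises their agreement
by the Pearson correlation *r* over bins. Across eyes, the decline of *r*
with Δt is modelled as

    E[r] = A · exp(−λ·Δt),        τ = ln 2 / λ,

with *A* fixed at 1 by default: simultaneously delivered tracers label the
same pattern, so their expected correlation at Δt = 0 is 1 up to measurement
noise. A free-amplitude form (`model_form="free"`) is provided because real
cohorts show r(0) slightly below 1; with the amplitude profiled out
analytically the optimisation stays one-dimensional either way. Eyes are
weighted equally and treated as independent samples (left and right eyes of
one animal carry independent segmental patterns).

The model is deliberately phenomenological. It carries no tracer-transport
physics, no intraocular pressure, and no distal vasculature; τ only
quantifies how quickly the spatial arrangement of active segments becomes
unrecognisable.

## Pipeline conventions

* **Background.** Each channel subtracts the mean of its own three 200×200 px
  ROI means (one central cornea, two sclera). A pooled two-channel scalar is
  available (`per_channel=False`). Negative post-subtraction values are kept:
  clipping would bias bin means and hence *r*, which is invariant under the
  per-channel affine shift.
* **TM domain.** A pixel is in-domain iff its centre (integer col/row
  coordinate) lies inside any of the user polygons, even-odd rule.
  Self-intersecting polygons are rejected. Everything outside is NaN from
  then on.
* **Straightening.** Unit-spacing samples along the centreline arc length;
  unit normal offsets spanning the band height; bilinear interpolation;
  both channels sampled at identical coordinates. Tangents come from central
  differences of the resampled path, so interior polyline vertices get
  angle-bisector (miter) normals; no spline smoothing — for the shallow
  corner angles of manually drawn centrelines the difference from a
  spline-based straightener is sub-pixel. The per-eye strip height defaults
  to the 90th percentile of local mask thickness along the centrelines;
  overshoot becomes NaN and drops out of the means.
* **Binning.** n_bins = round(width_µm / 212 µm), minimum 1; integer column
  widths distributed largest-remainder so they differ by at most one column.
  Rounding (not flooring) keeps the achieved width closest to the 212 µm
  target and reproduces 45 bins at the physiological ~9.54 mm circumference.
  Bins with zero valid pixels are flagged and excluded from every downstream
  sum; partially valid bins are kept regardless of their valid fraction
  (NaN exclusion is pixel-wise, not bin-wise).
* **Channel scaling.** s = ΣRᵢBᵢ/ΣBᵢ² multiplies the blue channel; it is the
  exact least-squares minimiser of Σ(Rᵢ − s·Bᵢ)². Computed over bin means by
  default; a pixel-level mode exists (`scaling_factor_pixels`) and the choice
  provably leaves *r* unchanged — it only matters for difference images and
  display.
* **Quadrants.** The circumferential origin is the puncture-site landmark,
  which sits at the centre of its quadrant: inferior for OD, superior for OS;
  OS mirrors OD (superior ↔ inferior).
* **Difference images.** Scaled blue minus red by default (positive = local
  filtration increased between labels); the order is a flag since either
  convention is defensible. Rendering maps positive → green, negative → red,
  NaN → black.

## Statistical choices

* Per-eye *r* requires ≥ 3 valid bins and non-degenerate variance in both
  channels; slope/intercept CIs use the t distribution with n − 2 df.
* The decay fit minimises the SSE over λ with a 200-point log-spaced scan
  (τ ∈ [10⁻³, 10⁴] d) to bracket the optimum — the objective is flat to
  machine precision for large λ, where a naive bounded search can stall —
  followed by bounded Brent polish (xatol 10⁻¹⁴). Noiseless model data are
  recovered to better than 6 significant digits.
* The 95% CI for τ is a nonparametric bootstrap over eyes (default 2000
  resamples, seeded); resamples with a single distinct Δt are dropped. The
  choice of bootstrap is a package decision; profile-likelihood or asymptotic
  intervals would be equally defensible.
* t-tests operate on raw *r* values (one-sample against 0; unpaired
  two-sample with pooled variance), matching common practice in this
  literature; a Fisher-z switch is provided as a sensitivity analysis.
  Zero-variance samples are handled explicitly (t = 0, p = 1 when means
  agree; |t| → ∞, p → 0 flagged otherwise).

## The synthetic generator

The underlying segmental pattern is a zero-mean stationary Gaussian field on
the circle with squared-exponential covariance
cov(d) = σ²·exp(−d²/2ℓ²), sampled spectrally (circulant eigenvalues via FFT),
so periodicity and the covariance are exact. Temporal change is the
stationary AR(1)/OU update f₂ = ρf₁ + √(1−ρ²)ε with ρ = exp(−ln2·Δt/τ), so
corr(f₁, f₂) = ρ analytically and the decay law holds by construction rather
than approximately.

Defaults (one-time choices, with units):

| parameter | default | rationale |
| --- | --- | --- |
| correlation length ℓ | 300 µm | segmental clusters span a few hundred µm to mm; 300 µm gives ~15–20 independent patches per circumference and a per-eye spread of *r* comparable to real cohorts |
| half-life τ | 5 d | the headline turnover scale for young adult mice |
| marginal σ | 1 (a.u.) | free scale; intensity map absorbs units |
| baseline / gain | 100 / 20 | baseline ≥ 4·gain·σ keeps rendered intensities nonnegative without truncating the Gaussian — truncation would distort the analytic correlation law |
| channel gain ratio | 0.6 | blue dimmer than red, so the least-squares factor works upward as in real data |
| noise sd | 4 (a.u.) | per-pixel; per-bin noise on the fast path is noise_sd/√(pixels per bin) |
| pixel size | 1.30 µm/px | from the paired µm/px bin dimensions of the imaging setup (212.0 µm ≈ 163 px) |
| geometry | 2600² px, band radius 1168 px, height 278 µm, 4 regions | physiological ~9.54 mm limbal circumference; four clover-leaf regions with 12 px incision gaps |

Rendering paints I(θ) = baseline + gain·f(θ) uniformly across the band
height, multiplies blue by the gain ratio, adds a bright puncture marker
corneal-side of the band, a constant background, and per-pixel Gaussian
noise (negatives from noise clipped at 0). `annotate_geometry` supplies the
polygon ROIs, centrelines and background ROIs that a human would draw;
centrelines start 4 px inside the incision gaps with ~12 px vertex spacing —
as an annotator does — which keeps bilinear interpolation at strip ends from
bleeding across the gap boundary.

What the generator does **not** emulate: optics (no PSF, vignetting or tile
seams), tracer-retention loss, anterior–posterior intensity structure within
the band (intensity is constant across the height), within-animal
correlation between paired eyes, and irregular hand-cut region shapes.
Passing tests therefore validate the geometry, bookkeeping and statistics of
the pipeline and the self-consistency of the decay analysis — not robustness
to the full messiness of real flat mounts.

## Validation problem sizes

The test suite runs the analytic-law checks with 10⁴-sample grids averaged
over 20–60 field pairs; the image round trip at the full default geometry
with zero noise (profile/ground-truth correlation > 0.99); parameter
recovery with 100 simulated cohorts per generating τ ∈ {2, 5, 10} d, each
with the standard design (Δt ∈ {0, 2, 7, 14}, 5–6 eyes) and 500 bootstrap
resamples per fit; and null behaviour with 10⁴ six-eye null cohorts
(vectorised). These sizes make the whole suite run in about a minute while
keeping Monte-Carlo error comfortably inside each tolerance.

## Known limitations

* The squared-exponential spatial covariance is a smoothness assumption; no
  quantitative spatial statistics of real tracer patterns were available to
  fit ℓ or the covariance family.
* Bin-level correlations ignore spatial autocorrelation between neighbouring
  bins; *r* is reported as a descriptive statistic exactly as practitioners
  do, and the per-eye regression CIs inherit that caveat.
* The decay fit assumes a common τ across eyes within a cohort;
  heterogeneity shows up only through the bootstrap CI.
* Straightening assumes the hand-drawn centreline stays near the band's
  middle; grossly eccentric centrelines shift bin content but leave the
  NaN-exclusion machinery intact.
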