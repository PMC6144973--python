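# Methods

This note records the models, algorithms and parameter choices behind
`ovoscope`, the assumptions they rest on, and what the synthetic-data
generator does and does not emulate.

## Radiometry

Raw camera counts are assumed to follow a monotone response
`counts = full_scale · radiance^(1/γ)` (or an explicit increasing lookup
curve). Linearization inverts this; normalization scales each band
independently so the mean linear signal over the grey-standard patch maps
to the standard's nominal reflectance (40% by default). Two guards:

- **Saturation**: pixels within 1% of full scale are flagged and excluded
  from patch means (a fully saturated patch is a calibration failure).
- **Over-range reflectance**: values above 100% (specular highlights) are
  flagged, never clipped; all downstream means use unflagged pixels only.

Normalization is scale-invariant (multiplying all counts by k > 0 changes
nothing) and band-independent by construction. Vignetting and flat-field
correction are out of scope: the synthetic scenes are rendered under
spatially uniform illumination, and real images with strong vignetting
would need correcting upstream.

## Spot segmentation

A pixel inside the RoI is a spot candidate when its across-band VIS
reflectance lies at least `offset_pp` (default 5 percentage points) below
the local RoI mean within a `window_px` (default 31 px) square window;
the local mean is computed with a masked filter so pixels outside the RoI
never contaminate it. Candidates are cleaned by a morphological opening
(radius-1 disk), connected with 8-connectivity, and components smaller
than `min_spot_px` (default 9 px) are dropped. The defaults were chosen
on noiseless synthetic fixtures with ≥10 pp contrast and ≥5 px spot
diameter, where the segmentation recovers counts exactly and spottiness
to well under 1 pp; they are configuration values, not constants, because
real spot/background contrast varies. Spottiness is defined as
100 · spot area / RoI area, with the RoI exactly as drawn.

A spotless egg reports NaN for spot reflectance and size (written as a
blank CSV field, never 0): a zero would masquerade as a measurement.

## VIS→UV registration (Local Weighted Mean)

UV sensitivity of converted cameras is poor, so spots are segmented in
the VIS frame and transferred to the UV frame through a space-variant
transform fitted from at least 13 manually marked control-point pairs
(fitting refuses below 13). The LWM construction used here:

- For each control point, a second-order bivariate polynomial per output
  axis is least-squares fitted to its 12 nearest control points under the
  constraint that it passes exactly through its own pair (the constrained
  basis is the quadratic monomials vanishing at the point).
- Each polynomial's influence radius is the distance to the farthest
  neighbour used in its fit; its blend weight at an evaluation point is
  `((1−t)₊)²/t²` with `t = distance/radius` — radially decreasing,
  vanishing at the radius, and diverging at the control point itself.

Weights are normalized to sum to one wherever at least one kernel is
active, which makes the transform exactly interpolating (the diverging
weight hands full control to the anchored polynomial) and exactly
reproduces any global affine map (quadratics contain affines; zero
residual at every neighbourhood). The classical formulation leaves the
kernel shape open; this singular-Shepard form was chosen precisely for
those two checkable guarantees. Locations outside every kernel fall back
to the nearest point's polynomial and are logged — extrapolation there is
unreliable, but such locations only occur far from the egg.

Masks are transferred by inverse mapping (an LWM fitted with the roles of
the frames swapped) with nearest-neighbour sampling, keeping the output
strictly binary; this is the documented mask contract, at the cost of
±half-pixel edge effects, which bound the UV reflectance error on
fixtures to about 1 pp.

## Morphometry

The RoI outline is revolved about its long axis, the direction through
the two most distant boundary vertices. At each of 200 stations the
outline is cut perpendicular to the axis and the radius taken as the mean
of the two half-widths — the revolved solid cannot represent bilateral
asymmetry, so the outline is symmetrized. Volume and surface use the
composite trapezoid rule with central differences for r′ (one-sided at
the poles). At 200 stations a rasterized sphere and prolate spheroid are
recovered to ~0.05%, and doubling the station count moves the result by
<0.1%; the pole regions, where r′ diverges, are the dominant error and
stay far below the 0.5% working tolerance. Scale comes from the
photographed scale bar (`mm_per_px = known_mm / pixel distance`).

## Mixed models

All models are Gaussian: `y = Xβ + Σ_k Z_k u_k + ε` with
`u_k ~ N(0, σ²θ_k I)`. For fixed variance ratios θ the GLS β and profiled
σ² are closed form, so fitting is a 1–2 dimensional optimization of the
profiled ML or REML objective over log θ (bounded scalar search for one
component, Nelder–Mead with three starts for more). A ratio below 1e−6 is
flagged "random effect at boundary". The profiled log-likelihood equals a
dense multivariate-normal evaluation to machine precision (a test
enforces 1e−6), and ML/REML coefficients and likelihoods match
statsmodels' MixedLM on random-intercept models.

**Penalized smooths.** A cubic regression spline with basis dimension 5
(interior knots at covariate quantiles — the ≤5-knot cap guards against
over-fitting at n ≈ 110) carries a second-divided-difference penalty on
its coefficients at the Greville abscissae, whose null space is exactly
the linear functions; the smooth therefore decomposes into a linear
column in X and a penalized "wiggle" block whose variance ratio is the
inverse smoothing parameter, estimated by the same profiled likelihood.
As λ→∞ the fit collapses exactly to the least-squares line. The reported
edf is 1 (the linear part) plus the trace of the wiggle block of the
influence matrix, so a smooth's edf lies in [1, 4].

**Model comparison.** AICc with k = fixed coefficients + residual
variance + one per variance component and smoothing parameter; this
bookkeeping reproduces the df column of the study's comparison tables
(null = 3, one linear covariate = 4, year + latitude = 5, year +
s(latitude) = 6, year + sv + quartic insolation = 9). The random-effect
assessment compares REML AICc with/without the site intercept under the
full parametric fixed model; fixed-effect sets are compared under ML.
Akaike weights, a competitive flag (Δ ≤ 2) and an uninformative-extra
flag (competitive superset of the best model) are reported; nothing is
pruned. `selected_label` additionally applies the parsimony screen the
method prescribes — among competitive models, extra parameters that
cannot beat a simpler rival by more than 2 AICc are read as uninformative,
so the most parsimonious competitive model is reported. Under a true
null this matters: some spurious one-parameter extension attains the
strictly lowest AICc in roughly a quarter of replicates (the expected
χ²₁ exceedance), while the screened outcome settles on the null in ~90%.

Polynomial terms use centered, unit-SD covariates raised to powers 1..d
(raw, not orthogonal); coefficients are reported on that standardized
scale, and the back-transformation is the usual division by the
covariate's SD powers. p-values come from t statistics with n − k
residual df and are flagged approximate.

**R².** Marginal R²m = var(Xβ̂)/(var(Xβ̂)+σ²_site+σ²_ε) and conditional
R²c add σ²_site to the numerator (population variance of the fitted
fixed part over the data). They are reported for parametric models only;
smooth models show a dash. **Concurvity** between two terms is the
fraction of one term's centered fitted contribution explained by
projection onto the other's basis: 0 = none, 1 = unidentifiable.

**PCA.** Eigen-decomposition of the Pearson correlation matrix of the
seven log traits (spot number uses log(x+1) so spotless eggs remain
admissible; a zero-spottiness egg is flagged incomplete and excluded from
the PCA rather than silently dropped — the museum series this emulates
contained only spotted eggs, so the case is a synthetic-data edge).
Sign convention: PC1 oriented so the VIS background-reflectance loading
is positive (positive scores = lighter eggs), PC2 so the spot-size
loading is positive.

## The synthetic generators

**Image pairs.** The egg is a two-parameter ovoid of revolution,
`r(u) = (B/2)√(1−u²)(1+c·u)` (length L, breadth B, asymmetry c), whose
reference volume and surface come from adaptive quadrature at ~1e−9
relative tolerance. Scenes are defined analytically (ovoid, circular
spots placed fully inside the egg with bounded retries, a rectangular
40% standard patch, a 10 mm scale bar) and rasterized at pixel centers;
counts apply the gamma response with additive Gaussian count noise. The
UV image is the same scene viewed through a smooth VIS→UV warp
(superposed Gaussian bumps, peak displacement normalized to the requested
magnitude, default 4 px — the protocol's misregistration magnitude is not
documented, so a few pixels was chosen as the plausible scale of a lens
refocus between filter changes) and rendered at twice the VIS noise SD to
mimic degraded UV signal-to-noise. Control points are sampled at integer
pixels inside the RoI, partners computed exactly from the warp. Not
emulated: real shell texture and gloss, vignetting, chromatic aberration,
camera spectral sensitivity curves, demosaicing. Passing tests therefore
demonstrate the pipeline's correctness on geometrically and
radiometrically faithful scenes, not robustness to those optical effects.

**Trait datasets.** 30 sites at latitudes 11–55°N; site-level insolation
falls linearly with latitude (1.0 − 0.01·lat kW/m², SD 0.02) and
temperature likewise (40 − 0.35·lat °C, SD 1.5), mirroring the reported
latitudinal gradients. Egg counts per site are Poisson(110/30), so a
dataset averages 110 eggs. The lightness axis is generated as

    PC1 = 0.027·(year − 1915) + q(insolation) + 69.850·(sv − 0.23)
          + site intercept + noise,

with years uniform on 1858–1972 and sv ~ N(0.23, 0.00623) mm⁻¹. The
quartic q is built from polynomials orthogonalized under the insolation
distribution with 55% of its variance in the pure fourth-order component,
signs giving the reported curve shape (darker at both insolation
extremes, lightest near 0.8 kW/m²). The variance scales are anchored to
the study's printed summaries: total PC1 variance equals the first
correlation-PCA eigenvalue (0.63 × 7), fixed effects explain 45% of it
and fixed + site 48% (the reported R²m/R²c), the fourth-order share is
set by the printed R²m contrast between the cubic and quartic models, and
the sv scatter by the printed SE of the sv slope. The centering
references (year 1915, sv at its mean) are a choice — the study reports
slopes only, which centering does not affect. PC2 carries no fixed
structure: site intercept + noise with total variance 0.22 × 7 and 27% of
it between sites (the reported conditional R²). Because covariates are
drawn independently (beyond the latitude links), recovery tests certify
unbiasedness under the generating model, not robustness to confounding
between year, egg size and environment that a museum series may contain.

## Numerical and interface choices

- Determinism: every stochastic routine takes a seed; identical seed and
  parameters give bit-identical images, tables and manifests (SHA-256
  checksums in the simulate manifest).
- Coordinates: origin top-left, x rightward, y downward, 0-based; RoIs
  and patches are (x, y) polygon vertex lists in JSON sidecars; images
  are 16-bit TIFF.
- The measure command row-flags per-egg failures (missing sidecar, too
  few control points — the UV columns stay blank and the VIS side still
  runs) and continues; the analyze command accepts either the seven
  traits (running log + PCA first) or precomputed pc1/pc2 scores.
- Degenerate inputs: self-intersecting RoIs, coincident scale points,
  fully spotted eggs, constant traits, single-site tables and saturated
  standard patches all raise typed errors naming the problem.

## Known limitations

- The LWM inverse used for mask transfer is a reverse-direction fit, not
  the analytic inverse; for the few-pixel warps of interest the
  discrepancy is far below the nearest-neighbour quantization.
- The segmentation is a single fixed algorithm (adaptive threshold +
  opening); heavily textured or gradient-lit shells would need parameter
  retuning or a different segmenter.
- Smooth-term edf and the AICc df bookkeeping follow one explicit
  convention; other software counts differently, so absolute AICc values
  are comparable only within this package.
- Concurvity is reported pairwise for fitted terms, not as a full
  worst-case decomposition.
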