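# Methods

This note documents the models, algorithms and numerical choices behind
`hsdfm`, and what the synthetic-data experiments do and do not demonstrate.

## Reflectance cubes

A raw acquisition is a stack `I(m, n, λ)` of narrow-band images (default
grid 480–650 nm, 5 nm steps, 8 nm bandwidth; 35 bands) with per-band
exposure times `Δτ(λ)` chosen by the instrument to fill the camera's
dynamic range.  Reflectance is

```
X(m,n,λ) = (I/Δτ₁ − I_dark/Δτ₂) / (I_ref/Δτ₃ − I_dark/Δτ₄)
```

where the reference (white standard) and dark cubes are averaged over the
field of view to spectra before use.  One dark acquisition serves both the
numerator and denominator; the two dark exposure vectors default to equal
but may differ (`dark_exposure_denominator`).  Negative numerators (dark
exceeding signal in a noisy band) are deliberately kept rather than
clipped: clipping would break the linear mixing model the unmixing stage
depends on.  A non-positive denominator in any band raises an error naming
the offending wavelength.  Cube axis order is pinned to (row, col, band),
row-major, origin top-left, for raster I/O round trips (ENVI BSQ written;
BSQ/BIL/BIP read; multi-page TIFF with a JSON sidecar as the alternative).

### Spatial flattening

Long-range illumination non-uniformity is removed per band by dividing by
a unit-mean Gaussian-blurred estimate of the illumination field
(default σ = 50 px; an anisotropic (σ_row, σ_col) pair gives a directional
blur).  The estimate is iterated to a fixed point — divide, re-blur,
re-divide, until the blurred result is uniform to 1e−6 or 100 iterations —
which makes the operator idempotent (re-flattening changes values by less
than 1e−3 relative) and preserves each band mean exactly by a final
rescale.  Two caveats are inherent to retrospective flattening and worth
knowing: structure at scales at or above σ is treated as illumination
(real features of that size are flattened too), and edge bias limits how
well gradients spanning the whole image can be removed when σ approaches
the image size.  Flattening is applied per band; whether a broadband
(shared) field would be preferable is an open design choice — per-band
fields also absorb wavelength-dependent non-uniformity, which is why they
are the default here.

## Supervised route: SAM with OSCA thresholds

Endmembers are per-band means (with per-band standard deviations and pixel
counts) over annotated regions of interest.  The spectral correlation
angle between a pixel spectrum and an endmember,
`α = arccos(x·μ/(‖x‖‖μ‖))` clamped to [0, π/2], is scale-invariant, so
amplitude variations (illumination residue, specimen thickness) do not
affect classification.  Zero-norm pixels have no direction; they are
assigned angle π/2, counted, and always classified as background.

A tissue's segmentation map marks pixels with `α < αᵗʰ` (strict, per the
printed rule; boundary pixels are excluded).  The threshold is anchored by
the orthogonalized SCA: given a reference cube known to contain none of
the tissue (a fat-only cube for non-fat endmembers, a benign-fibroadenoma
cube for fat), the fill-factor curve `f(β̄) = #{β(m,n) ≤ β̄}/N` of the
angle map against the reference rises sigmoidally to 1, and the OSCA is
the smallest threshold with `f > 0`.  On a uniform grid this rounds the
minimum reference angle up to the grid; `build_library` evaluates it on
the exact grid formed by the reference angles themselves (the grid-step→0
limit of the sweep), so the stored OSCA equals the minimum reference angle
and segmenting the reference at its own OSCA yields exactly zero positive
pixels — the zero-false-positive construction the threshold exists for.
A uniform-grid curve (default 0.01 rad steps up to π/2) is retained for
display, and per-type threshold overrides support manual sweeps above the
OSCA.  The companion coverage curve counts strictly (`α < t`), matching
the segmentation rule; at π/2 it equals 1 minus the degenerate-pixel
fraction.

The integrated map assigns each pixel, among the types passing their
thresholds, the one with the smallest angle; exact ties (a measure-zero
event on real data) go to the earlier library entry and are logged.  The
library serializes to versioned JSON and round-trips byte-identically.

## Unsupervised route: K-means + NNLS

Stacked cubes become a pixel matrix `X ∈ ℝⁿˣᵖ`.  Lloyd's algorithm runs on
the reflectance rows as-is — no per-pixel normalization, since amplitude
is informative — with initial centers drawn uniformly without replacement
from the *distinct* rows, 10 restarts by default, convergence when the
assignment stabilizes (cap 300 iterations), and empty clusters re-seeded
from the farthest point.  The best-objective restart is returned; the
objective is recomputable exactly from the partition.  Clusters are ranked
by their share of the between-cluster variance,
`|Sᵢ|·‖μᵢ − x̄‖² / Σⱼ|Sⱼ|·‖μⱼ − x̄‖²` ("percentage of variance" admits
several readings — within-cluster share and pixel-count share are the
alternatives; the between-cluster share is implemented because it directly
measures how much structure a cluster explains).  Abundances solve
per-pixel NNLS against the endmember matrix; they are *not* normalized to
sum to one (only nonnegativity is imposed), and display scaling of the
3-color composites (each channel to its own maximum) is separate from the
stored values.

## Cross-validation

Centroids are paired to library endmembers greedily by ascending spectral
angle, with a 0.3 rad cap beyond which clusters stay unmatched.  The
residual ratio `(μˢᵘᵖ − μᵘⁿˢᵘᵖ)/μᵘⁿˢᵘᵖ` is computed bandwise after
normalizing both spectra to unit band-mean (the supervised route is
scale-free while centroids carry amplitude; without alignment the metric
conflates shape with gain — a raw mode is available).  Spatial agreement
is scored by the Dice coefficient between the binary segmentation and the
abundance map thresholded at half its maximum.  A pair passes when the
maximum absolute residual is below 2% and Dice meets the configured floor.

## Synthetic scenes

Tissue spectra are analytic templates constrained by the qualitative
dark-field features of breast tissue: blood — declining baseline with
Gaussian oxy-hemoglobin absorption dips at 540 and 575 nm; fat — sigmoidal
rise below 550 nm, nearly flat above; three fibrous-tissue (ICT) variants
— negative linear slopes with a 3–4% sinusoidal ripple at distinct periods;
epithelium — ICT-like, nearly flat, reduced ripple; and four carcinoma
shapes (IDC: declining with a broad shallow depression around 580 nm;
phyllodes: deeper, more curved dip; IMC and ILC: concave-down with local
maxima near 590 and 520 nm).  No quantitative tissue spectra are published
as tables, so the templates are the package's own constructions; their
free parameters were fixed once so that all pairwise spectral angles are
at least 0.1 rad (verified by a test), keeping the scenes separable by
angle-based classification without being trivially easy.

A scene is a set of rectangular regions with nonnegative mixing weights
(sum ≤ 1) over templates.  The generator converts true reflectance into
raw counts through a smooth synthetic lamp×sensor response, per-band
exposures mimicking an auto-scan, an additive dark rate (2 counts/ms), an
optional smooth multiplicative illumination field, and i.i.d. multiplicative
Gaussian noise on the sample counts (a shot-noise proxy; Poisson counts
would add realism but none of the analysis consumes count statistics).
The emitted dark and reference cubes are consistent with the forward
model, so reflectance normalization recovers the planted mixture exactly
in the noiseless case.  Reference specimens (fat-only, fibroadenoma-only)
get a smooth per-pixel amplitude texture with a fixed spectral shape.
Everything is driven by one seed and is byte-reproducible.

The standard study scene (128×128, five tissues: blood, fat, ICT, IDC,
IMC) uses five stripes whose cores are pure (≈17% of the pixels each,
comfortably above the 10% pure-pixel floor) with four-row mixed-gradient
patches spanning a third of the columns at each internal boundary.  The
mixed boundaries emulate the sub-pixel mixing always present at real
tissue interfaces, and they matter algorithmically: with fully isolated
pure clouds, randomly initialized Lloyd iterations can place two centers
in one cloud and none in another and have no gradient to migrate along,
occasionally merging two tissues even with 10 restarts.  The bridge pixels
restore reliable recovery (verified over 40 seeds) at the cost of a small,
quantified centroid bias (worst carcinoma residual ≈ 1%).  A pure-stripe
variant (`pure_stripe_regions`) is used for the exact-recovery tests.

What passing synthetic tests does **not** show: robustness to spatial
texture within tissues, instrument point-spread blur, wavelength
mis-calibration, specular contamination, or tissue spectra outside the
template family.  The synthetic study validates the algorithmic chain, not
the biological claim.

## Phantom optics

Mie coefficients for a homogeneous sphere use the logarithmic-derivative
downward recurrence (started 16 orders above the truncation
`x + 4x^{1/3} + 2`), with Riccati–Bessel functions by upward recurrence —
stable and accurate to machine precision for the sub-micron size
parameters involved (cross-checked in tests against a direct
spherical-Bessel evaluation and the analytic Rayleigh and index-matched
limits).  Refractive-index dispersions are pinned Cauchy fits:
polystyrene `n = 1.5725 + 0.0031080/λ² + 0.00034779/λ⁴` (λ in µm) and
water `n = 1.3199 + 6878/λ² − 1.132e9/λ⁴ + 1.11e14/λ⁶` (λ in nm) — smooth,
standard forms adequate to a few 1e−3 over 400–800 nm.  Bulk properties
assume independent scattering in the dilute regime (volume fraction
< 0.01, warned otherwise): `μₛ = ρ·Q_sca·π(d/2)²` with number density
`ρ = φ/(πd³/6)`, hence μₛ and μₛ′ = μₛ(1−g) exactly linear in φ.

The Monte-Carlo model launches photons uniformly over a 5 mm source disc
at 15° incidence into a semi-infinite medium, samples exponential free
paths with μ_t = μ_s + μ_a, scatters by inverse-CDF sampling of the
tabulated Mie phase function (1024-point cosine grid — not a
Henyey–Greenstein surrogate, since the bead phase function is exactly
known), and handles absorption by survival weighting with Russian-roulette
termination below 1e−4 weight.  A photon is collected if it crosses the
surface inside the concentric 1.6 mm field of view with polar exit angle
below `asin(NA/n)` (NA = 0.13, n = 1.33 assuming an aqueous interface);
that cone (≈5.6°) is smaller than the incidence angle, so unscattered
light is never collected — the dark-field condition, enforced as a
geometry invariant.  The boundary is refractive-index matched (no Fresnel
step) by default; the true instrument boundary (coverslip) is not
described well enough to pin, and a Fresnel treatment would be the natural
extension.  Photons deeper than 10 mm (several transport mean free paths
for all phantoms considered; deep returners re-emerge spread far beyond
the field of view and contribute negligibly — verified against a 50 mm
cutoff within Monte-Carlo error) or exceeding 20 000 scattering events are
tallied in a cutoff bucket, so with μ_a = 0 the collected, escaped and
cutoff weights sum to the injected count to machine precision.  The
standard error comes from the per-photon outcome variance; all runs are
seeded and bit-reproducible.

The look-up table simulates R(φ, λ) on the φ grid 0.0005–0.005 (step
0.0005) and λ grid 400–800 nm (step 25 nm) by default, storing Monte-Carlo
standard errors and μₛ′(λ) per row, serialized as a plain-text table with
a provenance header (seed, photon count, geometry) that reloads
bit-identically.  Inversion of a measured spectrum least-squares fits the
piecewise-linear interpolation between φ rows; within each interval the
objective is quadratic with a closed-form minimizer, so grid-node spectra
invert exactly and off-grid fractions resolve to the interpolation
tolerance.  Default desk-scale photon budgets are 10⁶ per point for
single-wavelength studies (enough for 3-σ ordering of the 0.001/0.002/
0.003 volume fractions) and 10⁵ per LUT node; statistical error scales as
1/√N.

## Problem sizes and runtime

The shipped study sizes are chosen so a full run is interactive on one
CPU: the ten-seed carcinoma agreement study (128×128 scenes, k = 5,
10 restarts) completes in well under a minute; the three-fraction
Monte-Carlo ordering check at 10⁶ photons takes about two minutes; the
whole test suite runs in a few minutes.

## Known limitations

- Templates are qualitative stand-ins; no claim of quantitative fidelity
  to any real tissue spectrum is made or needed by the tests.
- K-means on raw reflectance inherits the usual sensitivity to relative
  cluster variances; the ranking heuristic is one of several defensible
  readings of "variance explained per cluster".
- Greedy endmember matching is not a globally optimal assignment in
  adversarial geometries; it coincides with it whenever each centroid has
  one clear nearest library spectrum (the regime the tests verify).
- The Monte Carlo omits polarization, finite sample thickness, bead
  polydispersity and Fresnel boundaries.
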