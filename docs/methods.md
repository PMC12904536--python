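# Methods

## Transport model

Light propagation is modeled as a photon random walk solving the radiative
transport equation.  Steps are sampled from the free-path distribution
`s = −ln ξ / μt` with `μt = μa + μs`; at each interaction the photon weight
is multiplied by the single-scattering albedo `μs/μt` (implicit capture)
and the direction is deflected by a Henyey–Greenstein angle with anisotropy
`g` (inverse-CDF sampling; `E[cos θ] = g`).  Weights below 10⁻⁴ enter
Russian roulette with survival probability 0.1 — the standard MCML
variance-control pair; both constants are module-level and unbiased by
construction.  Refractive-index boundaries use unpolarized Fresnel
coefficients with stochastic reflect/transmit decisions; total internal
reflection returns the photon to the medium.  Specular reflection at first
surface contact is tallied separately and excluded from diffuse reflectance
(the integrating-sphere convention).

Units: lengths in mm, coefficients in mm⁻¹, wavelengths in nm.  The
canonical spectral grid is 400–700 nm in 5 nm steps (61 nodes); spectra are
interpolated linearly and never extrapolated — they are smooth at this
resolution, so no smoothing is applied.

### Geometries

*Slab*: laterally infinite layer, normal (or oblique) incidence, diffuse R
and T tallied with per-photon sums of squares for standard errors.  The
semi-infinite case is the slab with effectively infinite thickness and
requires μa > 0 to terminate.

*Vessel scene*: a 30 mm cube of tissue with a horizontal cylinder (diameter
d, top at depth z below the surface; z measures to the cylinder **top**).
Illumination is two 160 × 160 mm rectangular sources at 45°, 270 mm away; at
that standoff the solid-angle variation over the 30 mm block is below ~1 %,
so the sources are modeled as two uniform parallel beams at ±45°, alternated
photon by photon.  Detection bins photons exiting the top surface within an
acceptance cone of half-angle 10° about the surface normal (pinhole-like)
into a 64 × 64 pixel grid.  Forward tracing with exit binning replaces
camera-to-scene reverse tracing; by optical reciprocity the two give the
same radiance estimates, and forward tracing needs only analytic
plane/cylinder intersections instead of a tetrahedral mesh.  Tissue and
vessel share a refractive index (the silicone-in-silicone phantom case), so
the internal boundary only switches interaction coefficients; a mismatched
internal boundary is not modeled.  Photons crossing the bottom or lateral
faces are terminated and tallied as lost — edge pixels are therefore
slightly dimmer than the interior, which is physical for a finite block,
and side loss is a few percent for the default properties.

### White referencing

Raw per-pixel tallies are detected-weight fractions.  They are referenced
to an ideal Lambertian unit-albedo standard in the same geometry, which
sends `sin²(θ_acc)/n_pixels` of the incident light into each pixel's
acceptance cone; dividing by that factor yields a reflectance `R_H`
comparable across wavelengths and of order the true
directional-hemispherical reflectance.  Contrast statistics
`C(λ) = (R_tissue − R_vein)/R_tissue` are unaffected by the factor.

## Integrating-sphere style inversion

The slab lookup table stores forward Monte Carlo (R, T) on log-spaced
(μa, μs′) grids (default 10 × 10 over the range of interest, 10⁵ photons per
node) with its full context.  Inversion runs bound-constrained Gauss–Newton
on cubic-spline interpolants of R and T over (log μa, log μs′), started at
the nearest grid node; cubic interpolation keeps the interpolation error of
the round trip well under the Monte Carlo noise at these grid densities.  A
measurement whose best forward residual exceeds the table's noise floor is
rejected with the nearest attainable (R, T) named.

The reflectance-only variant exploits scale invariance: a half-space has no
intrinsic length, so its diffuse reflectance depends on (μa, μs) only
through the albedo `a = μs/(μa+μs)` at fixed g and indices.  One
pure-scattering walk in units of 1/μt records the number of interactions K
before top exit; then `R(a) = (1−R_sp)·E[a^K]` *exactly, for every albedo at
once*.  Walks are censored at K = 6000 interactions, biasing R by less than
a^6000 (< 10⁻⁵ at the largest albedo the skin model reaches).  Given
measured R(λ) and a predefined μs′(λ), the albedo is recovered by a
bracketed root find on the strictly increasing R(a) and converted to
μa = μs(1−a)/a.  This makes the 61-wavelength inversion essentially free
after one ~30 s simulation and keeps the per-wavelength errors strongly
correlated (one shared curve), so the recovered spectrum is smooth.

## Pigment fitting

The mixture model is linear: `μa_fit(λ) = Σ cᵢ·bᵢ(λ)` with cᵢ ≥ 0, plus an
optional fixed base-material offset.  The objective is the unweighted sum
of squared residuals on the shared grid (per-wavelength weights optional).
The problem is convex, so the 30 random restarts (log-uniform initial
concentrations over [10⁻³, 10] × a target/basis scale) guard the
trust-region solver rather than the model; the restart with minimal χ² is
returned, together with per-band residuals (400–440 nm vs 440–700 nm) so a
short-blue mismatch — where real pigment libraries fail to follow the Soret
peak — is visible in diagnostics rather than hidden in one number.

## Colorimetry

Camera raw RGB is the rectangle-rule quadrature of
reflectance × SPD × channel sensitivity on the working grid.  The raw→XYZ
matrix is least-squares fitted so that the camera's raw responses to a
training set of smooth reflectances reproduce the CIE 1931 2° standard
observer XYZ of the same stimuli under the same illuminant; the observer
functions are evaluated from the Wyman–Sloan–Shirley multi-Gaussian fit.
CIELAB uses the standard piecewise transform; the default Lab/sRGB white
point is a perfect diffuser under the scene illuminant through the same
camera chain, so a spectrally flat surface always renders neutral
regardless of the illuminant (D65/sRGB white available for display
conversion).  ΔE defaults to CIE76 (Euclidean); CIEDE2000 is available via
`method="ciede2000"`.  Real DSLR channel sensitivities are not shipped; the
default camera is three Gaussian channels at 600/540/460 nm (σ 35/35/30 nm).

## Synthetic data: what it does and does not emulate

The generators produce the *structure* the analysis depends on, not any
measured spectrum:

- Skin: μa = baseline + Gaussian bands (defaults: a strong blue band at
  430 nm, σ 35 nm, 0.8 mm⁻¹ amplitude emulating the combined Soret/melanin
  rise of lightly pigmented forearm skin; weak 545/575 nm blood bands;
  0.015 mm⁻¹ red baseline) and μs′ = 3.0·(λ/500)^−1.6 mm⁻¹.  These defaults
  put the semi-infinite reflectance in the 0.15–0.65 range across
  400–700 nm — visually skin-like — and give blue light a penetration depth
  of ~0.3 mm versus ~3 mm for red, the regime in which a 1 mm-deep vessel
  is red-visible and blue-invisible.
- Blood: μa = scale·[S·ε_oxy + (1−S)·ε_deoxy] with frozen analytic shapes
  (Soret-like 430 nm band; oxy double band 542/576 nm with the W-shaped
  local minimum near 560 nm; deoxy single 555 nm band; deoxy red tail making
  ε_deoxy(660) ≫ ε_oxy(660)).  Venous S = 0.7, arterial S = 1.0.  The shapes
  are versioned constants — changing them changes every phenomenon the
  package reports — and a CSV loader accepts user-supplied tabulated
  extinction spectra for realism.
- Camera/illuminant: Gaussian RGB channels and a two-lobe white-LED SPD
  (450 nm pump + 560 nm phosphor).
- The seven-pigment basis spans the blood targets by construction, so
  representable-target fits reach χ² ≈ 0; real pigment libraries would not,
  particularly below 440 nm.

Consequently, passing phenomenon tests demonstrate that the *mechanism*
(wavelength-dependent penetration + vessel absorption + contrast-based
color) is reproduced under realistic spectral structure; they are not a
quantitative prediction for any particular skin, and layered skin with
subcutaneous fat — which deepens vessel visibility in vivo — is outside the
model.

## Hyperspectral emulation

Synthetic cubes are white-referenced renders with multiplicative Gaussian
noise (default σ = 1 %).  The vein ROI is the pixel strip within d/4 of the
cylinder midline; the tissue ROI is an equal strip 8 mm lateral.  Pixel
pitch for the default 64-pixel grid over the 30 mm block is ≈ 0.47 mm;
cross-section profiles are averaged over all rows (the scene is uniform
along the cylinder axis, so row averaging only reduces counting noise).

## Problem sizes and numerical choices

Default experiment renders use 13 wavelengths (450–690 nm in 20 nm steps),
a 64 × 64 pixel grid and 1–4 × 10⁵ photons per wavelength; slab oracles use
10⁵–10⁶ photons.  These sizes put ROI-mean contrast noise near 1–3 % in the
red (where the signal is ≳ 20 %) while keeping a full analysis in minutes
on one CPU; they are deliberately smaller than the ~10⁹-photon renders a
GPU implementation would use, which changes noise floors but none of the
reported orderings.  All stochastic operations take explicit seeds and are
bit-reproducible; per-wavelength and per-node streams are derived from the
base seed by a fixed affine map modulo 2³¹−1.  Degenerate inputs (μa=μs=0
slabs with mismatched boundaries, zero-width acceptance cones, vessels
protruding from the block, unphysical R+T>1 pairs) are rejected with named
errors rather than propagated.

## Known limitations

- Homogeneous tissue only: no layering, no subcutaneous fat, no melanin as
  a separate layer — vessel visibility at depth is underestimated relative
  to in vivo.
- Matched refractive index between tissue and vessel; no polarization,
  fluorescence, or Mie theory.
- The detector model is an acceptance cone about the surface normal, not a
  lens; absolute radiometric calibration is by the analytic Lambertian
  white factor rather than a simulated standard.
- Perception is represented only by reflectance-contrast metrics and
  CIELAB differences; no Retinex-style computational model is included.
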