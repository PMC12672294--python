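# Methods

## Scope and model

The package derives TG-43 source parameters for a point-like electronic
kV X-ray source from voxelized dose-rate grids (dose per unit tube
current, cGy·h⁻¹·µA⁻¹) and from a film plane offset 1 cm from the source
axis. All geometry uses continuous source-centred coordinates in cm:
tube axis = +z, polar angle θ from +z, transverse plane θ₀ = 90°, voxel
*centres* as sample positions, trilinear interpolation everywhere. The
point-source geometry function G_P(r) = 1/r² is the only one offered:
the device has no conventional active-source volume for a line-source
model, and with G_P the anisotropy function reduces to the plain dose
ratio F(r, θ) = D(r, θ)/D(r, θ₀).

The dose-rate constant is carried per unit tube current (the
electronic-brachytherapy convention). The classical division by
air-kerma strength is exposed as a clearly separated mode with explicit
unit harmonization (Gy·cm²·min⁻¹ → cGy·cm²·h⁻¹, factor 6000), because
for this device the published per-current value and the published S_K
are not linked by a derivable normalization; neither convention is
asserted as the other's arithmetic.

## Synthetic dose kernel

`generate_dose_grid` evaluates

D(r, θ, φ) = K · r⁻² · c_m · A_m(r) · f_polar(θ) · (1 + ε·sin(2φ + φ₀)) · (1 + η)

per voxel centre, with η ~ N(0, noise_sd) multiplicative and seeded
(per-medium sub-seeds, so water and ABS grids from one top-level seed
carry independent but reproducible noise). K is fixed so the transverse
water dose at 1 cm equals a configurable reference level. The voxel
containing the source is flagged unusable (NaN) — 1/r² is singular
there — and interpolation within one voxel of it is invalid by
construction. Grids are truncatable for tests but may not exceed the
30 × 30 × 20 cm³ phantom.

### Attenuation laws

Two families are provided. `ExpPolyAttenuation` is the analytic family
A(r) = exp(−Σ cₖ rᵏ) (k ≥ 1, so A(0) = 1): one coefficient is plain
exponential attenuation, a negative quadratic term emulates beam
hardening. It is used throughout the closed-form tests. The *default
water law*, however, is `TabulatedAttenuation`: a monotone-cubic (PCHIP)
interpolation of log A through knots derived from the reference water
g(r) table, pinned to A(0) = 1 and A(1 cm) = 0.5 (of the order of one
half-value layer of water at ~50 kVp effective energy; the absolute
scale of A is unobservable in normalized profiles) and extended linearly
in log A beyond the last knot. The reason is quantitative: the reference
water g(r) falls from 1.00 to 0.84 within the first millimetre beyond
1 cm yet still retains 0.18 at 5 cm, and a Chebyshev (linear-program)
feasibility analysis shows no two-coefficient exponent — nor any
three-coefficient polynomial exponent — can stay within ±0.05 of all 22
tabulated values (best attainable max residuals 0.081 and 0.062). The
tabulated law reproduces the reference profile to interpolation accuracy
(extracted water g(r) within ~0.013 everywhere) while remaining a valid
attenuation law.

The ABS law is tied to water in closed form: with
CF(r) = c·exp(−Δμ·r) solving CF(1) = 1.23 and CF(5) = 0.85
(c = 1.349, Δμ = 0.0924 cm⁻¹), the default sets
A_ABS(r) = A_water(r)·exp(+Δμ·r) and c_ABS = 1/c — ABS attenuates less,
consistent with its lower effective atomic number. This single choice
reproduces both published CF endpoints exactly and lands the implied ABS
g(r) within ~0.03 of the published ABS column at every radius, and the
g-ratio column endpoint (0.69 at 5 cm) exactly.

### Angular structure

f_polar(θ) = 1 + a·cosθ + b·cos²θ, normalized at θ₀ by construction.
The defaults solve a constrained least-squares fit to the published
per-angle means: forward enhancement f(0°) = 1.16 held exactly and f
constrained monotone decreasing over [0°, 180°] (a transmission-target
tube emits forward-peaked and is shielded backward; the unconstrained
fit would produce a spurious backward enhancement of 1.50 from data that
only span 0–90°). The constrained optimum sits on the boundary b = a/2,
giving a = 2·0.16/3, b = 0.16/3 and f(180°) = 0.947. Azimuthal ripple:
ε = 0.03 with phase 150° (published ripple ≤ 6%, maximum at 150°).
Scoring noise default 0.007 relative SD — a free parameter of the
generator, set so per-point extraction scatter is visible but
subdominant; it is not a transport-code statistic.

## Extraction choices

- Depth-dose: trilinear samples on the transverse circle, averaged over
  360 azimuths. Polar samples: 2°-wide θ bands (5 sub-angles) × 120
  azimuths, averaged; bands partly outside the grid are marked invalid,
  never averaged one-sidedly.
- The reference dose at (r₀, θ₀) is interpolated, not nearest-voxel, to
  avoid a half-voxel bias; normalizations g(r₀) = 1, F(r, θ₀) = 1 and
  azimuthal ratio(0°) = 1 are then set exactly.
- Curve-to-curve interpolation (conversion derivation, reference-dose
  lookup) is PCHIP in log-dose vs log-radius: exact for power laws and
  well conditioned for exponential-attenuation curves, where
  interpolation in dose space loses percent-level accuracy near the
  source.
- Table statistics use the sample SD (n−1); argmax locations break ties
  toward the smaller radius (then angle).
- Voxel-bin ring averages (the brute-force cross-check and the
  uncertainty-region estimator) are biased low by a few percent at
  r ≈ 1 cm against point estimators, because a one-voxel-wide discrete
  annulus holds more voxels at its outer edge; the two agree within 0.5%
  from 2 cm outward.

## Film model

netOD = log₁₀[(PV_unexposed − PV_background)/(PV_exposed − PV_background)],
the standard radiochromic convention (the red channel by default), and
dose as a least-squares cubic in netOD, refused if non-monotone inside
the calibrated range; out-of-range pixels are clamped and flagged, never
silently extrapolated. The film plane is parallel to the tube axis at
perpendicular distance d (default 1 cm, 75 dpi pitch); a pixel at
in-plane (u, v) maps to r = √(u² + v² + d²), θ = arccos(u/r). Validity
requires θ ≥ 20° (film directional dependence) and r·sinθ ≥ d — the
plane's geometric reach, which also governs which (r, θ) lattice cells
the film path may populate (a cell below the reach line would only
collect one-sided edge pixels and is masked). Film energy dependence is
not corrected pixelwise; it enters only as the 11% Type B budget
component, and films are assumed scan-stabilized.

## Conversion function

CF(r) = D_water(r)/D_ABS(r), derived pointwise on the shared radii
(monotone-cubic interpolation in between; optional low-order polynomial
fit, since no particular functional form is privileged). Applied
multiplicatively; converting a normalized g-table automatically
renormalizes at r₀ — conversion and normalization commute only up to
that constant, which is asserted numerically in the tests. The relative
RMSE of converting the ABS derivation curve back to water is stored on
the object and is the conversion's uncertainty entry.

## Uncertainty budget

Percent throughout. Components are Type A or B, combined in quadrature
per type; total = √(A² + B²), always — the packaged reference budget's
printed total (12.06%) exceeds the strict quadrature of its own
components (12.02%) and is reported as a discrepancy, not reproduced.
Grid estimators: statistical = dose-weighted mean of per-voxel relative
errors; geometric = 100·(max − min)/(2·mean·√3) over the voxels within
±0.5 mm of the transverse plane and of the stated radius (uniform-
distribution model of voxel-alignment sensitivity; larger near the
source, where the per-ring gradient is steeper).

## What the generator does and does not emulate

It reproduces: inverse-square falloff with medium-dependent hardened
attenuation, the distance-dependent water/ABS contrast (CF > 1 near,
< 1 far, strictly decreasing), forward-peaked polar anisotropy,
small azimuthal ripple, and seeded multiplicative scoring noise.  It
does **not** transport photons: there is no spectral scoring, no
scatter buildup, no tube-body geometry (the 47 mm tube is a virtual
point), and its anisotropy is radius-independent, whereas the real
source's forward enhancement grows with distance. Passing tests
therefore validate the *extraction and conversion machinery* and the
internal consistency of the published tables — not transport physics.
Within the kernel family the extractors are exactly separable (g blind
to the polar profile, F blind to attenuation), which the suite asserts.

## Default problem sizes

Default grids are 105 × 105 × 89 voxels of 1 mm (±5.2 cm transverse,
±4.4 cm axial): the smallest lattice that covers the 5 cm radial and
4.2 cm × 20° anisotropy tabulation ranges with interpolation margin,
chosen so a full two-medium pipeline runs in seconds while leaving
grid-convergence headroom (halving the voxel changes extracted
depth-dose by < 1%). Full-phantom 300 × 300 × 200 grids are supported.

## Known limitations

- The printed reference tables contain internal inconsistencies
  (rounded CF vs dose-rate-constant pair, printed budget total, ragged
  anisotropy rows); these are transcribed verbatim, documented in
  `fixtures/FIXTURE_NOTES.md`, and surfaced by `regression_report`
  rather than smoothed over.
- The classical Λ mode divides by S_K after unit harmonization but no
  published cross-check exists for this device; it is provided as a
  convention, not a validated value.
- Film-path anisotropy inherits the plane's reach mask: θ < 20° and
  r·sinθ < d cells are never populated, exactly as in the physical
  measurement geometry.
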