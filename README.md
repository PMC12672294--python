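# mxtdosim

TG-43 dosimetric characterization of a carbon-nanotube **miniature X-ray
tube (mXT)** — an electronic brachytherapy source that replaces
radionuclides such as ¹⁹²Ir with an electrically controlled kV photon
emitter. The package is written for medical physicists and source
developers who need the standard brachytherapy source parameters of such
a device, derived reproducibly from voxelized dose calculations and
radiochromic-film measurements performed in a machined ABS plastic
phantom rather than in water.

## The model

The AAPM TG-43 formalism factorizes the dose rate around a source as

```
D(r, θ) = Λ · G(r, θ)/G(r₀, θ₀) · g(r) · F(r, θ)
```

with the reference point at r₀ = 1 cm, θ₀ = 90°. Because the mXT has no
conventional active volume, the point-source geometry function
G_P(r) = 1/r² is used throughout, so

- **dose-rate constant** Λ — the reference-point dose rate; for an
  electronic source it is conventionally expressed *per unit tube
  current* (cGy·h⁻¹·µA⁻¹) rather than per air-kerma strength (the
  classical division by S_K is available as a separate mode);
- **radial dose function** g(r) = [D(r, θ₀)/D(r₀, θ₀)]·r²/r₀² — the
  transverse falloff with the geometric factor removed, g(r₀) = 1;
- **anisotropy function** F(r, θ) = D(r, θ)/D(r, θ₀) — the polar
  variation, F(r, θ₀) = 1;
- **azimuthal ratios** — dose around the tube axis normalized at 0°.

Measurements are made in an ABS phantom (density 1.04 g/cm³) and
converted to water with a distance-dependent **material conversion
function** CF(r) = D_water(r)/D_ABS(r), derived as the ratio of paired
transverse depth-dose curves; its relative RMSE doubles as the
conversion's entry in the TG-138-style uncertainty budget (Type A/B
components combined in quadrature).

A seeded **synthetic dose-kernel generator** stands in for Monte-Carlo
transport and film scans:

```
D(r, θ, φ) = K · r⁻² · c_m · A_m(r) · f_polar(θ) · (1 + ε·h(φ)) · (1 + noise)
```

with per-medium attenuation laws A_m, a forward-peaked polar profile,
≤6% azimuthal ripple and multiplicative Gaussian scoring noise. Its
calibrated defaults reproduce the published behaviour of the
characterized mXT (see `docs/methods.md`), so every extraction stage is
testable end to end without external data. Packaged, checksummed CSV
fixtures transcribe the published reference tables for regression
checks.

## Worked example

Derive the conversion function and convert ABS-measured parameters to
water (`examples/02_material_conversion.py`):

```
conversion function CF(r) = D_water / D_ABS:
  CF(1 cm) = 1.230
  CF(2 cm) = 1.122
  CF(3 cm) = 1.023
  CF(4 cm) = 0.932
  CF(5 cm) = 0.850
conversion RMSE (stored as its uncertainty): 6.96e-17
dose-rate constant: 1092.07 (ABS) -> 1343.48 (water) cGy/h/uA
ABS g(r) converted to water (renormalized at 1 cm):
  g_water(2 cm) = 0.565
  g_water(3 cm) = 0.379
  g_water(4 cm) = 0.250
  g_water(5 cm) = 0.180
```

CF falls from 1.23 at 1 cm to 0.85 at 5 cm: near the source water
absorbs the soft kV spectrum more strongly than ABS, while far out the
harder remaining spectrum reverses the ratio. The converted dose-rate
constant (~1344 cGy·h⁻¹·µA⁻¹) and water g(r) values track the reference
characterization of this source; the pointwise conversion is exact on
its derivation radii, hence the ~1e-16 RMSE (a smooth polynomial fit
stores a non-trivial RMSE instead).

The other examples cover simulation + TG-43 extraction (`01`), the film
netOD workflow and its geometric measurability mask (`03`), the
uncertainty budget (`04`), and the packaged reference tables with their
regression self-test (`05`). A thin CLI mirrors the pipeline stages:
`mxtdosim simulate | extract | film-calibrate | film-convert | derive-cf
| apply-cf | budget | report | regression`.

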