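# Reference-table fixtures

These CSVs transcribe the published dosimetric characterization tables for
the carbon-nanotube miniature X-ray tube (mXT) source that this package
models: radial dose functions in ABS and water by Monte Carlo and film,
anisotropy-function blocks, azimuthal ratios, and the measurement
uncertainty budget. Values are stored exactly as printed, including the
source's internal inconsistencies, which are listed here so that no code or
test silently "fixes" them:

- **Λ vs CF rounding.** The reference dose-rate constant in ABS is
  1104.28 cGy·h⁻¹·μA⁻¹ and in water 1344.14 cGy·h⁻¹·μA⁻¹, implying a
  conversion factor of 1.21719 at 1 cm, while the conversion factor is
  printed (rounded) as 1.23. The package derives its own conversion
  function; neither printed rounding is asserted against the other.
- **Abstract-style g(r) values** (0.49/0.33/0.22/0.15 at 2–5 cm) match no
  column of the radial-dose table and are not carried as fixtures.
- **Uncertainty total.** The printed budget total is 12.06% while the
  strict quadrature of the printed components is
  √(0.04² + 0.50² + 11.00² + 4.72² + 0.98²) = 12.02%. The package computes
  the strict quadrature and reports the discrepancy.
- **ABS difference-column mean.** The printed column mean is 0.07
  (recomputation from the printed columns gives 0.067); the accompanying
  text rounds the same quantity to 0.06. The regression report asserts
  0.07.
- **Ragged anisotropy rows.** Short rows of the film-measured and
  film/Monte-Carlo-ratio anisotropy blocks are aligned to the largest
  radii, consistent with the geometric reach rule r·sin θ ≥ 1 cm of a film
  plane offset 1 cm from the source axis. This alignment reproduces the
  printed row means exactly and places the printed ratio minimum 0.84 at
  (r = 3.6 cm, θ = 20°) as stated in the source text. The θ = 20° rows then
  begin at r = 2.8 cm, which marginally violates the reach rule
  (2.8·sin 20° = 0.958 cm); those cells are flagged `uncertain = True` and
  no statistic asserted by the package depends on them individually.

Fixture files are immutable and SHA-256 checksummed at load
(`mxtdosim.fixtures.load_fixtures`).
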