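"""Combine the measurement uncertainty budget and the grid-based estimators.

Components are percent, typed A (statistical) or B (systematic), combined
in quadrature per type; the total is the quadrature of the two sums.
"""

from mxtdosim import (
    SourceSpec,
    combine_budget,
    default_components,
    default_kernel_params,
    generate_dose_grid,
    mc_geometric_uncertainty,
    mc_statistical_uncertainty,
    transverse_ring_doses,
)

budget = combine_budget(default_components())
print("film-measurement budget:")
for c in budget.components:
    print(f"  [{c.type}] {c.name:<35s} {c.value:5.2f}%")
print(f"  Type A quadrature: {budget.quadrature_sum_a:.2f}%")
print(f"  Type B quadrature: {budget.quadrature_sum_b:.2f}%")
print(f"  total (strict quadrature): {budget.total:.2f}%")

params = default_kernel_params(seed=4)
grid = generate_dose_grid(SourceSpec(), params, "water")
for r in (1.0, 3.0):
    ring = transverse_ring_doses(grid, r)
    geo = mc_geometric_uncertainty(ring)
    print(f"grid geometric uncertainty at {r:.0f} cm "
          f"({ring.size} ring voxels): {geo:.2f}%")
rel_err = [100.0 * params.noise_sd] * 4  # constant per-voxel noise model
print("dose-weighted statistical uncertainty:",
      f"{mc_statistical_uncertainty(rel_err, [1.0, 2.0, 3.0, 4.0]):.2f}%")
print("note: the near-field geometric term dominates because the dose "
      "gradient across a 1 mm ring is steepest close to the source")
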