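"""Non-rival informational and access benefits: line-of-sight delivery of
scenic value and least-cost access to open space.  Non-rival contact
multiplies value by the number of users, so delivered totals can exceed
the in-situ supply."""

import numpy as np

from spanflow import (
    BenefitSpec,
    GridSpec,
    RasterLayer,
    RouterSpec,
    SpanProblem,
    run_span,
    viewshed,
)

spec = GridSpec(7, 7, 30.0)
dem_vals = np.zeros((7, 7))
dem_vals[3, 3] = 25.0  # a hill in the middle
dem = RasterLayer(spec, dem_vals)

vis = viewshed(dem, observer=(3, 3), max_distance=200.0)
print(f"viewshed from the hilltop: {int(vis.values.sum())} of 49 cells visible")

# one scenic source (relative quality 0-100) seen by several households
source = RasterLayer(spec, np.zeros((7, 7)))
source.values[3, 3] = 80.0
sink = RasterLayer(spec, np.zeros((7, 7)))
use = RasterLayer(spec, np.zeros((7, 7)))
for cell in ((1, 1), (1, 5), (5, 1), (5, 5)):
    use.values[cell] = 1.0

problem = SpanProblem(
    source, sink, use,
    BenefitSpec("provisioning", "non_rival", "scenic quality", "rank"),
    RouterSpec("line_of_sight", dem=dem, max_distance=300.0),
)
outputs = run_span(problem)
print(f"scenic value {source.values[3, 3]:.0f} seen by "
      f"{int(use.total())} users -> total delivered "
      f"{outputs.actual_use.total():.0f} "
      "(non-rival use multiplies, it does not deplete)")

# least-cost access: the same users walking to an amenity over a cost surface
cost = RasterLayer(spec, np.ones((7, 7)))
problem2 = SpanProblem(
    source, sink, use,
    BenefitSpec("provisioning", "non_rival", "open-space quality", "rank"),
    RouterSpec("access_cost", cost=cost, max_cost=10.0),
)
outputs2 = run_span(problem2)
print(f"access routing delivers {outputs2.actual_use.total():.0f} "
      "to the same users via least-cost paths")
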