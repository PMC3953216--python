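"""Build a synthetic terrain, derive slope, and round-trip it through the
ESRI ASCII grid format."""

import tempfile
from pathlib import Path

import numpy as np

from spanflow import LandscapeSpec, make_dem, read_ascii_grid, slope_percent, write_ascii_grid

spec = LandscapeSpec(seed=42, n_rows=20, n_cols=20, relief=40.0, tilt=2.0)
dem = make_dem(spec)
slope = slope_percent(dem)

print(f"DEM: {dem.spec.n_rows}x{dem.spec.n_cols} cells of "
      f"{dem.spec.cell_size:.0f} m, elevation {dem.values.min():.1f}-"
      f"{dem.values.max():.1f} m")
print(f"slope: mean {slope.mean():.1f}%, max {slope.values.max():.1f}% "
      f"(steepest 8-neighbour descent)")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "dem.asc"
    write_ascii_grid(dem, path)
    back = read_ascii_grid(path)
    print("round-trip bit-identical:", bool(np.array_equal(back.values, dem.values)))
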