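"""Synthetic-landscape fixtures: correlated terrain, clumped land cover,
source/sink/use intensity surfaces and Bayesian-network training cases.

Every generator is a pure function of its spec and seed, so all tests and
examples run from nothing but code.  Terrain is smoothed white noise
(iterated neighbourhood averaging — deterministic across platforms) with a
controllable relief amplitude and an optional monotone tilt that gives
downslope routing a guaranteed outlet at the east edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .bayes import BayesNet
from .errors import DomainError
from .raster import GridSpec, RasterLayer
from .span import BenefitSpec, RouterSpec, SpanProblem

__all__ = ["LandscapeSpec", "make_dem", "make_land_cover", "make_span_case",
           "make_bn_cases"]


@dataclass(frozen=True)
class LandscapeSpec:
    """Statistical controls of the synthetic landscape.

    ``relief`` is the standard deviation (map length units) of the DEM
    field; ``smoothness`` is the number of 3x3 averaging passes;
    ``tilt`` is the eastward drop per column, giving downslope routing an
    outlet.  Class intensities are mean per-cell source/sink/use amounts
    per land-cover class.  The 30 m cell and ~50 m relief defaults match a
    Landsat-scale hilly watershed, the setting the flow models target.
    """

    seed: int
    n_rows: int = 24
    n_cols: int = 24
    cell_size: float = 30.0
    relief: float = 50.0
    smoothness: int = 3
    tilt: float = 2.0
    n_classes: int = 4
    patch_size: float = 16.0
    source_intensity: tuple[float, ...] = (10.0, 4.0, 1.0, 0.0)
    sink_intensity: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)
    use_intensity: tuple[float, ...] = (0.0, 0.0, 3.0, 8.0)
    bn_case_count: int = 1000

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_classes < 1:
            raise DomainError("counts must be >= 1")
        if self.relief < 0 or self.patch_size <= 0:
            raise DomainError("relief must be >= 0 and patch_size > 0")
        for name in ("source_intensity", "sink_intensity", "use_intensity"):
            vals = getattr(self, name)
            if len(vals) < self.n_classes:
                raise DomainError(f"{name} needs one entry per class")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size)


def make_dem(spec: LandscapeSpec) -> RasterLayer:
    """Seeded smoothed random terrain rescaled to the requested relief.

    ``relief = 0`` gives a perfectly flat (or purely tilted) surface; the
    same seed always gives the same field.
    """
    rng = np.random.default_rng(spec.seed)
    field_ = rng.standard_normal((spec.n_rows, spec.n_cols))
    for _ in range(spec.smoothness):
        field_ = uniform_filter(field_, size=3, mode="nearest")
    sd = field_.std()
    if spec.relief > 0 and sd > 0:
        field_ = field_ * (spec.relief / sd)
    else:
        field_ = np.zeros_like(field_)
    cols = np.arange(spec.n_cols)
    field_ = field_ + spec.tilt * (spec.n_cols - 1 - cols)[None, :]
    field_ -= field_.min()
    return RasterLayer(spec.grid, field_, semantics="elevation", units="m")


def make_land_cover(spec: LandscapeSpec) -> RasterLayer:
    """Clumped class map by seeded region growing.

    The number of growth seeds is ``n_cells / patch_size`` so the expected
    patch size (cells) matches the requested value; growth order is
    randomised from the seed, giving irregular but reproducible patches.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_cells = spec.n_rows * spec.n_cols
    n_seeds = max(int(round(n_cells / spec.patch_size)), spec.n_classes)
    cover = np.full((spec.n_rows, spec.n_cols), -1, dtype=int)
    flat = rng.choice(n_cells, size=n_seeds, replace=False)
    frontier: list[tuple[float, int, int]] = []
    for k, f in enumerate(flat):
        i, j = divmod(int(f), spec.n_cols)
        cls = k % spec.n_classes
        cover[i, j] = cls
        frontier.append((rng.random(), i, j))
    import heapq
    heapq.heapify(frontier)
    while frontier:
        _, i, j = heapq.heappop(frontier)
        cls = cover[i, j]
        for di, dj in ((0, 1), (1, 0), (0, -1), (-1, 0)):
            ni, nj = i + di, j + dj
            if 0 <= ni < spec.n_rows and 0 <= nj < spec.n_cols and cover[ni, nj] < 0:
                cover[ni, nj] = cls
                heapq.heappush(frontier, (rng.random(), ni, nj))
    return RasterLayer(spec.grid, cover.astype(float),
                       semantics="land_cover", units="class")


def make_span_case(spec: LandscapeSpec, benefit: BenefitSpec,
                   router_mode: str = "d8_downslope",
                   ) -> tuple[SpanProblem, dict[str, float]]:
    """A complete flow problem over a clumped synthetic landscape.

    Source, sink and use layers take each class's intensity everywhere the
    class occurs.  Returns the problem plus closed-form expected totals
    (class intensity times class cell count) for assertion.
    """
    dem = make_dem(spec)
    cover = make_land_cover(spec)
    cls = cover.values.astype(int)

    def intensity_layer(intensities, semantics):
        lut = np.asarray(intensities[:spec.n_classes], dtype=float)
        return RasterLayer(spec.grid, lut[cls], semantics, benefit.units)

    source = intensity_layer(spec.source_intensity, "source")
    sink = intensity_layer(spec.sink_intensity, "sink")
    use = intensity_layer(spec.use_intensity, "use")

    counts = np.bincount(cls.ravel(), minlength=spec.n_classes)
    expected = {
        "sum_source": float(np.dot(counts, spec.source_intensity[:spec.n_classes])),
        "sum_sink": float(np.dot(counts, spec.sink_intensity[:spec.n_classes])),
        "sum_use": float(np.dot(counts, spec.use_intensity[:spec.n_classes])),
    }
    if router_mode == "d8_downslope":
        router = RouterSpec("d8_downslope", dem=dem)
    elif router_mode == "line_of_sight":
        router = RouterSpec("line_of_sight", dem=dem,
                            max_distance=6 * spec.cell_size)
    elif router_mode == "access_cost":
        cost = RasterLayer(spec.grid, 1.0 + cover.values, "traversal_cost", "cost")
        router = RouterSpec("access_cost", cost=cost,
                            max_cost=float(spec.n_cols))
    elif router_mode == "global_mix":
        router = RouterSpec("global_mix")
    else:
        raise DomainError(f"unknown router mode {router_mode!r}")
    return SpanProblem(source, sink, use, benefit, router), expected


def make_bn_cases(net: BayesNet, n: int, seed: int) -> pd.DataFrame:
    """``n`` ancestral samples from the network, one column per node."""
    if n < 0:
        raise DomainError("n must be >= 0")
    rng = np.random.default_rng(seed)
    order = net.topological_order
    data = {name: np.empty(n, dtype=int) for name in order}
    for name in order:
        ps = net.parents[name]
        cpt = net.cpts[name]
        if ps:
            idx = tuple(data[p] for p in ps)
            rows = cpt[idx]  # (n, card)
        else:
            rows = np.broadcast_to(cpt, (n, cpt.shape[-1]))
        cum = np.cumsum(rows, axis=1)
        u = rng.random((n, 1))
        data[name] = np.minimum((u > cum).sum(axis=1), cpt.shape[-1] - 1)
    return pd.DataFrame({
        name: pd.Categorical.from_codes(data[name], list(net.nodes[name].states))
        .astype(str)
        for name in net.nodes
    })
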