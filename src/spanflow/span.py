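"""Service-flow propagation: route a service carrier from source cells
through sinks to users and assemble the full output-map taxonomy.

A flow problem couples three aligned rasters — carrier production
(source), absorption capacity (sink) and beneficiary demand (use) — with
benefit semantics (provisioning vs preventive, rival vs non-rival) and a
transport mode.  Four transport modes cover the common carrier classes:

* ``d8_downslope``  — hydrologic carriers (water, sediment, nutrients);
* ``line_of_sight`` — informational carriers (scenic quality);
* ``access_cost``   — human-powered access to amenities (open space);
* ``global_mix``    — well-mixed carriers (atmospheric CO2).

Every simulation runs twice: a *possible* pass with all sinks disabled and
an *actual* pass with sinks active.  Subtracting the passes yields the
blocked maps; subtracting the possible pass from the in-situ (theoretical)
layers yields the inaccessible maps.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InternalConsistencyError, UndefinedRatioError
from .raster import NEIGHBOR_OFFSETS, GridSpec, RasterLayer

__all__ = [
    "BenefitSpec",
    "RouterSpec",
    "SpanProblem",
    "SpanOutputs",
    "SweepResult",
    "route_d8",
    "run_span",
    "derive_output_maps",
    "viewshed",
    "cost_distance",
    "sustainability_sweep",
    "potential_need_ratio",
]

ROUTER_MODES = ("d8_downslope", "line_of_sight", "access_cost", "global_mix")


@dataclass(frozen=True)
class BenefitSpec:
    """Semantics of the benefit a flow problem delivers.

    For preventive benefits the same carrier mechanics apply with reversed
    value interpretation: delivered use is damage received, and the flow
    blocked by sinks is the damage prevented (sinks beneficial).
    """

    benefit_type: str  # "provisioning" | "preventive"
    rivalness: str     # "rival" | "non_rival"
    carrier: str
    units: str

    def __post_init__(self) -> None:
        if self.benefit_type not in ("provisioning", "preventive"):
            raise DomainError(f"unknown benefit type {self.benefit_type!r}")
        if self.rivalness not in ("rival", "non_rival"):
            raise DomainError(f"unknown rivalness {self.rivalness!r}")
        if not self.carrier or not self.units:
            raise DomainError("carrier and units must be set")


@dataclass
class RouterSpec:
    """Transport mode plus its mode-specific parameters.

    ``d8_downslope``: dem.  ``line_of_sight``: dem, max_distance.
    ``access_cost``: cost (per-cell traversal cost), max_cost.
    ``global_mix``: no parameters.
    """

    mode: str
    dem: RasterLayer | None = None
    max_distance: float | None = None
    cost: RasterLayer | None = None
    max_cost: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ROUTER_MODES:
            raise DomainError(f"unknown router mode {self.mode!r}")
        if self.mode == "d8_downslope" and self.dem is None:
            raise DomainError("d8_downslope requires a DEM")
        if self.mode == "line_of_sight" and (self.dem is None or self.max_distance is None):
            raise DomainError("line_of_sight requires a DEM and max_distance")
        if self.mode == "access_cost" and (self.cost is None or self.max_cost is None):
            raise DomainError("access_cost requires a cost layer and max_cost")


@dataclass
class SpanProblem:
    """Inputs of one flow simulation; all layers share one grid geometry."""

    source: RasterLayer
    sink: RasterLayer
    use: RasterLayer
    benefit: BenefitSpec
    router: RouterSpec

    def __post_init__(self) -> None:
        specs = {self._geom(l.spec) for l in (self.source, self.sink, self.use)}
        if len(specs) != 1:
            raise DomainError("source, sink and use layers must share one GridSpec")
        for name, layer in (("source", self.source), ("sink", self.sink),
                            ("use", self.use)):
            if np.any(layer.values[layer.valid_mask] < 0):
                raise DomainError(f"{name} layer has negative values")
        if self.router.mode == "line_of_sight" and self.benefit.rivalness != "non_rival":
            raise DomainError("line_of_sight routing supports non-rival benefits only")
        for aux in (self.router.dem, self.router.cost):
            if aux is not None and self._geom(aux.spec) != self._geom(self.source.spec):
                raise DomainError("router layers must share the problem GridSpec")

    @staticmethod
    def _geom(s: GridSpec):
        return (s.n_rows, s.n_cols, s.cell_size, s.x_ll, s.y_ll)

    @property
    def spec(self) -> GridSpec:
        return self.source.spec

    def with_use_scaled(self, factor: float) -> "SpanProblem":
        scaled = self.use.with_values(self.use.filled(0.0) * factor)
        return SpanProblem(self.source, self.sink, scaled, self.benefit, self.router)


@dataclass
class _PassResult:
    """Raw per-pass maps before taxonomy assembly."""

    flow: np.ndarray            # carrier traversing each cell
    use_received: np.ndarray    # delivered benefit (or contact) per use cell
    sink_absorbed: np.ndarray   # carrier absorbed per sink cell
    source_delivered: np.ndarray  # delivered benefit attributed to origins
    exported: float = 0.0       # carrier leaving the grid at terminals


@dataclass
class SpanOutputs:
    """The full output-map taxonomy of one flow simulation."""

    theoretical_source: RasterLayer
    theoretical_sink: RasterLayer
    theoretical_use: RasterLayer
    possible_source: RasterLayer
    possible_use: RasterLayer
    possible_flow: RasterLayer
    actual_source: RasterLayer
    actual_sink: RasterLayer
    actual_use: RasterLayer
    actual_flow: RasterLayer
    inaccessible_source: RasterLayer
    inaccessible_sink: RasterLayer
    inaccessible_use: RasterLayer
    blocked_source: RasterLayer
    blocked_use: RasterLayer
    blocked_flow: RasterLayer
    run_log: dict = field(default_factory=dict)

    MAP_NAMES = (
        "theoretical_source", "theoretical_sink", "theoretical_use",
        "possible_source", "possible_use", "possible_flow",
        "actual_source", "actual_sink", "actual_use", "actual_flow",
        "inaccessible_source", "inaccessible_sink", "inaccessible_use",
        "blocked_source", "blocked_use", "blocked_flow",
    )

    def as_dict(self) -> dict[str, RasterLayer]:
        return {name: getattr(self, name) for name in self.MAP_NAMES}

    def totals(self) -> dict[str, float]:
        return {name: layer.total() for name, layer in self.as_dict().items()}


# ---------------------------------------------------------------------------
# D8 routing
# ---------------------------------------------------------------------------

def route_d8(dem: RasterLayer) -> np.ndarray:
    """Steepest-descent single-flow directions.

    Returns an int array: 0-7 clockwise from East pointing to the steepest
    strictly lower neighbour (drop/distance, diagonals weighted by sqrt 2),
    or -1 for terminal cells (pits, flats, nodata).  The resulting graph is
    acyclic because elevation strictly decreases along every edge.
    """
    z = dem.values
    spec = dem.spec
    nod = dem.nodata_mask
    best_grad = np.zeros(spec.shape)
    direction = np.full(spec.shape, -1, dtype=np.int8)
    for code, (di, dj) in enumerate(NEIGHBOR_OFFSETS):
        dist = spec.cell_size * (math.sqrt(2.0) if di and dj else 1.0)
        zn = np.full(spec.shape, np.inf)
        i0, i1 = max(di, 0), spec.n_rows + min(di, 0)
        j0, j1 = max(dj, 0), spec.n_cols + min(dj, 0)
        block = z[i0:i1, j0:j1].copy()
        block[nod[i0:i1, j0:j1]] = np.inf
        zn[i0 - di:i1 - di, j0 - dj:j1 - dj] = block
        with np.errstate(invalid="ignore"):
            grad = (z - zn) / dist
        better = grad > best_grad
        best_grad = np.where(better, grad, best_grad)
        direction[better] = code
    direction[nod] = -1
    return direction


def _successor_index(direction: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Flat index of each cell's downstream neighbour (-1 for terminals)."""
    succ = np.full(spec.shape, -1, dtype=np.int64)
    ii, jj = np.meshgrid(np.arange(spec.n_rows), np.arange(spec.n_cols), indexing="ij")
    for code, (di, dj) in enumerate(NEIGHBOR_OFFSETS):
        sel = direction == code
        succ[sel] = (ii[sel] + di) * spec.n_cols + (jj[sel] + dj)
    return succ.ravel()


def _run_d8_pass(problem: SpanProblem, sinks_active: bool) -> _PassResult:
    """One sweep in topological (upstream-to-downstream) order.

    Per cell, in order: the sink absorbs, rival use withdraws (non-rival
    use registers contact without depletion), the remainder passes
    downstream.  Origin attribution is carried as a sparse composition per
    cell and scaled proportionally at every absorption/withdrawal.
    """
    spec = problem.spec
    dem = problem.router.dem
    direction = route_d8(dem)
    succ = _successor_index(direction, spec)
    n = spec.n_rows * spec.n_cols
    source = problem.source.filled(0.0).ravel()
    cap = problem.sink.filled(0.0).ravel() if sinks_active else np.zeros(n)
    demand = problem.use.filled(0.0).ravel()
    rival = problem.benefit.rivalness == "rival"
    # upstream cells are strictly higher, so descending elevation is a
    # topological order of the flow graph
    elev = dem.filled(-np.inf).ravel()
    order = np.argsort(-elev, kind="stable")

    flow = np.zeros(n)
    use_received = np.zeros(n)
    sink_absorbed = np.zeros(n)
    source_delivered = np.zeros(n)
    exported = 0.0
    inbox: dict[int, dict[int, float]] = {}

    for c in order:
        c = int(c)
        comp = inbox.pop(c, {})
        if source[c] > 0:
            comp[c] = comp.get(c, 0.0) + source[c]
        through = sum(comp.values())
        flow[c] = through
        if through <= 0.0:
            continue
        remainder = through
        absorb = min(remainder, cap[c])
        if absorb > 0:
            factor = (remainder - absorb) / remainder
            for k in comp:
                comp[k] *= factor
            sink_absorbed[c] = absorb
            remainder -= absorb
        if demand[c] > 0 and remainder > 0:
            contact = min(remainder, demand[c])
            use_received[c] = contact
            share = contact / remainder
            for k, amt in comp.items():
                source_delivered[k] += amt * share
            if rival:
                keep = 1.0 - share
                for k in comp:
                    comp[k] *= keep
                remainder -= contact
        if remainder <= 0.0:
            continue
        s = succ[c]
        if s < 0:
            exported += remainder
        else:
            box = inbox.setdefault(int(s), {})
            for k, amt in comp.items():
                if amt > 0.0:
                    box[k] = box.get(k, 0.0) + amt
    return _PassResult(flow.reshape(spec.shape), use_received.reshape(spec.shape),
                       sink_absorbed.reshape(spec.shape),
                       source_delivered.reshape(spec.shape), exported)


# ---------------------------------------------------------------------------
# Line of sight
# ---------------------------------------------------------------------------

def _profile_crossings(a: tuple[int, int], b: tuple[int, int]):
    """Parameters t in (0, 1) where the segment from cell center ``a`` to
    cell center ``b`` crosses a row or column of cell centers (in row/col
    units; x = col, y = row)."""
    (i0, j0), (i1, j1) = a, b
    ts: list[float] = []
    if j1 != j0:
        step = 1 if j1 > j0 else -1
        for m in range(j0 + step, j1, step):
            ts.append((m - j0) / (j1 - j0))
    if i1 != i0:
        step = 1 if i1 > i0 else -1
        for m in range(i0 + step, i1, step):
            ts.append((m - i0) / (i1 - i0))
    return sorted(set(ts))


def _profile_elevation(z: np.ndarray, valid: np.ndarray,
                       a: tuple[int, int], b: tuple[int, int], t: float) -> float | None:
    """Terrain elevation at parameter t along the ray, linearly interpolated
    between the two adjacent cell centers on the crossed center-line.
    Returns None when a needed center is nodata (transparent)."""
    (i0, j0), (i1, j1) = a, b
    x = j0 + t * (j1 - j0)
    y = i0 + t * (i1 - i0)
    eps = 1e-9
    if abs(x - round(x)) < eps:  # on a column of centers: interpolate in y
        j = int(round(x))
        ylo = math.floor(y)
        yhi = min(ylo + 1, z.shape[0] - 1)
        f = y - ylo
    else:  # on a row of centers: interpolate in x
        i = int(round(y))
        xlo = math.floor(x)
        xhi = min(xlo + 1, z.shape[1] - 1)
        f = x - xlo
        if not (valid[i, xlo] and valid[i, xhi]):
            return None
        return (1 - f) * z[i, xlo] + f * z[i, xhi]
    if not (valid[ylo, j] and valid[yhi, j]):
        return None
    return (1 - f) * z[ylo, j] + f * z[yhi, j]


def _sight_clear(z: np.ndarray, valid: np.ndarray,
                 obs: tuple[int, int], tgt: tuple[int, int]) -> bool:
    """True when no interpolated terrain elevation strictly between the two
    cell centers rises above the straight sight line."""
    if obs == tgt:
        return True
    z0 = z[obs]
    z1 = z[tgt]
    for t in _profile_crossings(obs, tgt):
        h = _profile_elevation(z, valid, obs, tgt, t)
        if h is None:
            continue
        line = z0 + t * (z1 - z0)
        if h > line + 1e-12:
            return False
    return True


def viewshed(dem: RasterLayer, observer: tuple[int, int],
             max_distance: float) -> RasterLayer:
    """Binary visibility from one observer cell.

    A cell is visible iff no terrain elevation along the center-to-center
    ray (linearly interpolated between cell centers) rises above the sight
    line.  The observer is always visible; cells farther than
    ``max_distance`` (center to center, map units) are 0.
    """
    spec = dem.spec
    oi, oj = observer
    if not (0 <= oi < spec.n_rows and 0 <= oj < spec.n_cols):
        raise DomainError("observer cell outside the grid")
    z = dem.values
    valid = dem.valid_mask
    out = np.zeros(spec.shape)
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            d = math.hypot(i - oi, j - oj) * spec.cell_size
            if d > max_distance:
                continue
            if not valid[i, j]:
                continue
            if _sight_clear(z, valid, (oi, oj), (i, j)):
                out[i, j] = 1.0
    out[oi, oj] = 1.0
    return RasterLayer(spec, out, semantics="visibility", units="0/1")


def _ray_cells(a: tuple[int, int], b: tuple[int, int]) -> list[tuple[int, int]]:
    """Ordered cells traversed by the segment from center ``a`` to center
    ``b`` (supercover by boundary crossings), endpoints included."""
    (i0, j0), (i1, j1) = a, b
    ts = [0.0, 1.0]
    di, dj = i1 - i0, j1 - j0
    if dj:
        lo, hi = sorted((j0, j1))
        for m in range(lo, hi):
            ts.append((m + 0.5 - j0) / dj)
    if di:
        lo, hi = sorted((i0, i1))
        for m in range(lo, hi):
            ts.append((m + 0.5 - i0) / di)
    ts = sorted(set(t for t in ts if 0.0 <= t <= 1.0))
    cells = []
    for t0, t1 in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (t0 + t1)
        cell = (int(round(i0 + tm * di)), int(round(j0 + tm * dj)))
        if not cells or cells[-1] != cell:
            cells.append(cell)
    if not cells:
        cells = [a]
    if cells[-1] != b:
        cells.append(b)
    return cells


def _run_los_pass(problem: SpanProblem, sinks_active: bool) -> _PassResult:
    """Each use cell receives every visible source within range; sinks act
    as ray-intercepting attenuators subtracting capacity from the
    contribution (floor 0).  Non-rival: contributions multiply by the use
    weight and nothing is depleted."""
    spec = problem.spec
    dem = problem.router.dem
    maxd = float(problem.router.max_distance)
    z = dem.values
    valid = dem.valid_mask
    source = problem.source.filled(0.0)
    cap = problem.sink.filled(0.0) if sinks_active else np.zeros(spec.shape)
    weight = problem.use.filled(0.0)

    flow = np.zeros(spec.shape)
    use_received = np.zeros(spec.shape)
    sink_absorbed = np.zeros(spec.shape)
    source_delivered = np.zeros(spec.shape)

    users = list(zip(*np.nonzero(weight > 0)))
    sources = list(zip(*np.nonzero(source > 0)))
    for (ui, uj) in users:
        w = weight[ui, uj]
        for (si, sj) in sources:
            if math.hypot(si - ui, sj - uj) * spec.cell_size > maxd:
                continue
            if not _sight_clear(z, valid, (int(ui), int(uj)), (int(si), int(sj))):
                continue
            remaining = source[si, sj]
            path = _ray_cells((int(si), int(sj)), (int(ui), int(uj)))
            for (ci, cj) in path:
                flow[ci, cj] += remaining * w
                if (ci, cj) != (si, sj) and (ci, cj) != (ui, uj):
                    ab = min(remaining, cap[ci, cj])
                    if ab > 0:
                        sink_absorbed[ci, cj] += ab
                        remaining -= ab
                if remaining <= 0:
                    break
            if remaining > 0:
                use_received[ui, uj] += remaining * w
                source_delivered[si, sj] += remaining * w
    # attenuation is non-consumptive across rays: the sink map records the
    # capacity actually exercised, never more than the capacity itself
    sink_absorbed = np.minimum(sink_absorbed, cap)
    return _PassResult(flow, use_received, sink_absorbed, source_delivered, 0.0)


# ---------------------------------------------------------------------------
# Cost distance / access routing
# ---------------------------------------------------------------------------

def cost_distance(cost: RasterLayer, origins: list[tuple[int, int]],
                  max_cost: float | None = None) -> RasterLayer:
    """Least cumulative traversal cost (8-connected) from the nearest origin.

    A step between adjacent cells costs the mean of the two endpoint costs,
    times sqrt(2) for diagonal moves.  Cells beyond ``max_cost`` (or
    unreachable) are nodata.
    """
    if not origins:
        raise DomainError("cost_distance requires at least one origin cell")
    if np.any(cost.values[cost.valid_mask] < 0):
        raise DomainError("cost layer has negative values")
    dist, _ = _dijkstra(cost, origins, max_cost)
    spec = cost.spec
    out = np.where(np.isfinite(dist), dist, spec.nodata)
    return RasterLayer(spec, out, semantics="cost_distance", units="cost")


def _dijkstra(cost: RasterLayer, origins: list[tuple[int, int]],
              max_cost: float | None):
    """Returns (distance array, predecessor flat-index array)."""
    spec = cost.spec
    c = cost.filled(np.inf)
    c[~cost.valid_mask] = np.inf
    dist = np.full(spec.shape, np.inf)
    pred = np.full(spec.shape, -1, dtype=np.int64)
    heap: list[tuple[float, int, int]] = []
    for (i, j) in origins:
        if not (0 <= i < spec.n_rows and 0 <= j < spec.n_cols):
            raise DomainError("origin cell outside the grid")
        dist[i, j] = 0.0
        heapq.heappush(heap, (0.0, i, j))
    while heap:
        d, i, j = heapq.heappop(heap)
        if d > dist[i, j]:
            continue
        for (di, dj) in NEIGHBOR_OFFSETS:
            ni, nj = i + di, j + dj
            if not (0 <= ni < spec.n_rows and 0 <= nj < spec.n_cols):
                continue
            if not np.isfinite(c[ni, nj]):
                continue
            step = 0.5 * (c[i, j] + c[ni, nj]) * (math.sqrt(2.0) if di and dj else 1.0)
            nd = d + step
            if max_cost is not None and nd > max_cost:
                continue
            if nd < dist[ni, nj]:
                dist[ni, nj] = nd
                pred[ni, nj] = i * spec.n_cols + j
                heapq.heappush(heap, (nd, ni, nj))
    return dist, pred


def _walk_path(pred: np.ndarray, spec: GridSpec, end: tuple[int, int],
               ) -> list[tuple[int, int]]:
    """Path from the Dijkstra origin to ``end`` (origin first)."""
    path = [end]
    i, j = end
    while pred[i, j] >= 0:
        p = int(pred[i, j])
        i, j = divmod(p, spec.n_cols)
        path.append((i, j))
    path.reverse()
    return path


def _run_access_pass(problem: SpanProblem, sinks_active: bool) -> _PassResult:
    """Users reach sources within ``max_cost`` by least-cost distance.

    Rival: source capacity is allocated over (user, source) claims in
    increasing cost order; exact cost ties on one source split
    proportionally to unmet demand.  Non-rival: every reachable source
    contributes fully to every reaching user.  In the actual pass, sinks on
    the least-cost path absorb carrier (shared capacities deplete in claim
    order for rival problems)."""
    spec = problem.spec
    cost = problem.router.cost
    max_cost = float(problem.router.max_cost)
    source = problem.source.filled(0.0)
    caps = problem.sink.filled(0.0).copy() if sinks_active else np.zeros(spec.shape)
    demand = problem.use.filled(0.0)
    rival = problem.benefit.rivalness == "rival"

    flow = np.zeros(spec.shape)
    use_received = np.zeros(spec.shape)
    sink_absorbed = np.zeros(spec.shape)
    source_delivered = np.zeros(spec.shape)

    users = [tuple(map(int, u)) for u in zip(*np.nonzero(demand > 0))]
    sources = [tuple(map(int, s)) for s in zip(*np.nonzero(source > 0))]
    if not users or not sources:
        return _PassResult(flow, use_received, sink_absorbed, source_delivered, 0.0)

    reach: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    claims = []  # (cost, user, source)
    for u in users:
        dist, pred = _dijkstra(cost, [u], max_cost)
        reach[u] = (dist, pred)
        for s in sources:
            if np.isfinite(dist[s]) and dist[s] <= max_cost:
                claims.append((float(dist[s]), u, s))
    claims.sort(key=lambda c: (c[0], c[1], c[2]))

    def transport(u, s, gross, w=1.0):
        """Move ``gross`` carrier from s to u along the least-cost path,
        absorbing into (and for rival problems depleting) path sinks.
        Flow increments scale with the user weight ``w``.  Returns the
        delivered amount (unweighted)."""
        _, pred = reach[u]
        path = _walk_path(pred, spec, s)  # user ... source
        path = list(reversed(path))       # source ... user
        current = gross
        for (ci, cj) in path:
            flow[ci, cj] += current * w
            if (ci, cj) != s and (ci, cj) != u:
                ab = min(current, caps[ci, cj])
                if ab > 0:
                    sink_absorbed[ci, cj] += ab
                    current -= ab
                    if rival:
                        caps[ci, cj] -= ab
            if current <= 0:
                break
        return max(current, 0.0)

    if not rival:
        for (_, u, s) in claims:
            w = demand[u]
            delivered = transport(u, s, source[s], w)
            use_received[u] += delivered * w
            source_delivered[s] += delivered * w
        # attenuation is non-consumptive across rays for non-rival use
        sink_absorbed = np.minimum(sink_absorbed, caps)
        return _PassResult(flow, use_received, sink_absorbed, source_delivered, 0.0)

    remaining = {s: source[s] for s in sources}
    unmet = {u: demand[u] for u in users}
    i = 0
    while i < len(claims):
        j = i
        while j < len(claims) and claims[j][0] == claims[i][0]:
            j += 1
        group = claims[i:j]
        # group by source so equal-cost claimants split proportionally
        by_source: dict[tuple, list[tuple]] = {}
        for (_, u, s) in group:
            by_source.setdefault(s, []).append(u)
        for s in sorted(by_source):
            claimants = [u for u in by_source[s] if unmet[u] > 0]
            if not claimants or remaining[s] <= 0:
                continue
            total_unmet = sum(unmet[u] for u in claimants)
            avail = remaining[s]
            for u in claimants:
                share = avail * unmet[u] / total_unmet if total_unmet > 0 else 0.0
                want = unmet[u]
                # withdraw enough extra to cover en-route absorption
                _, predu = reach[u]
                path = list(reversed(_walk_path(predu, spec, s)))
                cap_on_path = sum(caps[c] for c in path if c != s and c != u)
                gross = min(share, want + cap_on_path)
                if gross <= 0:
                    continue
                delivered = min(transport(u, s, gross), want)
                remaining[s] -= gross
                unmet[u] -= delivered
                use_received[u] += delivered
                source_delivered[s] += delivered
        i = j
    return _PassResult(flow, use_received, sink_absorbed, source_delivered, 0.0)


# ---------------------------------------------------------------------------
# Global mixing
# ---------------------------------------------------------------------------

def _run_global_pass(problem: SpanProblem, sinks_active: bool) -> _PassResult:
    """Well-mixed carrier: one global pool net of sink absorption,
    allocated to users proportionally to demand and capped by demand."""
    spec = problem.spec
    source = problem.source.filled(0.0)
    sink = problem.sink.filled(0.0) if sinks_active else np.zeros(spec.shape)
    demand = problem.use.filled(0.0)
    tot_s = float(source.sum())
    tot_k = float(sink.sum())
    absorbed = min(tot_s, tot_k)
    pool = tot_s - absorbed
    tot_d = float(demand.sum())
    if tot_d > 0 and pool > 0:
        alloc = np.minimum(demand, pool * demand / tot_d)
    else:
        alloc = np.zeros(spec.shape)
    delivered = float(alloc.sum())
    source_delivered = (source / tot_s * delivered) if tot_s > 0 else np.zeros(spec.shape)
    sink_absorbed = (sink / tot_k * absorbed) if tot_k > 0 else np.zeros(spec.shape)
    n_cells = spec.n_rows * spec.n_cols
    flow = np.full(spec.shape, pool / n_cells)
    exported = pool - delivered
    return _PassResult(flow, alloc, sink_absorbed, source_delivered, exported)


# ---------------------------------------------------------------------------
# Simulation driver and taxonomy assembly
# ---------------------------------------------------------------------------

_PASS_RUNNERS = {
    "d8_downslope": _run_d8_pass,
    "line_of_sight": _run_los_pass,
    "access_cost": _run_access_pass,
    "global_mix": _run_global_pass,
}


def run_span(problem: SpanProblem) -> SpanOutputs:
    """Run the two-pass flow simulation and assemble all output maps.

    The *possible* pass forces every sink capacity to 0; the *actual* pass
    runs with sinks active.  Identical inputs give bit-identical outputs:
    every router is deterministic.
    """
    runner = _PASS_RUNNERS[problem.router.mode]
    possible = runner(problem, sinks_active=False)
    actual = runner(problem, sinks_active=True)
    theoretical = (problem.source, problem.sink, problem.use)
    outputs = derive_output_maps(theoretical, possible, actual)
    outputs.run_log.update({
        "router": problem.router.mode,
        "benefit_type": problem.benefit.benefit_type,
        "rivalness": problem.benefit.rivalness,
        "carrier": problem.benefit.carrier,
        "exported_possible": possible.exported,
        "exported_actual": actual.exported,
    })
    return outputs


def _subtract(a: np.ndarray, b: np.ndarray, name: str, *,
              mode: str = "strict") -> np.ndarray:
    """a - b with rounding residue in (-1e-9, 0) clipped to 0.

    ``strict`` raises on structurally negative entries; ``floor`` clips
    them to 0 (used where non-rival replication can legitimately deliver
    more than the in-situ total); ``signed`` keeps them.
    """
    out = a - b
    tiny = (out < 0) & (out > -1e-9)
    out[tiny] = 0.0
    if mode == "strict":
        scale = max(float(np.abs(a).max()), 1.0)
        if np.any(out < -1e-6 * scale):
            raise InternalConsistencyError(
                f"{name} has negative entries beyond tolerance"
            )
        out[out < 0] = 0.0
    elif mode == "floor":
        out[out < 0] = 0.0
    return out


def derive_output_maps(theoretical, possible_pass: _PassResult,
                       actual_pass: _PassResult) -> SpanOutputs:
    """Assemble the taxonomy from the raw passes.

    blocked_X = possible_X - actual_X; inaccessible source/use =
    theoretical - possible; inaccessible sink = theoretical - actual.
    ``blocked_source`` may be locally negative under rival contention at
    confluences (origin shares shift when sinks activate); its aggregate is
    verified nonnegative instead.
    """
    theo_source, theo_sink, theo_use = theoretical
    spec = theo_source.spec

    def L(values, semantics, units=""):
        return RasterLayer(spec, values, semantics, units or theo_source.units)

    ps, pu, pf = (possible_pass.source_delivered, possible_pass.use_received,
                  possible_pass.flow)
    as_, ak, au, af = (actual_pass.source_delivered, actual_pass.sink_absorbed,
                       actual_pass.use_received, actual_pass.flow)
    blocked_source = _subtract(ps.copy(), as_, "blocked_source", mode="signed")
    if blocked_source.sum() < -1e-6 * max(ps.sum(), 1.0):
        raise InternalConsistencyError("aggregate blocked_source is negative")
    blocked_use = _subtract(pu.copy(), au, "blocked_use")
    # demand-driven withdrawal (access routing) can move extra carrier to
    # cover en-route absorption, so the flow difference floors at zero
    blocked_flow = _subtract(pf.copy(), af, "blocked_flow", mode="floor")
    # non-rival replication can deliver more than the in-situ totals, so
    # inaccessibility floors at zero (a no-op for rival problems)
    inaccessible_source = _subtract(theo_source.filled(0.0), ps,
                                    "inaccessible_source", mode="floor")
    inaccessible_use = _subtract(theo_use.filled(0.0), pu,
                                 "inaccessible_use", mode="floor")
    inaccessible_sink = _subtract(theo_sink.filled(0.0), ak, "inaccessible_sink")

    return SpanOutputs(
        theoretical_source=theo_source.copy(),
        theoretical_sink=theo_sink.copy(),
        theoretical_use=theo_use.copy(),
        possible_source=L(ps, "possible_source"),
        possible_use=L(pu, "possible_use"),
        possible_flow=L(pf, "possible_flow"),
        actual_source=L(as_, "actual_source"),
        actual_sink=L(ak, "actual_sink"),
        actual_use=L(au, "actual_use"),
        actual_flow=L(af, "actual_flow"),
        inaccessible_source=L(inaccessible_source, "inaccessible_source"),
        inaccessible_sink=L(inaccessible_sink, "inaccessible_sink"),
        inaccessible_use=L(inaccessible_use, "inaccessible_use"),
        blocked_source=L(blocked_source, "blocked_source"),
        blocked_use=L(blocked_use, "blocked_use"),
        blocked_flow=L(blocked_flow, "blocked_flow"),
    )


# ---------------------------------------------------------------------------
# Sustainability sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepResult:
    """Outcome of a demand sweep: supply ceiling relative to current need."""

    current_need: float
    max_potential: float
    ratio: int  # percent, nearest integer

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise DomainError("ratio must be nonnegative")


def potential_need_ratio(max_potential: float, current_need: float) -> int:
    """100 * max_potential / current_need, rounded half away from zero to
    the nearest integer percent."""
    if current_need <= 0:
        raise UndefinedRatioError("current need is zero; ratio undefined")
    x = 100.0 * max_potential / current_need
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def sustainability_sweep(problem: SpanProblem,
                         multipliers: list[float]) -> SweepResult:
    """Re-run the flow simulation with demand scaled by each multiplier.

    ``max_potential`` is the largest total delivered use observed across
    multipliers; ``current_need`` is the total demand at multiplier 1
    (inserted when absent).  The ratio is the integer percent
    100 * max_potential / current_need.
    """
    if not multipliers:
        raise DomainError("need at least one multiplier")
    if any(m <= 0 for m in multipliers):
        raise DomainError("multipliers must be positive")
    if sorted(multipliers) != list(multipliers):
        raise DomainError("multipliers must be sorted ascending")
    ms = list(multipliers)
    if 1.0 not in ms:
        ms = sorted(ms + [1.0])
    current_need = 0.0
    max_potential = 0.0
    for m in ms:
        scaled = problem.with_use_scaled(m)
        outputs = run_span(scaled)
        delivered = outputs.actual_use.total()
        max_potential = max(max_potential, delivered)
        if m == 1.0:
            current_need = outputs.theoretical_use.total()
    return SweepResult(current_need, max_potential,
                       potential_need_ratio(max_potential, current_need))
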