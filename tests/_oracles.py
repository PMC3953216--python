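"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a different route than the library:
joint enumeration for network posteriors, dense per-origin matrix
propagation for downslope flow, dense ray sampling for visibility, and
explicit graph shortest paths for cost distance.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

# neighbour order matches the library's documented convention
# (clockwise from East, row axis pointing south)
OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


# ---------------------------------------------------------------------------
# Bayesian networks
# ---------------------------------------------------------------------------

def enumerate_posterior(net, target: str, evidence: dict[str, str]) -> np.ndarray:
    """P(target | evidence) by summing the full joint distribution."""
    names = list(net.nodes)
    cards = [net.nodes[n].card for n in names]
    ev_idx = {n: net.nodes[n].states.index(s) for n, s in evidence.items()}
    t = names.index(target)
    probs = np.zeros(net.nodes[target].card)
    for assignment in itertools.product(*(range(c) for c in cards)):
        if any(assignment[names.index(n)] != i for n, i in ev_idx.items()):
            continue
        p = 1.0
        for k, name in enumerate(names):
            idx = tuple(assignment[names.index(par)] for par in net.parents[name])
            p *= net.cpts[name][idx + (assignment[k],)]
        probs[assignment[t]] += p
    z = probs.sum()
    return probs / z if z > 0 else probs


def smoothed_counts(cases, node, parents, node_states, parent_states, alpha):
    """Hand-counted additive-smoothing CPT for one node."""
    shape = tuple(len(s) for s in parent_states) + (len(node_states),)
    counts = np.zeros(shape)
    for _, row in cases.iterrows():
        pidx = tuple(parent_states[k].index(row[p]) for k, p in enumerate(parents))
        counts[pidx + (node_states.index(row[node]),)] += 1
    out = np.empty(shape)
    it = np.ndindex(shape[:-1]) if parents else [()]
    for pidx in it:
        row = counts[pidx]
        tot = row.sum()
        if alpha == 0 and tot == 0:
            out[pidx] = 1.0 / len(node_states)
        else:
            out[pidx] = (row + alpha) / (tot + alpha * len(node_states))
    return out


# ---------------------------------------------------------------------------
# Downslope flow
# ---------------------------------------------------------------------------

def steepest_descent_directions(dem_values, cell_size, nodata_mask):
    """Per-cell steepest strictly-lower neighbour by exhaustive check."""
    nr, nc = dem_values.shape
    direction = np.full((nr, nc), -1, dtype=int)
    for i in range(nr):
        for j in range(nc):
            if nodata_mask[i, j]:
                continue
            best, best_code = 0.0, -1
            for code, (di, dj) in enumerate(OFFSETS):
                ni, nj = i + di, j + dj
                if not (0 <= ni < nr and 0 <= nj < nc) or nodata_mask[ni, nj]:
                    continue
                dist = cell_size * (math.sqrt(2) if di and dj else 1.0)
                grad = (dem_values[i, j] - dem_values[ni, nj]) / dist
                if grad > best:
                    best, best_code = grad, code
            direction[i, j] = best_code
    return direction


def d8_pass_oracle(problem, sinks_active: bool):
    """Per-origin matrix propagation of every trajectory in topological
    order, with proportional depletion of shared sink capacity and rival
    demand.  Returns (flow, use, sink, source_delivered, exported)."""
    spec = problem.spec
    nr, nc = spec.shape
    n = nr * nc
    dem = problem.router.dem
    direction = steepest_descent_directions(dem.values, spec.cell_size,
                                            dem.nodata_mask)
    source = problem.source.filled(0.0).ravel()
    cap = problem.sink.filled(0.0).ravel() if sinks_active else np.zeros(n)
    demand = problem.use.filled(0.0).ravel()
    rival = problem.benefit.rivalness == "rival"
    elev = dem.filled(-np.inf).ravel()
    order = np.argsort(-elev, kind="stable")

    comp = np.zeros((n, n))  # comp[c, o]: carrier at c originating at o
    flow = np.zeros(n)
    use = np.zeros(n)
    sink = np.zeros(n)
    delivered = np.zeros(n)
    exported = 0.0
    for c in order:
        c = int(c)
        comp[c, c] += source[c]
        through = comp[c].sum()
        flow[c] = through
        if through <= 0:
            continue
        rem = through
        ab = min(rem, cap[c])
        if ab > 0:
            comp[c] *= (rem - ab) / rem
            sink[c] = ab
            rem -= ab
        if demand[c] > 0 and rem > 0:
            take = min(rem, demand[c])
            use[c] = take
            delivered += comp[c] * (take / rem)
            if rival:
                comp[c] *= (rem - take) / rem
                rem -= take
        if rem <= 0:
            continue
        code = direction[c // nc, c % nc]
        if code < 0:
            exported += rem
        else:
            di, dj = OFFSETS[code]
            succ = (c // nc + di) * nc + (c % nc + dj)
            comp[succ] += comp[c]
            comp[c] = 0.0
    shape = (nr, nc)
    return (flow.reshape(shape), use.reshape(shape), sink.reshape(shape),
            delivered.reshape(shape), exported)


# ---------------------------------------------------------------------------
# Visibility
# ---------------------------------------------------------------------------

def visibility_oracle(dem_values, obs, tgt, n_samples: int = 100) -> bool:
    """Dense sampling of the terrain profile along the sight ray.

    The profile is the piecewise-linear interpolation, along the ray, of
    the elevations where the ray crosses rows/columns of cell centers
    (each crossing interpolated between the two adjacent centers)."""
    if obs == tgt:
        return True
    (i0, j0), (i1, j1) = obs, tgt
    ts, hs = [0.0], [dem_values[obs]]
    crossings = []
    if j1 != j0:
        for m in range(min(j0, j1) + 1, max(j0, j1)):
            crossings.append((m - j0) / (j1 - j0))
    if i1 != i0:
        for m in range(min(i0, i1) + 1, max(i0, i1)):
            crossings.append((m - i0) / (i1 - i0))
    for t in sorted(set(crossings)):
        x = j0 + t * (j1 - j0)
        y = i0 + t * (i1 - i0)
        if abs(x - round(x)) < 1e-9:
            j = int(round(x))
            lo = math.floor(y)
            hi = min(lo + 1, dem_values.shape[0] - 1)
            f = y - lo
            h = (1 - f) * dem_values[lo, j] + f * dem_values[hi, j]
        else:
            i = int(round(y))
            lo = math.floor(x)
            hi = min(lo + 1, dem_values.shape[1] - 1)
            f = x - lo
            h = (1 - f) * dem_values[i, lo] + f * dem_values[i, hi]
        ts.append(t)
        hs.append(h)
    ts.append(1.0)
    hs.append(dem_values[tgt])
    z0, z1 = dem_values[obs], dem_values[tgt]
    # dense uniform samples plus the profile breakpoints, so a narrow
    # exceedance spike at a crossing cannot slip between samples
    samples = np.concatenate([np.linspace(0.0, 1.0, n_samples + 2)[1:-1],
                              np.asarray(ts[1:-1])])
    for t in np.sort(samples):
        h = np.interp(t, ts, hs)
        if h > z0 + t * (z1 - z0) + 1e-9:
            return False
    return True


# ---------------------------------------------------------------------------
# Cost distance
# ---------------------------------------------------------------------------

def cost_distance_oracle(cost_values, origins, max_cost=None):
    """Least-cost distances via an explicit networkx graph."""
    nr, nc = cost_values.shape
    g = nx.Graph()
    for i in range(nr):
        for j in range(nc):
            for di, dj in OFFSETS:
                ni, nj = i + di, j + dj
                if 0 <= ni < nr and 0 <= nj < nc:
                    w = 0.5 * (cost_values[i, j] + cost_values[ni, nj])
                    w *= math.sqrt(2) if di and dj else 1.0
                    g.add_edge((i, j), (ni, nj), weight=w)
    g.add_nodes_from(((i, j) for i in range(nr) for j in range(nc)))
    dist = np.full((nr, nc), np.inf)
    lengths = nx.multi_source_dijkstra_path_length(g, list(origins))
    for (i, j), d in lengths.items():
        if max_cost is None or d <= max_cost:
            dist[i, j] = d
    return dist
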