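"""Discrete Bayesian-network production functions.

A small, exact engine for the probabilistic models that turn evidence
raster layers into per-cell posterior distributions: network definition and
(de)serialisation, exact inference by variable elimination, CPT training
with additive (Dirichlet-style) smoothing, spatial application, and the
paired value/uncertainty map summaries (coefficient of variation for
numeric nodes, Shannon diversity for categorical ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, InconsistentEvidenceError
from .raster import GridSpec, RasterLayer

__all__ = [
    "DiscreteDistribution",
    "DistributionLayer",
    "BayesNet",
    "infer_posterior",
    "train_cpts",
    "apply_bn",
    "summarize",
]

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-9


@dataclass
class DiscreteDistribution:
    """A finite discrete distribution over ordered, labelled states."""

    states: tuple[str, ...]
    probs: np.ndarray
    midpoints: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.states),):
            raise DomainError("probs must have one entry per state")
        if np.any(self.probs < -_PROB_TOL):
            raise DomainError("probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > _PROB_TOL:
            raise DomainError("probabilities must sum to 1")

    def mean(self) -> float:
        if self.midpoints is None:
            raise DomainError("mean requires numeric state midpoints")
        return float(np.dot(self.probs, self.midpoints))

    def variance(self) -> float:
        m = self.mean()
        return float(np.dot(self.probs, (np.asarray(self.midpoints) - m) ** 2))

    def cv(self) -> float:
        """Coefficient of variation sqrt(var)/|mean|; 0 for a degenerate
        distribution with mean 0, NaN when mean is 0 but variance is not."""
        m = self.mean()
        v = self.variance()
        if m == 0.0:
            return 0.0 if v == 0.0 else float("nan")
        return float(np.sqrt(v) / abs(m))

    def entropy(self) -> float:
        """Shannon diversity -sum p ln p (natural log, 0 ln 0 := 0)."""
        p = self.probs[self.probs > 0]
        return float(-(p * np.log(p)).sum())

    def mode_index(self) -> int:
        """Index of the most probable state; ties go to the lowest index."""
        return int(np.argmax(self.probs))


@dataclass
class NodeDef:
    """A named discrete variable: ordered states, optional numeric midpoints."""

    states: tuple[str, ...]
    midpoints: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise DomainError("a node needs at least one state")
        if self.midpoints is not None and len(self.midpoints) != len(self.states):
            raise DomainError("midpoints must match states")

    @property
    def card(self) -> int:
        return len(self.states)


class BayesNet:
    """A DAG of discrete nodes with conditional probability tables.

    ``cpts[name]`` has shape ``(*parent_cards, card)``: the last axis runs
    over the node's own states and sums to 1 for every parent configuration.
    """

    def __init__(self, nodes: dict[str, NodeDef], parents: dict[str, tuple[str, ...]],
                 cpts: dict[str, np.ndarray]):
        self.nodes = dict(nodes)
        self.parents = {n: tuple(parents.get(n, ())) for n in self.nodes}
        self.cpts = {n: np.asarray(cpts[n], dtype=float) for n in self.nodes}
        self._validate()

    def _validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.nodes:
                    raise DomainError(f"unknown parent {p!r} of node {child!r}")
                g.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(g):
            raise DomainError("network graph contains a cycle")
        self._graph = g
        self._topo = tuple(nx.lexicographical_topological_sort(g))
        for name, node in self.nodes.items():
            want = tuple(self.nodes[p].card for p in self.parents[name]) + (node.card,)
            cpt = self.cpts[name]
            if cpt.shape != want:
                raise DomainError(
                    f"CPT of {name!r} has shape {cpt.shape}, expected {want}"
                )
            sums = cpt.sum(axis=-1)
            if np.any(np.abs(sums - 1.0) > _PROB_TOL):
                raise DomainError(f"CPT of {name!r} has columns not summing to 1")

    @property
    def topological_order(self) -> tuple[str, ...]:
        return self._topo

    def state_index(self, node: str, state: str) -> int:
        try:
            return self.nodes[node].states.index(state)
        except ValueError as exc:
            raise DomainError(f"node {node!r} has no state {state!r}") from exc

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "name": n,
                    "states": list(d.states),
                    **({"midpoints": list(d.midpoints)} if d.midpoints else {}),
                    "parents": list(self.parents[n]),
                    "cpt": self.cpts[n].reshape(-1, d.card).tolist(),
                }
                for n, d in self.nodes.items()
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BayesNet":
        nodes, parents, cpts = {}, {}, {}
        for entry in data["nodes"]:
            name = entry["name"]
            nodes[name] = NodeDef(
                tuple(entry["states"]),
                tuple(entry["midpoints"]) if entry.get("midpoints") else None,
            )
            parents[name] = tuple(entry.get("parents", ()))
        for entry in data["nodes"]:
            name = entry["name"]
            shape = tuple(nodes[p].card for p in parents[name]) + (nodes[name].card,)
            cpts[name] = np.asarray(entry["cpt"], dtype=float).reshape(shape)
        return cls(nodes, parents, cpts)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BayesNet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Exact inference: variable elimination
# ---------------------------------------------------------------------------

def _factors(net: BayesNet, evidence_idx: dict[str, int]):
    """CPTs reduced by evidence, as (vars, array) pairs."""
    factors = []
    for name in net.nodes:
        vars_ = net.parents[name] + (name,)
        arr = net.cpts[name]
        keep_vars = []
        index: list = []
        for v in vars_:
            if v in evidence_idx:
                index.append(evidence_idx[v])
            else:
                index.append(slice(None))
                keep_vars.append(v)
        factors.append((tuple(keep_vars), arr[tuple(index)]))
    return factors


def _multiply_and_marginalize(factors, eliminate: str):
    """Multiply the factors involving ``eliminate`` and sum it out."""
    touching = [f for f in factors if eliminate in f[0]]
    rest = [f for f in factors if eliminate not in f[0]]
    all_vars: list[str] = []
    for vars_, _ in touching:
        for v in vars_:
            if v not in all_vars:
                all_vars.append(v)
    prod = None
    for vars_, arr in touching:
        # broadcast arr into the all_vars axis order
        shape = [1] * len(all_vars)
        src = arr
        order = [all_vars.index(v) for v in vars_]
        expanded = np.moveaxis(
            src.reshape(src.shape + (1,) * (len(all_vars) - src.ndim)),
            range(len(vars_)), order,
        )
        prod = expanded if prod is None else prod * expanded
    axis = all_vars.index(eliminate)
    summed = prod.sum(axis=axis)
    new_vars = tuple(v for v in all_vars if v != eliminate)
    rest.append((new_vars, summed))
    return rest


def infer_posterior(net: BayesNet, target: str,
                    evidence: dict[str, str] | None = None) -> DiscreteDistribution:
    """Exact posterior P(target | evidence) by variable elimination.

    Equals brute-force summation over the full joint.  Evidence on the
    target itself yields a point mass.  Evidence with zero joint
    probability raises :class:`InconsistentEvidenceError`.
    """
    evidence = evidence or {}
    if target not in net.nodes:
        raise DomainError(f"unknown target node {target!r}")
    evidence_idx = {n: net.state_index(n, s) for n, s in evidence.items()}
    node = net.nodes[target]
    if target in evidence_idx:
        # still verify the evidence is jointly possible
        probs = np.zeros(node.card)
        rest = {n: s for n, s in evidence.items() if n != target}
        marginal = infer_posterior(net, target, rest)
        if marginal.probs[evidence_idx[target]] <= 0.0:
            raise InconsistentEvidenceError(
                f"evidence {evidence!r} has zero joint probability"
            )
        probs[evidence_idx[target]] = 1.0
        return DiscreteDistribution(node.states, probs, node.midpoints)

    factors = _factors(net, evidence_idx)
    hidden = [n for n in net.topological_order
              if n != target and n not in evidence_idx]
    for h in hidden:
        factors = _multiply_and_marginalize(factors, h)
    # combine remaining factors, all over {target} or {}
    result = np.ones(node.card)
    for vars_, arr in factors:
        if vars_ == (target,):
            result = result * arr
        elif vars_ == ():
            result = result * float(arr)
        else:  # pragma: no cover - cannot happen after full elimination
            raise AssertionError("unexpected residual factor")
    z = result.sum()
    if z <= 0.0:
        raise InconsistentEvidenceError(
            f"evidence {evidence!r} has zero joint probability"
        )
    return DiscreteDistribution(node.states, result / z, node.midpoints)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_cpts(net: BayesNet, cases: pd.DataFrame, prior_weight: float = 1.0) -> BayesNet:
    """Estimate CPTs from complete cases with additive smoothing.

    Each entry becomes ``(count + a) / (parent-config count + a*k)`` where
    ``k`` is the number of target states and ``a = prior_weight``.
    ``a = 0`` gives maximum-likelihood frequencies; a parent configuration
    never seen with ``a = 0`` gets a uniform row and a logged warning.
    """
    if prior_weight < 0:
        raise DomainError("prior_weight must be >= 0")
    for name in net.nodes:
        if name not in cases.columns:
            raise DomainError(f"cases table lacks a column for node {name!r}")
    idx_cols = {
        name: cases[name].map(
            {s: i for i, s in enumerate(net.nodes[name].states)}
        ).to_numpy()
        for name in net.nodes
    }
    for name, arr in idx_cols.items():
        if np.any(pd.isna(arr)):
            raise DomainError(f"cases contain an invalid state for node {name!r}")
    idx_cols = {name: arr.astype(int) for name, arr in idx_cols.items()}
    new_cpts: dict[str, np.ndarray] = {}
    for name, node in net.nodes.items():
        ps = net.parents[name]
        k = node.card
        shape = tuple(net.nodes[p].card for p in ps) + (k,)
        counts = np.zeros(shape)
        full_idx = tuple(idx_cols[p] for p in ps) + (idx_cols[name],)
        np.add.at(counts, full_idx, 1.0)
        parent_totals = counts.sum(axis=-1, keepdims=True)
        if prior_weight == 0.0:
            cpt = np.empty(shape)
            with np.errstate(invalid="ignore", divide="ignore"):
                cpt = counts / parent_totals
            unseen = (parent_totals == 0.0)[..., 0]
            if np.any(unseen):
                logger.warning(
                    "node %r: %d unseen parent configuration(s) set to uniform",
                    name, int(unseen.sum()),
                )
                cpt[unseen] = 1.0 / k
        else:
            cpt = (counts + prior_weight) / (parent_totals + prior_weight * k)
        new_cpts[name] = cpt
    return BayesNet(net.nodes, net.parents, new_cpts)


# ---------------------------------------------------------------------------
# Spatial application
# ---------------------------------------------------------------------------

@dataclass
class DistributionLayer:
    """A per-cell discrete distribution over one shared state list.

    ``probs`` has shape ``(n_rows, n_cols, k)``.  ``midpoints`` may be a
    single ``(k,)`` vector or a per-cell ``(n_rows, n_cols, k)`` array (the
    latter lets a degenerate cell sit at an exact continuous value).
    ``valid_mask`` is False at nodata cells, which carry no distribution.
    """

    spec: GridSpec
    states: tuple[str, ...]
    probs: np.ndarray
    midpoints: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    semantics: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        k = len(self.states)
        if self.probs.shape != self.spec.shape + (k,):
            raise DomainError("probs must have shape (n_rows, n_cols, n_states)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.spec.shape, dtype=bool)
        if self.midpoints is not None:
            self.midpoints = np.asarray(self.midpoints, dtype=float)
            if self.midpoints.shape not in ((k,), self.spec.shape + (k,)):
                raise DomainError("midpoints must be (k,) or per-cell (rows, cols, k)")
        sums = self.probs.sum(axis=-1)
        bad = self.valid_mask & (np.abs(sums - 1.0) > 1e-6)
        if np.any(bad):
            raise DomainError("cell distributions must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def cell(self, row: int, col: int) -> DiscreteDistribution:
        if not self.valid_mask[row, col]:
            raise DomainError(f"cell ({row}, {col}) is nodata")
        mids = None
        if self.midpoints is not None:
            mids = tuple(
                self.midpoints[row, col] if self.midpoints.ndim == 3 else self.midpoints
            )
        return DiscreteDistribution(self.states, self.probs[row, col], mids)

    def cell_midpoints(self) -> np.ndarray:
        """Midpoints broadcast to per-cell shape (rows, cols, k)."""
        if self.midpoints is None:
            raise DomainError("layer has no numeric midpoints")
        if self.midpoints.ndim == 3:
            return self.midpoints
        return np.broadcast_to(self.midpoints, self.spec.shape + (self.n_states,))

    @classmethod
    def point_mass(cls, layer: RasterLayer, state: str = "value") -> "DistributionLayer":
        """Wrap a deterministic raster as a one-state distribution layer."""
        vals = layer.values[..., None]
        probs = np.ones(layer.spec.shape + (1,))
        return cls(layer.spec, (state,), probs, midpoints=vals,
                   valid_mask=layer.valid_mask, semantics=layer.semantics,
                   units=layer.units)


def apply_bn(net: BayesNet, evidence_layers: dict[str, RasterLayer],
             discretizers: dict[str, np.ndarray], target: str,
             spec: GridSpec | None = None) -> DistributionLayer:
    """Run the network per cell against discretised evidence rasters.

    Continuous evidence is binned by its node's strictly increasing bin
    edges (``k+1`` edges for ``k`` states); values outside the edges are
    clamped to the nearest edge bin and logged.  Nodata evidence is treated
    as missing and marginalised, so an all-nodata cell gets the target's
    prior marginal.  Posteriors are cached per distinct evidence
    combination, which makes grid application cheap.
    """
    if target not in net.nodes:
        raise DomainError(f"unknown target node {target!r}")
    layers = dict(evidence_layers)
    if spec is None:
        if not layers:
            raise DomainError("need a GridSpec when no evidence layers are given")
        spec = next(iter(layers.values())).spec
    for name, layer in layers.items():
        if layer.spec.shape != spec.shape:
            raise DomainError(f"evidence layer {name!r} is not aligned to the grid")
        edges = np.asarray(discretizers[name], dtype=float)
        if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
            raise DomainError(f"bin edges for {name!r} must be strictly increasing")
        if len(edges) != net.nodes[name].card + 1:
            raise DomainError(
                f"{name!r}: need k+1 bin edges for k={net.nodes[name].card} states"
            )

    node = net.nodes[target]
    k = node.card
    probs = np.empty(spec.shape + (k,))
    cache: dict[frozenset, np.ndarray] = {}
    n_clamped = 0

    # precompute per-layer state indices (-1 = missing)
    state_idx: dict[str, np.ndarray] = {}
    for name, layer in layers.items():
        edges = np.asarray(discretizers[name], dtype=float)
        raw = np.digitize(layer.values, edges) - 1
        clamped = np.clip(raw, 0, net.nodes[name].card - 1)
        n_clamped += int(np.sum((raw != clamped) & layer.valid_mask))
        clamped[~layer.valid_mask] = -1
        state_idx[name] = clamped
    if n_clamped:
        logger.info("apply_bn: clamped %d out-of-range evidence values to edge bins",
                    n_clamped)

    names = list(layers)
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            ev = frozenset(
                (n, int(state_idx[n][i, j])) for n in names if state_idx[n][i, j] >= 0
            )
            post = cache.get(ev)
            if post is None:
                evidence = {n: net.nodes[n].states[s] for n, s in ev}
                post = infer_posterior(net, target, evidence).probs
                cache[ev] = post
            probs[i, j] = post
    mids = np.asarray(node.midpoints, dtype=float) if node.midpoints else None
    return DistributionLayer(spec, node.states, probs, midpoints=mids,
                             semantics=target)


def summarize(dl: DistributionLayer, kind: str) -> tuple[RasterLayer, RasterLayer]:
    """Collapse a distribution layer into paired (value, uncertainty) maps.

    ``numeric``: value = expected midpoint, uncertainty = coefficient of
    variation (0 for a degenerate zero-mean cell, nodata when the mean is 0
    with positive variance).  ``categorical``: value = modal state index
    (ties to the lowest index), uncertainty = Shannon diversity (natural
    log).
    """
    spec = dl.spec
    nodata = spec.nodata
    invalid = ~dl.valid_mask
    if kind == "numeric":
        mids = dl.cell_midpoints()
        mean = np.einsum("ijk,ijk->ij", dl.probs, mids)
        var = np.einsum("ijk,ijk->ij", dl.probs, (mids - mean[..., None]) ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.sqrt(var) / np.abs(mean)
        zero_mean = mean == 0.0
        cv[zero_mean & (var == 0.0)] = 0.0
        cv[zero_mean & (var > 0.0)] = nodata
        mean = mean.copy()
        mean[invalid] = nodata
        cv[invalid] = nodata
        return (
            RasterLayer(spec, mean, dl.semantics + "_mean", dl.units),
            RasterLayer(spec, cv, dl.semantics + "_cv", ""),
        )
    if kind == "categorical":
        mode = np.argmax(dl.probs, axis=-1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(dl.probs > 0, np.log(dl.probs), 0.0)
        ent = -np.sum(dl.probs * logp, axis=-1)
        mode[invalid] = nodata
        ent[invalid] = nodata
        return (
            RasterLayer(spec, mode, dl.semantics + "_mode", "state index"),
            RasterLayer(spec, ent, dl.semantics + "_shannon", "nats"),
        )
    raise DomainError(f"unknown summary kind {kind!r}")
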