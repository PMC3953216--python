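"""Multi-criteria model assembly: rank candidate datasets/models for a
spatial context, resolve a concept into a tree of computable components,
apply scenario overrides, and record provenance.

Ontology reasoning is deliberately replaced by ordered specificity tag
paths (for example ``carbon -> soil-carbon -> top-soil-carbon``); the
ranking behaviour is preserved without a reasoner.  Six criteria, each
normalised to [0, 100], enter a weighted sum: semantic specificity, scale
specificity, detail/resolution, semantic distance, currency, and the
user-attributed quality rank (default 50 when unset).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DomainError, ResolutionError
from .raster import RasterLayer

__all__ = [
    "CandidateRecord",
    "ResolutionContext",
    "Scenario",
    "ResolutionNode",
    "score_candidate",
    "rank_candidates",
    "resolve",
    "apply_scenario",
]

CRITERIA = ("semantic_specificity", "scale_specificity", "detail",
            "semantic_distance", "currency", "user_rank")

_PREDICATE_RE = re.compile(
    r"^\s*(\w+)\s*(<=|>=|==|!=|<|>)\s*(-?\d+(?:\.\d+)?)\s*$"
)


@dataclass(frozen=True)
class CandidateRecord:
    """One entry of the model/data registry."""

    id: str
    concept: str
    kind: str  # "dataset" | "model"
    semantic_tags: tuple[str, ...]
    extent: tuple[float, float, float, float]  # x0, y0, x1, y1
    resolution: float
    time_period: tuple[float, float] | None = None
    source_ontology: str = ""
    user_rank: float | None = None
    requires: tuple[str, ...] = ()
    context_predicates: tuple[str, ...] = ()
    payload: object = None       # layer path, callable, net, ... opaque here
    priority: int = 0            # scenario overrides get 1

    def __post_init__(self) -> None:
        if self.kind not in ("dataset", "model"):
            raise DomainError(f"unknown candidate kind {self.kind!r}")
        if self.user_rank is not None and not (0 <= self.user_rank <= 100):
            raise DomainError("user_rank must lie in [0, 100]")
        if self.kind == "dataset" and self.requires:
            raise DomainError("datasets cannot require other concepts")


@dataclass
class ResolutionContext:
    """Where and when a model is being assembled, plus criterion weights."""

    extent: tuple[float, float, float, float]
    cell_size: float
    time_period: tuple[float, float] | None = None
    variables: dict = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    ontology: str = ""

    def __post_init__(self) -> None:
        w = {c: 1.0 for c in CRITERIA}
        w.update(self.weights)
        for c, v in w.items():
            if c not in CRITERIA:
                raise DomainError(f"unknown ranking criterion {c!r}")
            if v < 0:
                raise DomainError("criterion weights must be nonnegative")
        total = sum(w.values())
        if total <= 0:
            raise DomainError("at least one criterion weight must be positive")
        self.weights = {c: v / total for c, v in w.items()}


def _extent_overlap(a, b) -> float:
    """Intersection area of two (x0, y0, x1, y1) boxes."""
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    return max(w, 0.0) * max(h, 0.0)


def _period_overlap(candidate, ctx_period) -> float:
    """Currency sub-score in [0, 1]."""
    if ctx_period is None or candidate is None:
        return 1.0
    c0, c1 = candidate
    t0, t1 = ctx_period
    if c0 <= t0 and c1 >= t1:
        return 1.0
    span = t1 - t0
    if span <= 0:
        return 1.0 if c0 <= t0 <= c1 else 0.0
    return max(min(c1, t1) - max(c0, t0), 0.0) / span


def score_candidate(c: CandidateRecord, ctx: ResolutionContext,
                    target_path: tuple[str, ...] | None = None,
                    reference_ontology: str | None = None,
                    ) -> tuple[float, dict[str, float]]:
    """Weighted multi-criteria score in [0, 100] plus the per-criterion
    breakdown.  Raises :class:`ResolutionError` for a candidate with no
    spatial overlap (its score is undefined)."""
    ctx_area = _extent_overlap(ctx.extent, ctx.extent)
    overlap = _extent_overlap(c.extent, ctx.extent)
    if overlap <= 0:
        raise ResolutionError(
            f"candidate {c.id!r} does not overlap the context extent"
        )
    path = target_path if target_path else c.semantic_tags
    depth = 0
    for a, b in zip(c.semantic_tags, path):
        if a != b:
            break
        depth += 1
    breakdown = {
        "semantic_specificity": 100.0 * depth / max(len(path), 1),
        "scale_specificity": 100.0 * (overlap / ctx_area if ctx_area > 0 else 1.0),
        "detail": 100.0 * min(ctx.cell_size / c.resolution, 1.0),
        "semantic_distance": 100.0 if c.source_ontology == (
            reference_ontology if reference_ontology is not None else ctx.ontology
        ) else 50.0,
        "currency": 100.0 * _period_overlap(c.time_period, ctx.time_period),
        "user_rank": float(c.user_rank) if c.user_rank is not None else 50.0,
    }
    score = sum(ctx.weights[k] * v for k, v in breakdown.items())
    return score, breakdown


def rank_candidates(cands: list[CandidateRecord], ctx: ResolutionContext,
                    target_path: tuple[str, ...] | None = None,
                    reference_ontology: str | None = None,
                    ) -> list[tuple[CandidateRecord, float, dict]]:
    """Overlapping candidates in descending score order.

    Scenario overrides (priority 1) always precede baseline entries; ties
    break deterministically by finer resolution, then lexicographic id.
    """
    scored = []
    for c in cands:
        try:
            s, br = score_candidate(c, ctx, target_path, reference_ontology)
        except ResolutionError:
            continue
        scored.append((c, s, br))
    if not scored:
        raise ResolutionError("no candidate overlaps the context extent")
    scored.sort(key=lambda t: (-t[0].priority, -t[1], t[0].resolution, t[0].id))
    return scored


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------

_OPS = {
    "<": np.less, "<=": np.less_equal, ">": np.greater,
    ">=": np.greater_equal, "==": np.equal, "!=": np.not_equal,
}


def _eval_predicate(expr: str, ctx: ResolutionContext):
    """Evaluate ``var op number`` against a context variable.

    Returns a boolean (scalar variable) or a boolean mask (raster
    variable).  An unknown variable fails the guard (False)."""
    m = _PREDICATE_RE.match(expr)
    if not m:
        raise ConfigError(f"cannot parse context predicate {expr!r}")
    var, op, value = m.group(1), m.group(2), float(m.group(3))
    if var not in ctx.variables:
        return False
    obj = ctx.variables[var]
    if isinstance(obj, RasterLayer):
        mask = _OPS[op](obj.values, value)
        mask &= obj.valid_mask
        return mask
    return bool(_OPS[op](float(obj), value))


def _candidate_mask(c: CandidateRecord, ctx: ResolutionContext):
    """True/False/mask describing where the candidate's guards hold."""
    result: object = True
    for expr in c.context_predicates:
        r = _eval_predicate(expr, ctx)
        if isinstance(r, np.ndarray) or isinstance(result, np.ndarray):
            r_arr = r if isinstance(r, np.ndarray) else (
                np.ones_like(result, dtype=bool) if r else np.zeros_like(result, dtype=bool))
            result = (result & r_arr) if isinstance(result, np.ndarray) else (
                r_arr if result else np.zeros_like(r_arr, dtype=bool))
        else:
            result = result and r
        if isinstance(result, bool) and not result:
            return False
    return result


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------

@dataclass
class ResolutionNode:
    """One node of the resolved model tree."""

    concept: str
    candidate: CandidateRecord
    score: float
    breakdown: dict[str, float]
    mask_fraction: float = 1.0   # spatial fraction of the grid served
    children: list["ResolutionNode"] = field(default_factory=list)

    def all_candidate_ids(self) -> list[str]:
        out = [self.candidate.id]
        for ch in self.children:
            out.extend(ch.all_candidate_ids())
        return out


def resolve(concept: str, registry: list[CandidateRecord],
            ctx: ResolutionContext,
            target_path: tuple[str, ...] | None = None,
            reference_ontology: str | None = None,
            _stack: tuple[str, ...] = (),
            _provenance: list | None = None,
            ) -> tuple[list[ResolutionNode], list[dict]]:
    """Resolve a concept to the best eligible candidate(s).

    The top-ranked eligible candidate is chosen; when its context
    predicates cover only part of the grid, further candidates are added
    until the grid is covered (the gentle/steep-slope partition case), so
    one concept may map to several nodes over disjoint spatial segments.
    Model candidates recursively resolve their required concepts; datasets
    are leaves.  Cyclic requirements are rejected.  Returns the tree roots
    and a provenance record listing every choice with its score breakdown.
    """
    if not registry:
        raise ResolutionError("registry is empty")
    if concept in _stack:
        raise ResolutionError(
            "cyclic requirements: " + " -> ".join(_stack + (concept,))
        )
    provenance = [] if _provenance is None else _provenance
    pool = [c for c in registry if c.concept == concept]
    if not pool:
        raise ResolutionError(
            f"no candidate observes concept {concept!r}"
            + (f" (required via {' -> '.join(_stack)})" if _stack else "")
        )
    ranked = rank_candidates(pool, ctx, target_path, reference_ontology)

    nodes: list[ResolutionNode] = []
    covered: object = False  # False | True | mask
    for cand, score, breakdown in ranked:
        if covered is True:
            break
        mask = _candidate_mask(cand, ctx)
        if mask is False:
            continue
        if isinstance(covered, np.ndarray) and isinstance(mask, np.ndarray):
            gain = mask & ~covered
            if not gain.any():
                continue
            effective = gain
        else:
            effective = mask
        frac = (float(np.mean(effective)) if isinstance(effective, np.ndarray)
                else 1.0)
        node = ResolutionNode(concept, cand, score, breakdown, frac)
        provenance.append({
            "concept": concept,
            "candidate": cand.id,
            "kind": cand.kind,
            "score": score,
            "breakdown": breakdown,
            "mask_fraction": frac,
            "parent": _stack[-1] if _stack else None,
        })
        for req in cand.requires:
            children, _ = resolve(
                req, registry, ctx,
                target_path=cand.semantic_tags,
                reference_ontology=cand.source_ontology,
                _stack=_stack + (concept,),
                _provenance=provenance,
            )
            node.children.extend(children)
        nodes.append(node)
        if effective is True or (isinstance(mask, np.ndarray) and covered is False
                                 and mask.all()):
            covered = True
        elif isinstance(mask, np.ndarray):
            covered = mask if covered is False else (covered | mask)
            if isinstance(covered, np.ndarray) and covered.all():
                covered = True
    if not nodes:
        raise ResolutionError(
            f"no eligible candidate for concept {concept!r} in this context"
        )
    return nodes, provenance


def provenance_to_json(provenance: list[dict]) -> str:
    return json.dumps(provenance, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A named set of concept overrides applied on top of a baseline
    registry."""

    name: str
    overrides: dict  # concept -> CandidateRecord or layer path string


def apply_scenario(registry: list[CandidateRecord],
                   scenario: Scenario) -> list[CandidateRecord]:
    """Return a new registry where the scenario's candidates take maximal
    priority for their concepts; the baseline list is left unmodified."""
    known = {c.concept for c in registry}
    out = list(registry)
    for concept, override in scenario.overrides.items():
        if concept not in known:
            raise ConfigError(
                f"scenario {scenario.name!r} overrides unknown concept {concept!r}"
            )
        if isinstance(override, CandidateRecord):
            cand = replace(override, concept=concept, priority=1)
        else:
            # a bare layer path becomes a dataset candidate covering everything
            template = next(c for c in registry if c.concept == concept)
            cand = CandidateRecord(
                id=f"{scenario.name}:{concept}",
                concept=concept,
                kind="dataset",
                semantic_tags=template.semantic_tags,
                extent=template.extent,
                resolution=template.resolution,
                payload=override,
                priority=1,
            )
        out.append(cand)
    return out
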