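"""Multi-criteria ranking, concept resolution and scenario overrides."""

import numpy as np
import pytest

from spanflow import (
    CandidateRecord,
    ConfigError,
    GridSpec,
    RasterLayer,
    ResolutionContext,
    ResolutionError,
    Scenario,
    apply_scenario,
    rank_candidates,
    resolve,
    score_candidate,
)

CTX_EXTENT = (0.0, 0.0, 100.0, 100.0)


def candidate(id="c", concept="precip", kind="dataset", tags=("precip",),
              extent=CTX_EXTENT, resolution=10.0, **kw):
    return CandidateRecord(id=id, concept=concept, kind=kind,
                           semantic_tags=tuple(tags), extent=extent,
                           resolution=resolution, **kw)


def context(**kw):
    kw.setdefault("extent", CTX_EXTENT)
    kw.setdefault("cell_size", 10.0)
    return ResolutionContext(**kw)


class TestScoring:
    def test_default_user_rank_is_50(self):
        _, breakdown = score_candidate(candidate(), context())
        assert breakdown["user_rank"] == 50.0

    def test_explicit_user_rank_used(self):
        _, breakdown = score_candidate(candidate(user_rank=80.0), context())
        assert breakdown["user_rank"] == 80.0

    def test_identical_candidates_score_identically(self):
        a, _ = score_candidate(candidate(id="a"), context())
        b, _ = score_candidate(candidate(id="b"), context())
        assert a == b

    def test_weighted_mean_recomputed_by_hand(self):
        ctx = context()
        score, br = score_candidate(candidate(), ctx)
        assert score == pytest.approx(sum(br.values()) / 6.0)
        assert all(0 <= v <= 100 for v in br.values())

    def test_partial_coverage_lowers_scale_specificity(self):
        half = candidate(extent=(0.0, 0.0, 50.0, 100.0))
        _, br = score_candidate(half, context())
        assert br["scale_specificity"] == pytest.approx(50.0)

    def test_semantic_specificity_depth_fraction(self):
        target = ("carbon", "soil-carbon", "top-soil-carbon")
        shallow = candidate(tags=("carbon",))
        deep = candidate(tags=target)
        _, br_s = score_candidate(shallow, context(), target_path=target)
        _, br_d = score_candidate(deep, context(), target_path=target)
        assert br_s["semantic_specificity"] == pytest.approx(100 / 3)
        assert br_d["semantic_specificity"] == pytest.approx(100.0)

    def test_no_overlap_excluded(self):
        off = candidate(extent=(500.0, 500.0, 600.0, 600.0))
        with pytest.raises(ResolutionError):
            score_candidate(off, context())

    def test_currency_overlap_fraction(self):
        c = candidate(time_period=(2000.0, 2005.0))
        _, br = score_candidate(c, context(time_period=(2000.0, 2010.0)))
        assert br["currency"] == pytest.approx(50.0)


class TestRanking:
    def test_single_candidate_first(self):
        ranked = rank_candidates([candidate()], context())
        assert len(ranked) == 1

    def test_finer_local_beats_coarser_global(self):
        fine = candidate(id="local", resolution=10.0)
        coarse = candidate(id="global", resolution=1000.0)
        ranked = rank_candidates([coarse, fine], context())
        assert ranked[0][0].id == "local"

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(70)
        pool = [
            candidate(id=f"c{i}",
                      resolution=float(rng.integers(5, 500)),
                      user_rank=float(rng.integers(0, 101)),
                      extent=(0.0, 0.0, float(rng.integers(40, 101)), 100.0))
            for i in range(12)
        ]
        ctx = context()
        ranked = rank_candidates(pool, ctx)
        scores = {c.id: score_candidate(c, ctx)[0] for c in pool}
        expected = sorted(pool, key=lambda c: (-scores[c.id], c.resolution, c.id))
        assert [r[0].id for r in ranked] == [c.id for c in expected]

    def test_deterministic_tie_break(self):
        a = candidate(id="a", resolution=10.0)
        b = candidate(id="b", resolution=10.0)
        ranked = rank_candidates([b, a], context())
        assert [r[0].id for r in ranked] == ["a", "b"]


def erosion_registry():
    """Gentle/steep partition: two models guard on a slope layer."""
    gentle = candidate(id="rusle", concept="erosion", kind="model",
                       tags=("erosion", "empirical"),
                       context_predicates=("slope <= 20",),
                       requires=("rainfall", "cover"))
    steep = candidate(id="steep-bn", concept="erosion", kind="model",
                      tags=("erosion", "probabilistic"),
                      context_predicates=("slope > 20",),
                      requires=("rainfall",))
    rain = candidate(id="rain-map", concept="rainfall", tags=("rainfall",))
    cover = candidate(id="cover-map", concept="cover", tags=("cover",))
    return [gentle, steep, rain, cover]


def slope_context():
    spec = GridSpec(4, 4, 10.0)
    slope_vals = np.zeros((4, 4))
    slope_vals[:, 2:] = 35.0  # east half steep
    slope = RasterLayer(spec, slope_vals, semantics="slope", units="%")
    return context(variables={"slope": slope})


class TestResolve:
    def test_single_dataset_one_leaf(self):
        nodes, prov = resolve("precip", [candidate()], context())
        assert len(nodes) == 1 and not nodes[0].children
        assert prov[0]["concept"] == "precip"

    def test_slope_partition_yields_both_branches(self):
        nodes, prov = resolve("erosion", erosion_registry(), slope_context())
        ids = {n.candidate.id for n in nodes}
        assert ids == {"rusle", "steep-bn"}
        fractions = {n.candidate.id: n.mask_fraction for n in nodes}
        assert fractions["rusle"] == pytest.approx(0.5)
        assert fractions["steep-bn"] == pytest.approx(0.5)
        # requirements resolved beneath each model
        assert {c.candidate.id for n in nodes for c in n.children} >= {"rain-map"}

    def test_matches_exhaustive_max_score_resolution(self):
        rng = np.random.default_rng(71)
        registry = [
            candidate(id=f"m{i}", concept="top", kind="model",
                      user_rank=float(rng.integers(0, 101)),
                      requires=("mid",))
            for i in range(3)
        ] + [
            candidate(id=f"d{i}", concept="mid",
                      user_rank=float(rng.integers(0, 101)))
            for i in range(3)
        ]
        ctx = context()
        nodes, _ = resolve("top", registry, ctx)
        # exhaustive: best model by score, then best dataset beneath it
        top_pool = [c for c in registry if c.concept == "top"]
        mid_pool = [c for c in registry if c.concept == "mid"]
        best_top = max(top_pool,
                       key=lambda c: (score_candidate(c, ctx)[0], c.id))
        assert nodes[0].candidate.id == best_top.id
        child = nodes[0].children[0]
        best_mid = max(
            mid_pool,
            key=lambda c: (score_candidate(
                c, ctx, best_top.semantic_tags, best_top.source_ontology)[0],
                c.id))
        assert child.candidate.id == best_mid.id

    def test_unresolvable_dependency_names_chain(self):
        broken = candidate(id="m", concept="top", kind="model",
                           requires=("missing",))
        with pytest.raises(ResolutionError, match="missing"):
            resolve("top", [broken], context())

    def test_cycle_rejected(self):
        a = candidate(id="a", concept="A", kind="model", requires=("B",))
        b = candidate(id="b", concept="B", kind="model", requires=("A",))
        with pytest.raises(ResolutionError, match="cyclic"):
            resolve("A", [a, b], context())

    def test_repeat_calls_identical(self):
        registry = erosion_registry()
        ctx = slope_context()
        a_nodes, a_prov = resolve("erosion", registry, ctx)
        b_nodes, b_prov = resolve("erosion", registry, ctx)
        assert a_prov == b_prov
        assert [n.candidate.id for n in a_nodes] == [n.candidate.id for n in b_nodes]

    def test_removing_winner_promotes_runner_up(self):
        rng = np.random.default_rng(72)
        for _ in range(5):
            pool = [candidate(id=f"c{i}", user_rank=float(rng.integers(0, 101)))
                    for i in range(4)]
            ranked = rank_candidates(pool, context())
            reduced = [c for c in pool if c.id != ranked[0][0].id]
            nodes, _ = resolve("precip", reduced, context())
            assert nodes[0].candidate.id == ranked[1][0].id

    def test_provenance_replay_reproduces_tree(self):
        registry = erosion_registry()
        ctx = slope_context()
        _, prov = resolve("erosion", registry, ctx)
        _, replay = resolve("erosion", registry, ctx)
        assert prov == replay


class TestScenario:
    def test_empty_scenario_is_identity(self):
        registry = erosion_registry()
        out = apply_scenario(registry, Scenario("none", {}))
        assert out == registry

    def test_override_wins_resolution(self):
        registry = [candidate(id="base", user_rank=100.0)]
        override = candidate(id="alt", user_rank=0.0)
        new = apply_scenario(registry, Scenario("s", {"precip": override}))
        nodes, _ = resolve("precip", new, context())
        assert nodes[0].candidate.id == "alt"
        # baseline registry untouched
        assert registry == [candidate(id="base", user_rank=100.0)]

    def test_override_propagates_to_requiring_models(self):
        registry = erosion_registry()
        override = candidate(id="new-rain", concept="rainfall",
                             tags=("rainfall",))
        new = apply_scenario(registry, Scenario("s", {"rainfall": override}))
        nodes, _ = resolve("erosion", new, slope_context())
        rain_choices = {c.candidate.id for n in nodes for c in n.children
                        if c.concept == "rainfall"}
        assert rain_choices == {"new-rain"}

    def test_only_downstream_of_override_changes(self):
        registry = erosion_registry()
        override = candidate(id="new-rain", concept="rainfall",
                             tags=("rainfall",))
        new = apply_scenario(registry, Scenario("s", {"rainfall": override}))
        ctx = slope_context()
        _, base_prov = resolve("erosion", registry, ctx)
        _, alt_prov = resolve("erosion", new, ctx)
        base_by_concept = {p["concept"]: p["candidate"] for p in base_prov}
        alt_by_concept = {p["concept"]: p["candidate"] for p in alt_prov}
        assert alt_by_concept.pop("rainfall") == "new-rain"
        base_by_concept.pop("rainfall")
        assert base_by_concept == alt_by_concept

    def test_unknown_concept_rejected(self):
        with pytest.raises(ConfigError):
            apply_scenario(erosion_registry(),
                           Scenario("bad", {"nope": candidate()}))

    def test_layer_path_override_becomes_dataset(self):
        registry = erosion_registry()
        new = apply_scenario(registry,
                             Scenario("s", {"rainfall": "alt_rain.asc"}))
        added = [c for c in new if c.priority == 1]
        assert added[0].kind == "dataset" and added[0].payload == "alt_rain.asc"
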