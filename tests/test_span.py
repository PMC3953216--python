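"""Downslope flow routing, output-map taxonomy and demand sweeps."""

import numpy as np
import pytest

from spanflow import (
    BenefitSpec,
    DomainError,
    GridSpec,
    RasterLayer,
    RouterSpec,
    SpanProblem,
    SweepResult,
    UndefinedRatioError,
    potential_need_ratio,
    route_d8,
    run_span,
    sustainability_sweep,
)

from _oracles import d8_pass_oracle, steepest_descent_directions
from conftest import make_layer, random_d8_problem


def strip_problem(source, sink, use, rivalness="rival",
                  benefit_type="provisioning"):
    """A west-to-east 1xN strip with strictly decreasing elevation."""
    n = len(source)
    spec = GridSpec(1, n, 10.0)
    dem = RasterLayer(spec, np.arange(n, 0, -1, dtype=float)[None, :])
    return SpanProblem(
        RasterLayer(spec, np.asarray([source], float)),
        RasterLayer(spec, np.asarray([sink], float)),
        RasterLayer(spec, np.asarray([use], float)),
        BenefitSpec(benefit_type, rivalness, "water", "m3/yr"),
        RouterSpec("d8_downslope", dem=dem),
    )


class TestRouteD8:
    def test_east_sloping_plane_points_east(self):
        cols = np.arange(5)[::-1].astype(float)
        dem = make_layer(np.tile(cols, (5, 1)))
        direction = route_d8(dem)
        assert np.all(direction[:, :-1] == 0)  # 0 = East
        assert np.all(direction[:, -1] == -1)

    def test_bowl_pit_is_terminal_and_neighbours_point_in(self):
        dem_vals = np.full((3, 3), 5.0)
        dem_vals[1, 1] = 0.0
        direction = route_d8(make_layer(dem_vals))
        assert direction[1, 1] == -1
        assert direction[0, 0] == 1  # SE toward the pit
        assert direction[1, 0] == 0  # E
        assert direction[2, 2] == 5  # NW

    def test_matches_exhaustive_steepest_descent(self):
        rng = np.random.default_rng(21)
        dem = make_layer(rng.random((6, 6)) * 30)
        expected = steepest_descent_directions(dem.values, 10.0, dem.nodata_mask)
        np.testing.assert_array_equal(route_d8(dem), expected)

    def test_graph_acyclic(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            dem = make_layer(rng.random((6, 6)) * 10)
            direction = route_d8(dem)
            # follow successors from every cell; must terminate
            from spanflow.span import _successor_index
            succ = _successor_index(direction, dem.spec)
            for start in range(36):
                c, steps = start, 0
                while succ[c] >= 0:
                    c = succ[c]
                    steps += 1
                    assert steps <= 36, "cycle detected"


class TestRunSpanD8:
    def test_single_path_arithmetic(self):
        outputs = run_span(strip_problem([10, 0, 0], [0, 4, 0], [0, 0, 10]))
        assert outputs.possible_use.values[0, 2] == 10
        assert outputs.actual_use.values[0, 2] == 6
        assert outputs.blocked_use.values[0, 2] == 4
        assert outputs.actual_sink.values[0, 1] == 4

    def test_zero_sink_possible_equals_actual(self):
        rng = np.random.default_rng(30)
        problem = random_d8_problem(rng)
        problem.sink.values[:] = 0.0
        outputs = run_span(problem)
        np.testing.assert_allclose(outputs.possible_use.values,
                                   outputs.actual_use.values)
        np.testing.assert_allclose(outputs.possible_flow.values,
                                   outputs.actual_flow.values)
        assert outputs.blocked_use.total() == 0.0

    @pytest.mark.parametrize("rivalness", ["rival", "non_rival"])
    def test_matches_path_walking_oracle(self, rivalness):
        rng = np.random.default_rng(31)
        for _ in range(20):
            problem = random_d8_problem(rng, rivalness=rivalness)
            outputs = run_span(problem)
            for active, prefix in ((False, "possible"), (True, "actual")):
                flow, use, sink, delivered, exported = d8_pass_oracle(
                    problem, sinks_active=active)
                np.testing.assert_allclose(
                    outputs.as_dict()[f"{prefix}_flow"].values, flow, atol=1e-9)
                np.testing.assert_allclose(
                    outputs.as_dict()[f"{prefix}_use"].values, use, atol=1e-9)
                np.testing.assert_allclose(
                    outputs.as_dict()[f"{prefix}_source"].values, delivered,
                    atol=1e-9)
                if active:
                    np.testing.assert_allclose(
                        outputs.actual_sink.values, sink, atol=1e-9)
                    assert outputs.run_log["exported_actual"] == pytest.approx(
                        exported, abs=1e-9)

    def test_rival_conservation(self):
        rng = np.random.default_rng(32)
        for _ in range(10):
            problem = random_d8_problem(rng)
            outputs = run_span(problem)
            total = (outputs.actual_use.total() + outputs.actual_sink.total()
                     + outputs.run_log["exported_actual"])
            assert total == pytest.approx(outputs.theoretical_source.total(),
                                          rel=1e-9)

    def test_rival_delivery_caps(self):
        rng = np.random.default_rng(33)
        problem = random_d8_problem(rng)
        outputs = run_span(problem)
        assert outputs.actual_use.total() <= min(
            outputs.theoretical_source.total(),
            outputs.theoretical_use.total()) + 1e-9

    def test_possible_dominates_actual(self):
        rng = np.random.default_rng(34)
        for _ in range(5):
            outputs = run_span(random_d8_problem(rng))
            for x in ("use", "flow"):
                assert np.all(outputs.as_dict()[f"possible_{x}"].values
                              >= outputs.as_dict()[f"actual_{x}"].values - 1e-9)

    def test_taxonomy_identities(self):
        rng = np.random.default_rng(35)
        for _ in range(10):
            o = run_span(random_d8_problem(rng))
            np.testing.assert_allclose(
                o.blocked_use.values,
                o.possible_use.values - o.actual_use.values, atol=1e-9)
            np.testing.assert_allclose(
                o.blocked_flow.values,
                o.possible_flow.values - o.actual_flow.values, atol=1e-9)
            np.testing.assert_allclose(
                o.inaccessible_source.values,
                o.theoretical_source.values - o.possible_source.values, atol=1e-9)
            np.testing.assert_allclose(
                o.inaccessible_use.values,
                o.theoretical_use.values - o.possible_use.values, atol=1e-9)
            np.testing.assert_allclose(
                o.inaccessible_sink.values,
                o.theoretical_sink.values - o.actual_sink.values, atol=1e-9)
            # aggregate nonnegativity of the source accounting
            assert o.blocked_source.total() >= -1e-9

    def test_sink_monotonicity_provisioning(self):
        rng = np.random.default_rng(36)
        problem = random_d8_problem(rng)
        base = run_span(problem).actual_use.total()
        problem.sink.values[:] += 2.0
        more = run_span(problem).actual_use.total()
        assert more <= base + 1e-9

    def test_sink_monotonicity_preventive_blocked_use(self):
        rng = np.random.default_rng(37)
        problem = random_d8_problem(rng, benefit_type="preventive")
        base = run_span(problem).blocked_use.total()
        problem.sink.values[:] += 2.0
        more = run_span(problem).blocked_use.total()
        assert more >= base - 1e-9

    def test_deterministic(self):
        rng = np.random.default_rng(38)
        problem = random_d8_problem(rng)
        a = run_span(problem)
        b = run_span(problem)
        for name, layer in a.as_dict().items():
            np.testing.assert_array_equal(layer.values,
                                          b.as_dict()[name].values)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            strip_problem([-1, 0, 0], [0, 0, 0], [0, 0, 1])

    def test_mismatched_grids_rejected(self):
        spec_a = GridSpec(2, 2, 10.0)
        spec_b = GridSpec(2, 2, 20.0)
        with pytest.raises(DomainError):
            SpanProblem(
                RasterLayer(spec_a, np.zeros((2, 2))),
                RasterLayer(spec_b, np.zeros((2, 2))),
                RasterLayer(spec_a, np.zeros((2, 2))),
                BenefitSpec("provisioning", "rival", "water", "m3"),
                RouterSpec("d8_downslope",
                           dem=RasterLayer(spec_a, np.zeros((2, 2)))),
            )


class TestSweep:
    def test_printed_ratios(self):
        # worked sustainability figures: potential/need as integer percent
        assert potential_need_ratio(15443129, 15943889) == 97
        assert potential_need_ratio(304155269, 5958885) == 5104

    def test_saturation_on_unlimited_supply(self):
        # ample source everywhere: delivery equals scaled demand at the top
        problem = strip_problem([1000, 0, 0], [0, 0, 0], [0, 0, 5])
        result = sustainability_sweep(problem, [1.0, 2.0, 10.0])
        assert result.current_need == 5.0
        assert result.max_potential == 50.0
        assert result.ratio == 1000

    def test_multiplier_one_inserted(self):
        problem = strip_problem([10, 0, 0], [0, 0, 0], [0, 0, 5])
        result = sustainability_sweep(problem, [2.0])
        assert result.current_need == 5.0

    def test_zero_need_rejected(self):
        problem = strip_problem([10, 0, 0], [0, 0, 0], [0, 0, 0])
        with pytest.raises(UndefinedRatioError):
            sustainability_sweep(problem, [1.0])

    def test_unsorted_multipliers_rejected(self):
        problem = strip_problem([10, 0, 0], [0, 0, 0], [0, 0, 5])
        with pytest.raises(DomainError):
            sustainability_sweep(problem, [2.0, 1.0])

    def test_sweep_result_validates(self):
        with pytest.raises(DomainError):
            SweepResult(10.0, 5.0, -1)
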