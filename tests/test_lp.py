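"""Weight-tuning linear program: construction, solving, verification.

The small analytic and grid-enumeration oracles here are independent of
the solver path: the analytic instance is solved by hand, and the grid
oracle enumerates the weight simplex at 0.01 resolution.
"""

import numpy as np
import pytest

from bars.lp import LPSpec, build_lp, solve_lp, verify_solution
from bars.sampling import MCConfig, reverse_sample
from bars.weights import TermSchema, WeightVector, l1_norm

S2 = TermSchema(("a", "b"))
S3 = TermSchema(("a", "b", "c"))


def spec2(w0, mono, smooth, **kw):
    w0 = WeightVector(S2, np.asarray(w0, float))
    return LPSpec(
        schema=S2,
        w0=w0,
        monotonic_rows=tuple(mono),
        smoothing_rows=tuple(smooth),
        norm_target=l1_norm(w0),
        **kw,
    )


@pytest.fixture()
def analytic_spec():
    # one binding monotonicity row (forces w_b <= w_a), vacuous smoothing
    return spec2(
        (0.5, 1.5),
        mono=[(np.array([1.0, 1.0]), np.array([2.0, 0.0]))],
        smooth=[(np.array([1.0, 1.0]), np.array([1.1, 1.1]))],
    )


class TestSolve:
    def test_analytic_instance(self, analytic_spec):
        # feasibility forces w_a >= 1 on the simplex w_a + w_b = 2; the L1
        # distance 2 w_a - 1 is minimized at w_a = 1
        res = solve_lp(analytic_spec)
        assert res.status == "optimal"
        np.testing.assert_allclose(res.w_star.values, [1.0, 1.0], atol=1e-8)
        assert res.objective == pytest.approx(1.0, abs=1e-8)

    def test_feasible_anchor_returns_anchor(self):
        # rows already satisfied by w0: zero objective is attainable
        spec = spec2(
            (0.5, 1.5),
            mono=[(np.array([1.0, 1.0]), np.array([2.0, 2.0]))],
            smooth=[(np.array([0.0, 0.0]), np.array([1.0, 1.0]))],
        )
        res = solve_lp(spec)
        assert res.status == "optimal"
        np.testing.assert_allclose(res.w_star.values, [0.5, 1.5], atol=1e-8)
        assert res.objective == pytest.approx(0.0, abs=1e-8)

    def test_contradictory_rows_reported_via_slack(self):
        # w_b <= w_a and w_b >= 2.5 w_a cannot both hold with w_a+w_b = 2
        spec = spec2(
            (1.0, 1.0),
            mono=[
                (np.array([0.0, 1.0]), np.array([1.0, 0.0])),
                (np.array([2.5, 0.0]), np.array([0.0, 1.0])),
            ],
            smooth=[],
        )
        res = solve_lp(spec)
        assert res.status == "optimal_with_slack"
        assert max(res.slack_report) > 1e-6

    def test_norm_is_always_conserved(self, analytic_spec):
        res = solve_lp(analytic_spec)
        assert l1_norm(res.w_star) == pytest.approx(
            analytic_spec.norm_target, abs=1e-8
        )


from _oracles import grid_lp_objective as _grid_objective


class TestGridOracleEquivalence:
    def test_analytic_instance_against_grid(self, analytic_spec):
        res = solve_lp(analytic_spec)
        grid = _grid_objective(analytic_spec)
        assert grid is not None
        assert abs(res.objective - grid) <= 0.02

    def test_random_instances_match_grid(self):
        """On >= 20 random small instances the LP objective agrees with
        exhaustive 0.01-step simplex enumeration within 0.02."""
        rng = np.random.default_rng(2024)
        checked = 0
        attempts = 0
        while checked < 20 and attempts < 200:
            attempts += 1
            k = int(rng.integers(2, 4))
            schema = S2 if k == 2 else S3
            w0 = WeightVector(schema, rng.uniform(0.1, 1.0, k))
            n_rows = int(rng.integers(1, 5))
            rows = [
                (rng.uniform(0, 3, k), rng.uniform(0, 3, k))
                for _ in range(n_rows)
            ]
            spec = LPSpec(
                schema=schema,
                w0=w0,
                monotonic_rows=tuple(rows[:-1]),
                smoothing_rows=(rows[-1],),
                norm_target=l1_norm(w0),
            )
            grid = _grid_objective(spec)
            res = solve_lp(spec)
            if grid is None or res.status != "optimal":
                continue
            assert abs(res.objective - grid) <= 0.02, (
                f"instance {attempts}: lp {res.objective} vs grid {grid}"
            )
            # LP optimizes over the continuum, so it can only do better
            assert res.objective <= grid + 1e-8
            checked += 1
        assert checked >= 20


class TestBuildLP:
    @pytest.fixture()
    def paths(self, helix_native, uniform_w):
        cfg = MCConfig(max_steps=25, max_fail=10)
        return [
            reverse_sample(
                helix_native,
                uniform_w,
                cfg,
                m=6,
                rng=np.random.default_rng(100 + i),
            )
            for i in range(3)
        ]

    def test_row_counting(self, paths, uniform_w):
        max_points = 5
        spec = build_lp(paths, uniform_w, max_points=max_points)
        expected_mono = sum(
            min(len(p.points), max_points) - 1 for p in paths
        )
        assert len(spec.monotonic_rows) == expected_mono
        assert len(spec.smoothing_rows) == len(paths)

    def test_mean_neighbor_vector_is_arithmetic_mean(self, paths, uniform_w):
        spec = build_lp(paths, uniform_w)
        for path, (edge, target) in zip(paths, spec.smoothing_rows):
            manual = np.zeros_like(target)
            for tv in path.neighbor_terms:
                manual = manual + tv.values
            manual /= path.m
            np.testing.assert_allclose(target, manual, atol=1e-12)
            np.testing.assert_array_equal(edge, path.edge.terms.values)

    def test_hardest_variant_uses_highest_energy_neighbor(
        self, paths, uniform_w
    ):
        spec = build_lp(paths, uniform_w, smoothing="hardest")
        for path, (_, target) in zip(paths, spec.smoothing_rows):
            energies = [
                float(tv.values @ uniform_w.values)
                for tv in path.neighbor_terms
            ]
            hardest = path.neighbor_terms[int(np.argmax(energies))].values
            np.testing.assert_array_equal(target, hardest)

    def test_norm_target_is_anchor_norm(self, paths, uniform_w):
        spec = build_lp(paths, uniform_w)
        assert spec.norm_target == pytest.approx(l1_norm(uniform_w))

    def test_empty_path_list_rejected(self, uniform_w):
        with pytest.raises(ValueError):
            build_lp([], uniform_w)


class TestVerify:
    def test_optimal_solution_verifies_clean(self, analytic_spec):
        res = solve_lp(analytic_spec)
        report = verify_solution(res, analytic_spec)
        assert report["max_violation"] <= 1e-8
        assert report["violated_monotonic_rows"] == []

    def test_infeasible_point_reported_with_rows(self, analytic_spec):
        from bars.lp import LPResult

        bad = LPResult(
            w_star=WeightVector(S2, np.array([0.2, 1.8])),
            objective=0.0,
            status="optimal",
            slack_report=(),
        )
        report = verify_solution(bad, analytic_spec)
        assert report["max_monotonic_violation"] > 1e-8
        assert 0 in report["violated_monotonic_rows"]

    def test_norm_row_checked(self, analytic_spec):
        res = solve_lp(analytic_spec)
        report = verify_solution(res, analytic_spec)
        assert report["norm_violation"] <= 1e-8


class TestSerialization:
    def test_spec_json_round_trip(self, tmp_path, analytic_spec):
        f = tmp_path / "spec.json"
        analytic_spec.to_json(f)
        loaded = LPSpec.from_json(f)
        assert loaded.schema == analytic_spec.schema
        np.testing.assert_array_equal(
            loaded.w0.values, analytic_spec.w0.values
        )
        for (a, b), (c, d) in zip(
            loaded.monotonic_rows, analytic_spec.monotonic_rows
        ):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)
        res1 = solve_lp(analytic_spec)
        res2 = solve_lp(loaded)
        np.testing.assert_allclose(
            res1.w_star.values, res2.w_star.values, atol=1e-10
        )

    def test_result_json(self, tmp_path, analytic_spec):
        import json

        res = solve_lp(analytic_spec)
        f = tmp_path / "res.json"
        res.to_json(f)
        doc = json.loads(f.read_text())
        assert doc["status"] == "optimal"
        assert set(doc["w_star"]) == set(S2.names)
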