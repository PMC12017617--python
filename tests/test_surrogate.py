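"""Surrogate optimizer: design, interpolant, proposal, optimization, resume."""

import json

import numpy as np
import pytest

from neuroinflux.influence import ParameterSpec
from neuroinflux.surrogate import (
    CheckpointError,
    fit_rbf_surrogate,
    latin_hypercube,
    propose_candidate,
    resume_optimization,
    surrogate_optimize,
)

SPHERE_SPEC = ParameterSpec(["alpha_x", "alpha_y", "alpha_z"],
                            [-5, -5, -5], [5, 5, 5])


def sphere(theta):
    return float(np.sum(np.asarray(theta) ** 2))


class TestLatinHypercube:
    def test_one_point_per_slab(self):
        spec = ParameterSpec(["alpha_x"], [0.0], [1.0])
        pts = latin_hypercube(4, spec, seed=7).ravel()
        occupied = np.floor(pts * 4).astype(int)
        assert sorted(occupied) == [0, 1, 2, 3]

    def test_degenerate_bound_fixed(self):
        spec = ParameterSpec(["alpha_x", "baseline"], [0.0, 0.3], [1.0, 0.3])
        pts = latin_hypercube(6, spec, seed=0)
        np.testing.assert_array_equal(pts[:, 1], 0.3)
        assert np.all((pts[:, 0] >= 0) & (pts[:, 0] <= 1))

    def test_seeded_determinism(self):
        spec = ParameterSpec(["alpha_x", "alpha_y"], [-2, 0], [2, 5])
        np.testing.assert_array_equal(latin_hypercube(8, spec, seed=3),
                                      latin_hypercube(8, spec, seed=3))


class TestRbfSurrogate:
    def test_interpolates_sample_points(self, rng):
        pts = rng.random((12, 3))
        vals = rng.random(12)
        sur = fit_rbf_surrogate(pts, vals)
        np.testing.assert_allclose(sur(pts), vals, atol=1e-8)

    def test_reproduces_affine_functions(self, rng):
        pts = rng.random((15, 2)) * 4 - 2
        vals = 3.0 + 2.0 * pts[:, 0] - 0.5 * pts[:, 1]
        sur = fit_rbf_surrogate(pts, vals)
        query = rng.random((50, 2)) * 4 - 2
        expected = 3.0 + 2.0 * query[:, 0] - 0.5 * query[:, 1]
        np.testing.assert_allclose(sur(query), expected, atol=1e-6)

    def test_duplicate_points_deduplicated_with_warning(self, rng):
        pts = rng.random((10, 2))
        pts[5] = pts[2]
        vals = rng.random(10)
        with pytest.warns(UserWarning, match="duplicate"):
            sur = fit_rbf_surrogate(pts, vals)
        assert sur(pts[2:3])[0] == pytest.approx(vals[2], abs=1e-8)

    def test_near_duplicate_cluster_stays_finite(self, rng):
        base = rng.random((8, 2))
        cluster = base[0] + rng.normal(0, 1e-9, (5, 2))
        pts = np.vstack([base, cluster])
        vals = rng.random(len(pts))
        sur = fit_rbf_surrogate(pts, vals)
        assert np.all(np.isfinite(sur(rng.random((20, 2)))))

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="dims"):
            fit_rbf_surrogate(rng.random((3, 3)), rng.random(3))


class TestProposeCandidate:
    spec = ParameterSpec(["alpha_x", "alpha_y"], [0.0, 0.0], [1.0, 1.0])

    def _surrogate(self, fn, rng, n=12):
        pts = rng.random((n, 2))
        vals = np.array([fn(p) for p in pts])
        return fit_rbf_surrogate(pts, vals), pts

    def test_pure_exploration_returns_farthest_candidate(self, rng):
        sur, pts = self._surrogate(lambda p: p.sum(), rng)
        cand = propose_candidate(sur, pts, self.spec, explore_weight=0.0,
                                 seed=5)
        # compare against the distances of a reference cloud: the returned
        # point must be at least as far as any evaluated point's neighbour
        d_cand = np.linalg.norm(pts - cand, axis=1).min()
        assert d_cand > 0.05

    def test_pure_exploitation_tracks_surrogate_minimum(self, rng):
        center = np.array([0.6, 0.4])
        sur, pts = self._surrogate(lambda p: np.sum((p - center) ** 2), rng,
                                   n=25)
        cand = propose_candidate(sur, pts, self.spec, explore_weight=1.0,
                                 seed=5)
        assert np.linalg.norm(cand - center) < 0.2

    def test_in_bounds_and_fresh_for_many_seeds(self, rng):
        sur, pts = self._surrogate(lambda p: p.sum(), rng)
        for seed in range(100):
            cand = propose_candidate(sur, pts, self.spec,
                                     explore_weight=0.5, seed=seed)
            assert np.all(cand >= 0.0) and np.all(cand <= 1.0)
            assert np.linalg.norm(pts - cand, axis=1).min() > 0


class TestSurrogateOptimize:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_sphere_minimization(self, seed):
        result = surrogate_optimize(sphere, SPHERE_SPEC, 120, seed=seed)
        assert result.best_cost <= 1e-2
        assert np.all(np.diff(result.incumbent) <= 0)
        assert result.n_evaluations == 120

    def test_degenerate_box_single_evaluation(self):
        spec = ParameterSpec(["alpha_x", "alpha_y"], [0.3, -1.0], [0.3, -1.0])
        result = surrogate_optimize(sphere, spec, 50, seed=0)
        assert result.n_evaluations == 1
        np.testing.assert_array_equal(result.best_theta, [0.3, -1.0])

    def test_never_evaluates_out_of_bounds(self):
        seen = []

        def probe(theta):
            seen.append(np.asarray(theta).copy())
            return sphere(theta)

        surrogate_optimize(probe, SPHERE_SPEC, 60, seed=9)
        pts = np.array(seen)
        assert np.all(pts >= -5) and np.all(pts <= 5)

    def test_separable_quadratic_regression(self):
        spec = ParameterSpec(["alpha_a", "alpha_b", "alpha_c", "alpha_d"],
                             [-3] * 4, [4] * 4)
        weights = np.array([1.0, 2.0, 3.0, 0.5])

        def quad(theta):
            return float(np.sum(weights * (np.asarray(theta) - 0.5) ** 2))

        for seed in (1, 2, 3):
            result = surrogate_optimize(quad, spec, 150, seed=seed)
            assert result.best_cost <= 1e-2

    def test_best_cost_equals_history_minimum(self):
        result = surrogate_optimize(sphere, SPHERE_SPEC, 40, seed=4)
        assert result.best_cost == min(result.history)


class TestResume:
    def test_split_run_reproduces_uninterrupted_history(self, tmp_path):
        cp = tmp_path / "cp.json"
        full = surrogate_optimize(sphere, SPHERE_SPEC, 60, seed=5)
        surrogate_optimize(sphere, SPHERE_SPEC, 30, seed=5, checkpoint_path=cp)
        resumed = resume_optimization(cp, sphere, 30)
        assert len(resumed.records) == len(full.records) == 60
        for a, b in zip(full.records, resumed.records):
            np.testing.assert_array_equal(a.theta, b.theta)
            assert a.cost == b.cost

    def test_spec_mismatch_refused(self, tmp_path):
        cp = tmp_path / "cp.json"
        surrogate_optimize(sphere, SPHERE_SPEC, 20, seed=1, checkpoint_path=cp)
        other = ParameterSpec(["alpha_x", "alpha_y", "alpha_z"],
                              [-1, -1, -1], [1, 1, 1])
        with pytest.raises(CheckpointError, match="different parameter spec"):
            resume_optimization(cp, sphere, 10, spec=other)

    def test_zero_additional_evaluations_is_noop(self, tmp_path):
        cp = tmp_path / "cp.json"
        first = surrogate_optimize(sphere, SPHERE_SPEC, 25, seed=2,
                                   checkpoint_path=cp)
        resumed = resume_optimization(cp, sphere, 0)
        assert resumed.n_evaluations == 25
        assert resumed.best_cost == first.best_cost
        np.testing.assert_array_equal(resumed.best_theta, first.best_theta)

    def test_corrupted_checkpoint_diagnosed(self, tmp_path):
        cp = tmp_path / "cp.json"
        cp.write_text(json.dumps({"format": "bogus"}))
        with pytest.raises(CheckpointError):
            resume_optimization(cp, sphere, 5)

    def test_checkpoint_preserved_when_objective_raises(self, tmp_path):
        cp = tmp_path / "cp.json"
        calls = {"n": 0}

        def flaky(theta):
            calls["n"] += 1
            if calls["n"] > 15:
                raise RuntimeError("objective failure")
            return sphere(theta)

        with pytest.raises(RuntimeError, match="objective failure"):
            surrogate_optimize(flaky, SPHERE_SPEC, 40, seed=3,
                               checkpoint_path=cp)
        resumed = resume_optimization(cp, sphere, 0)
        assert resumed.n_evaluations == 15
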