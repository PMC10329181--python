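"""Forward ToA model, pairwise system assembly and the per-element solve."""

import numpy as np
import pytest
from scipy.optimize import minimize

import pactcal as pc
from pactcal.exceptions import (
    DegenerateGeometryError,
    InsufficientDataError,
    InvalidInputError,
)

from conftest import analytic_toas


class TestPredictToa:
    def test_coincident_points_give_zero(self, c_water):
        assert pc.predict_toa([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], c_water) == 0.0

    def test_hand_computed_division(self):
        c = pc.SoundSpeed(1.4829)
        t = pc.predict_toa([14.829, 0.0, 0.0], [0.0, 0.0, 0.0], c)
        assert t == pytest.approx(10.0, abs=1e-12)

    def test_linear_in_distance(self, c_water):
        t1 = pc.predict_toa([5.0, 0.0, 0.0], [0.0, 0.0, 0.0], c_water)
        t2 = pc.predict_toa([10.0, 0.0, 0.0], [0.0, 0.0, 0.0], c_water)
        assert t2 == pytest.approx(2.0 * t1)

    def test_nonfinite_input_rejected(self, c_water):
        with pytest.raises(InvalidInputError):
            pc.predict_toa([np.nan, 0.0, 0.0], [0.0, 0.0, 0.0], c_water)


class TestAssembleSystem:
    def test_hand_example_row_and_rhs(self):
        # transducer on the x-axis at 10 mm: d1 = 10 from the origin,
        # d2 = 9 from (1, 0, 0); the pair equation must read x = 10
        c = pc.SoundSpeed(1.0)
        grid = pc.PointSourceGrid(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))
        system = pc.assemble_system(grid, np.array([10.0, 9.0]), c)
        assert np.allclose(system.rows, [[1.0, 0.0, 0.0]])
        assert system.rhs[0] == pytest.approx((100 - 81 + 1 - 0) / 2)
        assert system.rhs[0] == pytest.approx(10.0)

    def test_reduces_to_law_of_cosines_with_anchor_at_origin(self, c_water):
        # with r'_1 = 0 the equation is x'_2 . x = (d1^2 - d2^2 + r'_2^2)/2,
        # i.e. d2^2 = d1^2 + r'_2^2 - 2 x'_2 . x, the law of cosines
        rng = np.random.default_rng(0)
        x = np.array([8.0, -4.0, 3.0])
        s2 = rng.normal(size=3)
        grid = pc.PointSourceGrid(np.vstack([[0.0, 0.0, 0.0], s2]))
        d = np.linalg.norm(x - grid.positions, axis=1)
        system = pc.assemble_system(grid, d / c_water.value, c_water)
        lhs = system.rows[0] @ x
        assert lhs == pytest.approx(system.rhs[0], rel=1e-12)
        assert d[1] ** 2 == pytest.approx(
            d[0] ** 2 + s2 @ s2 - 2 * s2 @ x, rel=1e-12
        )

    def test_duplicated_sources_excluded(self, c_water):
        grid = pc.PointSourceGrid(
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        )
        system = pc.assemble_system(grid, np.array([5.0, 5.0, 4.0]), c_water)
        assert len(system) == 2  # the (0, 1) zero row is dropped
        assert not np.any(np.all(system.rows == 0, axis=1))

    def test_masked_sources_dropped_and_too_few_raises(self, c_water, tetra_grid):
        t = np.array([5.0, 5.0, 5.0, 5.0])
        mask = np.array([True, True, False, False])
        system = pc.assemble_system(tetra_grid, t, c_water, mask=mask)
        assert len(system) == 1
        with pytest.raises(InsufficientDataError):
            pc.assemble_system(tetra_grid, t, c_water, mask=np.array([True] * 1 + [False] * 3))


class TestSolvePosition:
    def test_noiseless_round_trip_recovers_position(self, c_water, tetra_grid):
        x = np.array([7.0, -3.0, 2.0])
        t = pc.predict_toa(x, tetra_grid.positions, c_water)
        system = pc.assemble_system(tetra_grid, t, c_water)
        est, residual, cond = pc.solve_position(system)
        assert np.max(np.abs(est - x)) < 1e-9
        assert residual < 1e-9

    def test_coplanar_sources_raise_naming_z(self, c_water):
        grid = pc.PointSourceGrid(
            np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 1.0, 0.0]])
        )
        t = np.full(4, 50.0)
        system = pc.assemble_system(grid, t, c_water)
        with pytest.raises(DegenerateGeometryError, match="z direction"):
            pc.solve_position(system)

    def test_zero_mean_rhs_noise_gives_unbiased_estimate(self, c_water, tetra_grid):
        x = np.array([7.0, -3.0, 2.0])
        t = pc.predict_toa(x, tetra_grid.positions, c_water)
        system = pc.assemble_system(tetra_grid, t, c_water)
        rng = np.random.default_rng(42)
        trials = 10_000
        estimates = np.empty((trials, 3))
        for k in range(trials):
            noisy = pc.PairEquationSet(
                system.rows, system.rhs + rng.normal(0, 0.05, len(system)), system.pair_index
            )
            estimates[k], _, _ = pc.solve_position(noisy)
        bias = estimates.mean(axis=0) - x
        stderr = estimates.std(axis=0, ddof=1) / np.sqrt(trials)
        assert np.all(np.abs(bias) < 4 * stderr + 1e-12)

    def test_oracle_equivalence_normal_equations_and_direct_minimizer(self, c_water, tetra_grid):
        # pseudo-inverse solution == normal-equations solve == numerical
        # minimizer of ||Ax - b||^2 on a noisy instance
        x = np.array([3.0, 5.0, -2.0])
        t = pc.predict_toa(x, tetra_grid.positions, c_water)
        rng = np.random.default_rng(7)
        system = pc.assemble_system(tetra_grid, t + rng.normal(0, 0.01, 4), c_water)
        est, _, _ = pc.solve_position(system)
        A, b = system.rows, system.rhs
        normal = np.linalg.solve(A.T @ A, A.T @ b)
        direct = minimize(
            lambda v: np.sum((A @ v - b) ** 2), x0=np.zeros(3), method="BFGS",
            options={"gtol": 1e-14},
        ).x
        assert np.max(np.abs(est - normal)) < 1e-8
        assert np.max(np.abs(est - direct)) < 1e-6


class TestCalibrateArray:
    def test_noiseless_ring_recovered_to_micrometer(self, c_water, ring_geometry, stage_grid):
        pert = pc.perturb_positions(ring_geometry, 0.375, seed=3)
        toas = analytic_toas(pert.actual_positions, stage_grid, c_water)
        result = pc.calibrate_array(stage_grid, toas, c_water, geometry=ring_geometry)
        assert result.calibrated.all()
        err = np.abs(result.estimated_positions - pert.actual_positions)
        assert err.max() < 1e-6

    def test_anchored_pairs_match_all_pairs(self, c_water, tetra_grid):
        x = np.array([12.0, 4.0, -6.0])
        t = pc.predict_toa(x, tetra_grid.positions, c_water)
        all_sys = pc.assemble_system(tetra_grid, t, c_water, pair_mode="all")
        anch_sys = pc.assemble_system(tetra_grid, t, c_water, pair_mode="anchored")
        assert len(anch_sys) == len(tetra_grid) - 1
        xa, _, _ = pc.solve_position(all_sys)
        xb, _, _ = pc.solve_position(anch_sys)
        assert np.max(np.abs(xa - xb)) < 1e-9

    @pytest.mark.parametrize("shift", [np.array([5.0, -2.0, 11.0])])
    def test_translation_equivariance(self, c_water, tetra_grid, shift):
        x = np.array([9.0, 1.0, 4.0])
        toas = analytic_toas(x[None], tetra_grid, c_water)
        moved = pc.PointSourceGrid(tetra_grid.positions + shift)
        toas_moved = analytic_toas((x + shift)[None], moved, c_water)
        r1 = pc.calibrate_array(tetra_grid, toas, c_water)
        r2 = pc.calibrate_array(moved, toas_moved, c_water)
        assert np.allclose(
            r2.estimated_positions[0], r1.estimated_positions[0] + shift, atol=1e-8
        )

    def test_joint_scaling_of_frame_and_sound_speed(self, c_water, tetra_grid):
        # identical ToAs solved in a frame scaled by alpha with c scaled by
        # alpha yield alpha-scaled estimates: the scale ambiguity the
        # surrogate measurements resolve
        alpha = 1.7
        x = np.array([9.0, 1.0, 4.0])
        toas = analytic_toas(x[None], tetra_grid, c_water)
        scaled_grid = pc.PointSourceGrid(alpha * tetra_grid.positions)
        scaled_c = pc.SoundSpeed(alpha * c_water.value)
        r1 = pc.calibrate_array(tetra_grid, toas, c_water)
        r2 = pc.calibrate_array(scaled_grid, toas, scaled_c)
        assert np.allclose(r2.estimated_positions[0], alpha * r1.estimated_positions[0], atol=1e-8)

    def test_degenerate_transducer_flagged_not_dropped(self, c_water, ring_geometry, stage_grid):
        toas = analytic_toas(ring_geometry.designed_positions, stage_grid, c_water)
        bad = toas.valid.copy()
        bad[1:, 0] = False  # transducer 0 keeps a single valid source
        crippled = pc.ToAMatrix(np.where(bad, toas.times, np.nan), bad)
        result = pc.calibrate_array(stage_grid, crippled, c_water, geometry=ring_geometry)
        assert not result.calibrated[0]
        assert 0 in result.failures
        # designed coordinates retained so downstream code has a full set
        assert np.allclose(result.estimated_positions[0], ring_geometry.designed_positions[0])
        assert result.calibrated[1:].all()

    def test_all_transducers_failing_aborts(self, c_water, stage_grid):
        flat = pc.PointSourceGrid(stage_grid.positions * np.array([1.0, 1.0, 0.0]))
        toas = analytic_toas(np.array([[50.0, 0.0, 10.0]]).repeat(2, axis=0)[:2], flat, c_water)
        with pytest.raises(DegenerateGeometryError):
            pc.calibrate_array(flat, toas, c_water)

    def test_estimator_follows_sklearn_protocol(self, c_water, tetra_grid):
        from sklearn.base import clone

        est = pc.ArrayCalibrator(pair_mode="anchored", condition_limit=1e5)
        params = est.get_params()
        assert params["pair_mode"] == "anchored"
        cloned = clone(est)
        assert cloned.get_params() == params
        x = np.array([4.0, 4.0, 4.0])
        toas = analytic_toas(x[None], tetra_grid, c_water)
        fitted = cloned.fit(tetra_grid, toas, c=c_water)
        assert np.allclose(fitted.positions_[0], x, atol=1e-8)


class TestTypes:
    def test_sound_speed_plausibility_warning(self):
        with pytest.warns(UserWarning):
            pc.SoundSpeed(2.5)

    def test_wavelength_consistency(self, c_water):
        geom = pc.ArrayGeometry.from_positions(np.zeros((1, 3)), center_frequency=2.0)
        assert geom.wavelength(c_water) == pytest.approx(0.75)

    def test_toa_matrix_rejects_invalid_marked_valid(self):
        with pytest.raises(InvalidInputError):
            pc.ToAMatrix(np.array([[-1.0]]), np.array([[True]]))

    def test_grid_requires_two_sources(self):
        with pytest.raises(InsufficientDataError):
            pc.PointSourceGrid(np.zeros((1, 3)))
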