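"""Array builders, perturbation, forward simulator and vessel phantom."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import pactcal as pc
from pactcal.exceptions import InvalidInputError, TruncationError


class TestArrayGeometries:
    def test_ring_radius_and_angular_pitch(self):
        geom = pc.make_array_geometry("ring", radius=100.0, n_elements=512)
        pos = geom.designed_positions
        assert np.allclose(np.linalg.norm(pos, axis=1), 100.0)
        angles = np.unwrap(np.arctan2(pos[:, 1], pos[:, 0]))
        assert np.allclose(np.diff(angles), 2 * np.pi / 512)

    def test_zero_span_arc_rejected(self):
        with pytest.raises(InvalidInputError):
            pc.make_array_geometry("arc", radius=100.0, n_elements=8, angular_span_deg=0.0)

    def test_hemisphere_arcs_with_rotation_counts_and_sphere(self):
        geom = pc.make_array_geometry(
            "hemisphere_arcs", radius=120.0, n_elements=256,
            n_arcs=4, rotation_angles_deg=(0.0, 45.0),
        )
        pos = geom.designed_positions
        assert len(geom) == 2048
        assert np.allclose(np.linalg.norm(pos, axis=1), 120.0)
        assert len(np.unique(np.round(pos, 9), axis=0)) == 2048

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidInputError):
            pc.make_array_geometry("cube", radius=1.0, n_elements=8)


class TestPerturbation:
    def test_zero_shift_is_identity(self, ring_geometry):
        out = pc.perturb_positions(ring_geometry, 0.0, seed=0)
        assert np.array_equal(out.actual_positions, ring_geometry.designed_positions)

    def test_bounded_offsets_in_selected_axes_only(self):
        geom = pc.make_array_geometry("ring", radius=100.0, n_elements=512)
        out = pc.perturb_positions(geom, 0.375, axes=("x", "y"), seed=1)
        offsets = out.actual_positions - geom.designed_positions
        assert np.abs(offsets[:, :2]).max() <= 0.375
        assert np.all(offsets[:, 2] == 0.0)

    def test_offset_statistics_match_uniform_law(self):
        geom = pc.ArrayGeometry.from_positions(np.zeros((10_000, 3)))
        out = pc.perturb_positions(geom, 0.375, axes=("x",), seed=2)
        dx = (out.actual_positions - geom.designed_positions)[:, 0]
        assert abs(dx.mean()) < 0.01
        assert dx.max() > 0.37 and dx.min() < -0.37
        assert dx.std() == pytest.approx(0.375 / np.sqrt(3), rel=0.03)

    def test_deterministic_under_seed(self, ring_geometry):
        a = pc.perturb_positions(ring_geometry, 0.3, seed=9).actual_positions
        b = pc.perturb_positions(ring_geometry, 0.3, seed=9).actual_positions
        assert np.array_equal(a, b)


class TestPulseModel:
    def test_six_db_fractional_bandwidth_within_five_percent(self):
        pulse = pc.PulseModel(2.25, 0.98)
        fs = 80.0
        t = (np.arange(4096) - 2048) / fs
        spec = np.abs(np.fft.rfft(pulse.kernel(t)))
        f = np.fft.rfftfreq(4096, 1 / fs)
        peak = spec.max()
        above = f[spec >= 0.5 * peak]
        measured_fbw = (above.max() - above.min()) / 2.25
        assert measured_fbw == pytest.approx(0.98, rel=0.05)

    def test_n_shape_is_bipolar_and_antisymmetric(self):
        pulse = pc.PulseModel(2.0, 0.8, kind="n_shape_bandpassed")
        t = np.linspace(-1.0, 1.0, 501)
        k = pulse.kernel(t)
        assert np.allclose(k, -k[::-1], atol=1e-12)
        assert k[t < 0][np.argmax(np.abs(k[t < 0]))] > 0  # compression first

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            pc.PulseModel(0.0, 0.8)
        with pytest.raises(InvalidInputError):
            pc.PulseModel(2.0, 2.5)


class TestPointWaveforms:
    def test_peak_convention_places_maximum_at_model_arrival(self, c_water, tetra_grid):
        geom = pc.ArrayGeometry.from_positions(np.array([[40.0, 0.0, 0.0]]))
        waves = pc.simulate_point_waveforms(
            geom, tetra_grid, c_water, sampling_rate=40.0, arrival_reference="peak"
        )
        toas = pc.estimate_toas(waves, min_snr=0.0, reference="peak", refine="spline")
        expected = pc.predict_toa(geom.designed_positions[0], tetra_grid.positions, c_water)
        assert np.allclose(toas.times[:, 0], expected, atol=1e-3)

    def test_onset_convention_delays_peak_by_three_sigmas(self, c_water, tetra_grid):
        geom = pc.ArrayGeometry.from_positions(np.array([[40.0, 0.0, 0.0]]))
        pulse = pc.PulseModel(2.0, 0.8)
        w_on = pc.simulate_point_waveforms(
            geom, tetra_grid, c_water, pulse=pulse, sampling_rate=40.0,
            arrival_reference="onset", time_origin=20.0, duration=15.0,
        )
        w_pk = pc.simulate_point_waveforms(
            geom, tetra_grid, c_water, pulse=pulse, sampling_rate=40.0,
            arrival_reference="peak", time_origin=20.0, duration=15.0,
        )
        t_on = pc.estimate_toas(w_on, min_snr=0.0, reference="peak", refine="spline")
        t_pk = pc.estimate_toas(w_pk, min_snr=0.0, reference="peak", refine="spline")
        assert np.allclose(t_on.times - t_pk.times, pulse.onset_offset, atol=1e-3)

    def test_inverse_distance_amplitude(self, c_water):
        geom = pc.ArrayGeometry.from_positions(np.array([[20.0, 0.0, 0.0], [40.0, 0.0, 0.0]]))
        grid = pc.PointSourceGrid(np.array([[0.0, 0.0, 0.0], [0.0, 5.0, 0.0]]))
        waves = pc.simulate_point_waveforms(geom, grid, c_water, sampling_rate=40.0)
        peaks = waves.samples.max(axis=-1)
        assert peaks[0, 0] == pytest.approx(2.0 * peaks[0, 1], rel=1e-3)

    def test_short_record_raises_truncation_naming_pair(self, c_water, tetra_grid):
        geom = pc.ArrayGeometry.from_positions(np.array([[40.0, 0.0, 0.0]]))
        with pytest.raises(TruncationError, match="source"):
            pc.simulate_point_waveforms(
                geom, tetra_grid, c_water, sampling_rate=40.0,
                time_origin=0.0, duration=5.0,
            )

    def test_noise_deterministic_under_seed(self, c_water, tetra_grid):
        geom = pc.ArrayGeometry.from_positions(np.array([[40.0, 0.0, 0.0]]))
        a = pc.simulate_point_waveforms(geom, tetra_grid, c_water, noise_std=0.05, seed=4)
        b = pc.simulate_point_waveforms(geom, tetra_grid, c_water, noise_std=0.05, seed=4)
        assert np.array_equal(a.samples, b.samples)

    def test_end_to_end_loop_recovers_perturbed_ring(self, c_water, ring_geometry, stage_grid):
        # the full synthetic loop: simulate -> pick -> calibrate, in the
        # mutually consistent peak convention
        pert = pc.perturb_positions(ring_geometry, 0.375, seed=1)
        waves = pc.simulate_point_waveforms(
            pert, stage_grid, c_water, sampling_rate=40.0, arrival_reference="peak"
        )
        toas = pc.ToAPicker(reference="peak", refine="spline", min_snr=0.0).transform(waves)
        result = pc.calibrate_array(stage_grid, toas, c_water, geometry=ring_geometry)
        _, total = pc.position_rmse(pert.actual_positions, result.estimated_positions)
        assert total < 0.02 * ring_geometry.wavelength(c_water)


class TestVesselPhantom:
    def test_zero_branches_gives_empty_phantom(self):
        ph = pc.make_vessel_phantom((32, 32, 1), 0.2, n_branches=0, seed=0)
        assert not np.any(ph.values)

    def test_nonzero_voxels_lie_within_half_width_of_centerlines(self):
        ph, curves = pc.make_vessel_phantom(
            (64, 64, 1), 0.2, n_branches=3, width_range=(0.4, 0.8), seed=3,
            return_centerlines=True,
        )
        support = ph.voxel_centers(ph.values > 0)
        tree = cKDTree(np.vstack([pts for pts, _ in curves]))
        d, _ = tree.query(support)
        assert d.max() <= 0.8 / 2 + 1e-9

    def test_seed_determinism_and_variation(self):
        a = pc.make_vessel_phantom((32, 32, 1), 0.2, seed=5)
        b = pc.make_vessel_phantom((32, 32, 1), 0.2, seed=5)
        c = pc.make_vessel_phantom((32, 32, 1), 0.2, seed=6)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_small_nonsingleton_axis_rejected(self):
        with pytest.raises(InvalidInputError):
            pc.make_vessel_phantom((16, 32, 1), 0.2)


class TestPhantomWaveforms:
    def test_single_voxel_matches_point_simulation(self, c_water):
        geom = pc.make_array_geometry("ring", radius=50.0, n_elements=8)
        loc = np.array([1.0, -2.0, 0.0])
        phantom = pc.Phantom(np.full((1, 1, 1), 2.5), origin=loc, spacing=0.1)
        pulse = pc.PulseModel(2.0, 0.8)
        kwargs = dict(
            c=c_water, pulse=pulse, sampling_rate=20.0,
            time_origin=25.0, duration=20.0, arrival_reference="peak",
        )
        w_ph = pc.simulate_phantom_waveforms(geom, phantom, **kwargs)
        grid = pc.PointSourceGrid(np.vstack([loc, loc + [0.0, 0.0, 2.0]]))
        w_pt = pc.simulate_point_waveforms(geom, grid, **kwargs)
        ref = 2.5 * w_pt.samples[0]  # source 0 of the grid, scaled by the voxel value
        assert np.max(np.abs(w_ph.samples[0] - ref)) <= 1e-6 * np.max(np.abs(ref))

    def test_superposition_linearity(self, c_water):
        geom = pc.make_array_geometry("ring", radius=50.0, n_elements=8)
        rng = np.random.default_rng(0)
        va = np.zeros((32, 32, 1))
        vb = np.zeros((32, 32, 1))
        va[rng.integers(8, 24, 5), rng.integers(8, 24, 5), 0] = 1.0
        vb[rng.integers(8, 24, 5), rng.integers(8, 24, 5), 0] = 0.5
        spacing = 0.2
        kwargs = dict(
            c=c_water, sampling_rate=20.0, time_origin=25.0, duration=20.0,
            arrival_reference="peak",
        )
        wa = pc.simulate_phantom_waveforms(geom, pc.Phantom(va, (-3.1, -3.1, 0.0), spacing), **kwargs)
        wb = pc.simulate_phantom_waveforms(geom, pc.Phantom(vb, (-3.1, -3.1, 0.0), spacing), **kwargs)
        wab = pc.simulate_phantom_waveforms(
            geom, pc.Phantom(va + vb, (-3.1, -3.1, 0.0), spacing), **kwargs
        )
        assert np.allclose(wab.samples, wa.samples + wb.samples, atol=1e-12)
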