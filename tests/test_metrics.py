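"""Covariance-based size/spread, CNR, FWHM and position RMSE."""

import numpy as np
import pytest

import pactcal as pc
from pactcal.exceptions import InvalidInputError, UndefinedMetricError
from pactcal.reconstruction import Volume


def gaussian_volume(sigma=1.0, spacing=0.1, half=4.0, cov=None):
    n = int(2 * half / spacing) + 1
    axis = (np.arange(n) - (n - 1) / 2) * spacing
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    if cov is None:
        cov = sigma**2 * np.eye(3)
    prec = np.linalg.inv(cov)
    quad = np.einsum("...i,ij,...j->...", pts, prec, pts)
    values = np.exp(-0.5 * quad)
    return Volume(values, origin=np.full(3, axis[0]), spacing=spacing)


class TestSizeSpread:
    def test_isotropic_gaussian_matches_closed_form(self):
        # V = exp(-r^2 / 2 sigma^2) with sigma = 1 mm: V^2 is a Gaussian
        # density of covariance (1/2) I, so size = (1/2)^(3/2), spread = sqrt(3/2)
        vol = gaussian_volume(sigma=1.0)
        size, spread, cov = pc.compute_size_spread(vol)
        assert size == pytest.approx(0.5**1.5, rel=0.01)
        assert spread == pytest.approx(np.sqrt(1.5), rel=0.01)
        assert np.allclose(cov, 0.5 * np.eye(3), atol=0.01)

    def test_rotation_invariance_of_size_and_spread(self):
        cov = np.diag([1.0, 0.25, 0.5])
        theta = np.deg2rad(30)
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0.0],
             [np.sin(theta), np.cos(theta), 0.0],
             [0.0, 0.0, 1.0]]
        )
        v1 = gaussian_volume(cov=cov, half=3.5)
        v2 = gaussian_volume(cov=R @ cov @ R.T, half=3.5)
        s1 = pc.compute_size_spread(v1)
        s2 = pc.compute_size_spread(v2)
        assert s2[0] == pytest.approx(s1[0], rel=0.01)
        assert s2[1] == pytest.approx(s1[1], rel=0.01)

    def test_intensity_scale_invariance(self):
        vol = gaussian_volume(sigma=0.7, half=3.0)
        scaled = Volume(37.0 * vol.values, vol.origin, vol.spacing)
        assert pc.compute_size_spread(scaled)[:2] == pytest.approx(
            pc.compute_size_spread(vol)[:2]
        )

    def test_single_voxel_impulse_collapses_to_zero(self):
        values = np.zeros((9, 9, 9))
        values[4, 4, 4] = 3.0
        size, spread, _ = pc.compute_size_spread(Volume(values, np.zeros(3), 0.1))
        assert size == 0.0
        assert spread == 0.0

    def test_all_zero_volume_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pc.compute_size_spread(Volume(np.zeros((4, 4, 4)), np.zeros(3), 0.1))

    def test_spread_bounds_size_by_am_gm(self):
        vol = gaussian_volume(cov=np.diag([0.8, 0.3, 0.1]), half=3.0)
        size, spread, _ = pc.compute_size_spread(vol)
        assert spread**2 >= 3.0 * size ** (2.0 / 3.0) - 1e-9


class TestCnr:
    def test_equal_means_give_zero(self):
        values = np.zeros((10, 10, 1))
        rng = np.random.default_rng(0)
        values[:, :5] = rng.normal(0, 1, (10, 5, 1))
        signal = np.zeros_like(values, bool)
        signal[:, 6:] = True
        background = ~signal
        values[signal] = values[background].mean()
        assert pc.compute_cnr(values, signal, background) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        values = np.zeros((4, 4, 1))
        values[:2] = 10.0
        values[2:] = [[0.0], [2.0]] * 2
        signal = np.zeros_like(values, bool)
        signal[:2] = True
        background = ~signal
        expected = (10.0 - 1.0) / values[background].std()
        assert pc.compute_cnr(values, signal, background) == pytest.approx(expected)

    def test_positive_scale_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(1, 0.5, (8, 8, 1))
        signal = np.zeros_like(values, bool)
        signal[2:4, 2:4] = True
        background = ~signal
        a = pc.compute_cnr(values, signal, background)
        b = pc.compute_cnr(5.0 * values, signal, background)
        assert b == pytest.approx(a)

    def test_invalid_rois_rejected(self):
        values = np.ones((4, 4, 1))
        full = np.ones_like(values, bool)
        with pytest.raises(InvalidInputError):
            pc.compute_cnr(values, full, full)  # overlap
        with pytest.raises(InvalidInputError):
            pc.compute_cnr(values, np.zeros_like(full), ~full)  # empty
        signal = np.zeros_like(full)
        signal[0, 0] = True
        with pytest.raises(UndefinedMetricError):
            pc.compute_cnr(values, signal, ~signal)  # zero background variance


class TestFwhm:
    def test_triangle_profile(self):
        profile = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        assert pc.compute_fwhm(profile, 0.1) == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_profile_two_sqrt_two_ln_two(self):
        x = np.linspace(-5, 5, 201)
        profile = np.exp(-0.5 * x**2)
        fwhm = pc.compute_fwhm(profile, x[1] - x[0])
        assert fwhm == pytest.approx(2.354820045, abs=(x[1] - x[0]) / 2)

    def test_flat_profile_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pc.compute_fwhm(np.ones(32), 0.1)

    def test_profile_never_crossing_on_one_side_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pc.compute_fwhm(np.linspace(0.0, 1.0, 32), 0.1)


class TestPositionRmse:
    def test_identical_inputs_zero(self):
        pos = np.random.default_rng(0).normal(size=(10, 3))
        per_axis, total = pc.position_rmse(pos, pos)
        assert np.allclose(per_axis, 0.0)
        assert total == 0.0

    def test_constant_offset(self):
        pos = np.zeros((5, 3))
        per_axis, total = pc.position_rmse(pos, pos + [0.1, 0.0, 0.0])
        assert np.allclose(per_axis, [0.1, 0.0, 0.0])
        assert total == pytest.approx(0.1)

    def test_uniform_noise_second_moment(self):
        rng = np.random.default_rng(2)
        a = 0.3
        pos = np.zeros((200_000, 3))
        per_axis, _ = pc.position_rmse(pos, rng.uniform(-a, a, pos.shape))
        assert np.allclose(per_axis, a / np.sqrt(3), rtol=0.01)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            pc.position_rmse(np.zeros((3, 3)), np.zeros((4, 3)))


def test_default_rois_surround_an_isolated_peak():
    values = np.zeros((32, 32, 1))
    values[15:18, 15:18] = 1.0
    signal, background = pc.default_rois(values)
    assert signal[16, 16, 0]
    assert not background[16, 16, 0]
    assert background.sum() > 0
    assert not np.any(signal & background)
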