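"""Universal back-projection (UBP) volume reconstruction.

The filtered back-projection term for channel n is

    q_n(t) = 2 p_n(t) - 2 t dp_n/dt,

with t the absolute time since emission.  Each voxel accumulates
``q_n(||r - x_n|| / c + delay_n)`` over channels with solid-angle weights
(uniform by default, matching uniformly spaced elements; a cosine-weighted
mode is available for strongly oblique apertures).  The time derivative
uses central differences (one-sided at the record boundaries) and temporal
sampling is linear-interpolated; both are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SoundSpeed
from .exceptions import CoverageWarning, InvalidInputError
from .toa import WaveformSet

__all__ = ["Volume", "ubp_reconstruct", "solid_angle_weights"]


@dataclass
class Volume:
    """Reconstructed 3D volume with voxel geometry (mm)."""

    values: np.ndarray
    origin: np.ndarray  # center of voxel (0, 0, 0)
    spacing: np.ndarray  # per axis

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidInputError("volume values must be 3D")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("volume values must be finite")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float).ravel(), (3,)).copy()
        if np.any(self.spacing <= 0):
            raise InvalidInputError("spacing must be > 0")

    @property
    def shape(self):
        return self.values.shape

    def voxel_centers(self) -> np.ndarray:
        """(V, 3) array of voxel center coordinates, C-order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.origin + idx * self.spacing

    def argmax_position(self) -> np.ndarray:
        """Coordinates of the voxel with the largest value."""
        idx = np.unravel_index(int(np.argmax(self.values)), self.shape)
        return self.origin + np.asarray(idx) * self.spacing


def ubp_reconstruct(
    waveforms: WaveformSet,
    positions,
    c: SoundSpeed,
    origin,
    shape,
    spacing,
    weights="uniform",
    source_index: int = 0,
    chunk_voxels: int = 200_000,
) -> Volume:
    """Back-project one acquisition of a waveform set onto a voxel grid.

    Parameters
    ----------
    waveforms : WaveformSet
        The records; ``source_index`` selects the acquisition along the
        first axis (an imaging data set has a single one).
    positions : (N, 3) array
        Transducer coordinates (mm) to back-project with - designed for an
        uncalibrated image, estimated for a calibrated one.
    origin, shape, spacing
        Reconstruction region: coordinates (mm) of the first voxel center,
        voxel counts per axis, voxel size (mm, scalar or per axis).
    weights : {"uniform", "cosine"} or (N,) array
        Solid-angle weighting.  "uniform" gives every channel equal
        weight (appropriate when elements sample the aperture uniformly
        in solid angle); an explicit array supplies per-channel solid
        angles, e.g. :func:`solid_angle_weights` for arcs whose elements
        are uniform in polar angle; "cosine" additionally scales each
        contribution by the cosine between the voxel-to-element direction
        and the element's inward normal (taken to point toward the
        coordinate origin).

    Voxels whose arrival time falls outside the record contribute zero and
    trigger a :class:`CoverageWarning`.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    M, N, T = waveforms.shape
    if len(positions) != N:
        raise InvalidInputError(
            f"got {len(positions)} positions for {N} channels"
        )
    channel_w = np.ones(N)
    if isinstance(weights, str):
        if weights not in ("uniform", "cosine"):
            raise InvalidInputError(f"unknown weights mode {weights!r}")
    else:
        channel_w = np.asarray(weights, dtype=float).ravel()
        if len(channel_w) != N or np.any(channel_w < 0):
            raise InvalidInputError("weights array must hold N non-negative values")
        weights = "array"
    p = waveforms.samples[source_index]
    t = waveforms.times
    dt = 1.0 / waveforms.sampling_rate
    dpdt = np.gradient(p, dt, axis=-1)
    q = 2.0 * p - 2.0 * t[None, :] * dpdt
    delays = (
        np.zeros(N) if waveforms.receive_delays is None else waveforms.receive_delays
    )

    shape = tuple(int(n) for n in np.broadcast_to(np.asarray(shape), (3,)))
    vol = Volume(np.zeros(shape), origin, spacing)
    vox = vol.voxel_centers()
    out = np.zeros(len(vox))
    t0, t1 = t[0], t[-1]
    n_outside = 0
    for lo in range(0, len(vox), chunk_voxels):
        block = vox[lo : lo + chunk_voxels]
        acc = np.zeros(len(block))
        for n in range(N):
            diff = block - positions[n]
            dist = np.linalg.norm(diff, axis=1)
            tq = dist / c.value + delays[n]
            outside = (tq < t0) | (tq > t1)
            n_outside += int(outside.sum())
            contrib = channel_w[n] * np.interp(tq, t, q[n], left=0.0, right=0.0)
            if weights == "cosine":
                normal = -positions[n]
                nn = np.linalg.norm(normal)
                if nn > 0 and np.all(dist > 0):
                    cosang = np.abs(diff @ (normal / nn)) / dist
                    contrib = contrib * cosang
            acc += contrib
        out[lo : lo + chunk_voxels] = acc
    if n_outside:
        warnings.warn(
            f"{n_outside} voxel-channel arrival times fell outside the "
            "recorded window and contributed zero",
            CoverageWarning,
            stacklevel=2,
        )
    vol.values = out.reshape(shape)
    return vol


def solid_angle_weights(positions) -> np.ndarray:
    """Relative solid angles for elements on a sphere about the origin.

    Elements laid out uniformly in polar angle (arc arrays swept in
    azimuth) oversample the pole; weighting each channel by sin(theta)
    restores an even solid-angle measure.  Returns weights normalized to
    unit sum.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    r = np.linalg.norm(positions, axis=1)
    if np.any(r == 0):
        raise InvalidInputError("element at the origin has no defined direction")
    w = np.sqrt(np.maximum(1.0 - (positions[:, 2] / r) ** 2, 0.0))
    total = w.sum()
    if total == 0:
        raise InvalidInputError("all elements lie on the polar axis")
    return w / total
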