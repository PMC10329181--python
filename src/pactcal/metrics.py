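"""Image-quality metrics for reconstructed point targets.

The size and spread metrics generalize the power-RMS width of a signal to
3D: the squared reconstructed volume, normalized to unit mass, defines a
probability density over voxel centers whose covariance matrix
``Sigma_V2`` (mm^2) yields

    size   = sqrt(det Sigma_V2)   [mm^3]
    spread = sqrt(tr Sigma_V2)    [mm]

Both are axis-invariant and make no assumption about the polarity or the
shape of the reconstruction (negative lobes are squared, not clipped).
CNR is contrast over background standard deviation with explicit ROI
masks, since ROI-free definitions are ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, UndefinedMetricError
from .reconstruction import Volume

__all__ = [
    "MetricsReport",
    "compute_size_spread",
    "compute_cnr",
    "compute_fwhm",
    "position_rmse",
    "default_rois",
]


@dataclass
class MetricsReport:
    """Bundle of point-target metrics for one reconstruction."""

    cnr: float | None
    size: float  # mm^3
    spread: float  # mm
    covariance: np.ndarray  # 3x3, mm^2
    fwhm: dict | None = None  # profile label -> mm

    def __post_init__(self):
        if self.size < 0 or self.spread < 0:
            raise InvalidInputError("size and spread must be >= 0")


def compute_size_spread(volume: Volume):
    """Covariance-based size (mm^3) and spread (mm) of a volume.

    Returns ``(size, spread, covariance)`` where the covariance is that of
    the density proportional to the squared voxel values over the analyzed
    region.  Raises :class:`UndefinedMetricError` for an all-zero volume.
    """
    w = volume.values.astype(float).ravel() ** 2
    total = w.sum()
    if total <= 0:
        raise UndefinedMetricError("size/spread undefined for an all-zero volume")
    w = w / total
    coords = volume.voxel_centers()
    mean = w @ coords
    centered = coords - mean
    cov = (centered * w[:, None]).T @ centered
    det = max(float(np.linalg.det(cov)), 0.0)
    size = float(np.sqrt(det))
    spread = float(np.sqrt(np.trace(cov)))
    return size, spread, cov


def compute_cnr(values, signal_roi, background_roi) -> float:
    """Contrast-to-noise ratio between two voxel masks.

    ``(mean(signal) - mean(background)) / std(background)``; the masks
    must be non-empty and disjoint, and the background must have nonzero
    variance.
    """
    values = np.asarray(values, dtype=float)
    signal_roi = np.asarray(signal_roi, dtype=bool)
    background_roi = np.asarray(background_roi, dtype=bool)
    if signal_roi.shape != values.shape or background_roi.shape != values.shape:
        raise InvalidInputError("ROI masks must match the value array shape")
    if not signal_roi.any() or not background_roi.any():
        raise InvalidInputError("ROIs must be non-empty")
    if np.any(signal_roi & background_roi):
        raise InvalidInputError("ROIs must be disjoint")
    bg = values[background_roi]
    sd = float(bg.std())
    if sd == 0:
        raise UndefinedMetricError("background has zero variance; CNR undefined")
    return float((values[signal_roi].mean() - bg.mean()) / sd)


def default_rois(values, signal_level: float = 0.5, background_factor: float = 3.0):
    """Heuristic ROI masks for an isolated point target.

    Signal: voxels at or above ``signal_level`` of the maximum.
    Background: voxels outside the signal bounding box scaled by
    ``background_factor`` about its center.
    """
    values = np.asarray(values, dtype=float)
    peak = values.max()
    if peak <= 0:
        raise UndefinedMetricError("cannot derive ROIs from a non-positive image")
    signal = values >= signal_level * peak
    idx = np.argwhere(signal)
    lo, hi = idx.min(axis=0).astype(float), idx.max(axis=0).astype(float)
    center = (lo + hi) / 2.0
    half = np.maximum((hi - lo) / 2.0, 0.5) * background_factor
    grids = np.indices(values.shape)
    inside = np.ones(values.shape, dtype=bool)
    for ax in range(values.ndim):
        inside &= np.abs(grids[ax] - center[ax]) <= half[ax]
    background = ~inside
    if not background.any():
        raise UndefinedMetricError(
            "background ROI is empty; enlarge the region or reduce background_factor"
        )
    return signal, background


def compute_fwhm(profile, spacing: float) -> float:
    """Full width at half maximum of a sampled 1D profile, mm.

    Takes the half-maximum crossings nearest the (unique) peak on each
    side, linearly interpolated between samples.  Raises
    :class:`UndefinedMetricError` when a side never crosses half maximum.
    """
    profile = np.asarray(profile, dtype=float).ravel()
    if spacing <= 0:
        raise InvalidInputError("spacing must be > 0")
    if len(profile) < 3:
        raise InvalidInputError("profile needs at least 3 samples")
    peak_val = profile.max()
    if not np.isfinite(peak_val) or peak_val <= profile.min():
        raise UndefinedMetricError("profile has no peak")
    k = int(np.argmax(profile))
    half = peak_val / 2.0

    def crossing(direction: int) -> float:
        i = k
        while 0 <= i + direction < len(profile):
            j = i + direction
            if profile[j] < half:
                frac = (profile[i] - half) / (profile[i] - profile[j])
                return i + direction * frac
            i = j
        raise UndefinedMetricError(
            "profile never falls below half maximum on one side"
        )

    return float((crossing(+1) - crossing(-1)) * spacing)


def position_rmse(true_positions, estimated_positions):
    """Root-mean-square position error, per axis and Euclidean (mm).

    Returns ``(per_axis, total)`` where ``per_axis`` is a 3-vector of
    coordinate RMSEs and ``total = sqrt(mean ||error||^2)``.
    """
    true_positions = np.atleast_2d(np.asarray(true_positions, dtype=float))
    estimated_positions = np.atleast_2d(np.asarray(estimated_positions, dtype=float))
    if true_positions.shape != estimated_positions.shape:
        raise InvalidInputError("position arrays must have equal shapes")
    err = estimated_positions - true_positions
    per_axis = np.sqrt(np.mean(err**2, axis=0))
    total = float(np.sqrt(np.mean(np.sum(err**2, axis=1))))
    return per_axis, total
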