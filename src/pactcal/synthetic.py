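"""Synthetic PACT data: array geometries, band-limited point-source
waveforms and vessel-like phantoms.

The forward model is a delay-and-sum of band-limited pulse kernels with
1/r spherical spreading: every point emitter contributes
``kernel(t - ||x - x'|| / c) / ||x - x'||`` to a channel's record.  This
preserves exactly the quantity the calibration consumes (arrival times)
at desk scale; it is not a full wave solver (no heterogeneity,
attenuation, dispersion or element apertures), and transducers are
isotropic points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import ArrayGeometry, PointSourceGrid, SoundSpeed
from .exceptions import InvalidInputError, TruncationError
from .toa import WaveformSet

__all__ = [
    "PulseModel",
    "Phantom",
    "make_array_geometry",
    "perturb_positions",
    "simulate_point_waveforms",
    "make_vessel_phantom",
    "simulate_phantom_waveforms",
]

_TWO_SQRT_2LN2 = 2.0 * np.sqrt(2.0 * np.log(2.0))
# kernel evaluation half-width in envelope sigmas; the Gaussian tail beyond
# is ~1e-14 of the peak
_SUPPORT_SIGMAS = 8.0


@dataclass(frozen=True)
class PulseModel:
    """Band-limited transducer impulse response.

    A Gaussian one-way frequency response with center frequency ``f0``
    (MHz) and one-way 6 dB fractional bandwidth ``fbw`` corresponds in
    time to a Gaussian envelope of width

        sigma_t = 1 / (2 pi sigma_f),   sigma_f = (fbw f0 / 2) / sqrt(2 ln 2).

    ``gaussian_modulated`` is a cosine carrier under that envelope (peak
    amplitude 1 at t = 0), convenient for arrival picking.
    ``n_shape_bandpassed`` is a negative-sine carrier, the band-passed
    N-wave a small spherical absorber actually emits (compression before
    rarefaction, p ~ -tau near the center); universal back-projection,
    whose filter is derivative-dominated at imaging depths, reconstructs
    this shape to a positive peak centered on the source, so it is the
    default for imaging simulations.  The pulse onset is defined as 3
    envelope sigmas before the peak.
    """

    center_frequency: float = 2.0  # MHz
    fractional_bandwidth_6dB: float = 0.8
    kind: str = "gaussian_modulated"

    def __post_init__(self):
        if self.center_frequency <= 0:
            raise InvalidInputError("center_frequency must be > 0 MHz")
        if not (0 < self.fractional_bandwidth_6dB < 2):
            raise InvalidInputError("fractional_bandwidth_6dB must be in (0, 2)")
        if self.kind not in ("gaussian_modulated", "n_shape_bandpassed"):
            raise InvalidInputError(f"unknown pulse kind {self.kind!r}")

    @property
    def sigma_f(self) -> float:
        """Spectral envelope standard deviation, MHz."""
        return (self.fractional_bandwidth_6dB * self.center_frequency / 2.0) / _TWO_SQRT_2LN2 * 2.0

    @property
    def sigma_t(self) -> float:
        """Temporal envelope standard deviation, us."""
        return 1.0 / (2.0 * np.pi * self.sigma_f)

    @property
    def onset_offset(self) -> float:
        """Time from pulse onset to peak, us (3 envelope sigmas)."""
        return 3.0 * self.sigma_t

    @property
    def support_halfwidth(self) -> float:
        return _SUPPORT_SIGMAS * self.sigma_t

    def kernel(self, t) -> np.ndarray:
        """Evaluate the pulse at times ``t`` (us) relative to the peak."""
        t = np.asarray(t, dtype=float)
        envelope = np.exp(-0.5 * (t / self.sigma_t) ** 2)
        phase = 2.0 * np.pi * self.center_frequency * t
        carrier = np.cos(phase) if self.kind == "gaussian_modulated" else -np.sin(phase)
        return envelope * carrier


@dataclass
class Phantom:
    """Voxelized initial pressure distribution (arbitrary units)."""

    values: np.ndarray
    origin: np.ndarray  # mm, center of voxel (0, 0, 0)
    spacing: np.ndarray  # mm per axis

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidInputError("phantom values must be a 3D array")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise InvalidInputError("phantom values must be finite and non-negative")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float).ravel(), (3,)).copy()
        if np.any(self.spacing <= 0):
            raise InvalidInputError("spacing must be > 0")

    def voxel_centers(self, mask=None) -> np.ndarray:
        idx = np.argwhere(np.ones_like(self.values, bool) if mask is None else mask)
        return self.origin + idx * self.spacing


def make_array_geometry(
    kind: str,
    radius: float,
    n_elements: int,
    angular_span_deg: float = 90.0,
    n_arcs: int = 4,
    rotation_angles_deg=(0.0,),
    center_frequency: float = 2.0,
    fractional_bandwidth_6dB: float = 0.8,
) -> ArrayGeometry:
    """Construct an idealized transducer array.

    kind = "ring"
        ``n_elements`` uniformly spaced on a circle of ``radius`` in the
        z = 0 plane.
    kind = "arc"
        one vertical arc in the x-z plane spanning ``angular_span_deg`` of
        polar angle from the +z pole, elements at the midpoints of equal
        angular bins (so multi-arc assemblies share no pole element).
    kind = "hemisphere_arcs"
        ``n_arcs`` such arcs uniformly distributed in azimuth; each entry
        of ``rotation_angles_deg`` replicates the whole assembly rotated
        about z, modelling acquisition at several rotation stops as
        virtual element positions.
    """
    if radius <= 0 or n_elements < 1:
        raise InvalidInputError("radius must be > 0 and n_elements >= 1")

    def arc_points(azimuth_deg: float) -> np.ndarray:
        if angular_span_deg <= 0:
            raise InvalidInputError("angular_span_deg must be > 0")
        theta = np.deg2rad(angular_span_deg) * (np.arange(n_elements) + 0.5) / n_elements
        phi = np.deg2rad(azimuth_deg)
        return radius * np.column_stack(
            [
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(theta),
            ]
        )

    if kind == "ring":
        angles = 2.0 * np.pi * np.arange(n_elements) / n_elements
        pos = radius * np.column_stack(
            [np.cos(angles), np.sin(angles), np.zeros(n_elements)]
        )
    elif kind == "arc":
        pos = arc_points(0.0)
    elif kind == "hemisphere_arcs":
        if n_arcs < 1:
            raise InvalidInputError("n_arcs must be >= 1")
        blocks = []
        for rot in rotation_angles_deg:
            for a in range(n_arcs):
                blocks.append(arc_points(360.0 * a / n_arcs + rot))
        pos = np.vstack(blocks)
    else:
        raise InvalidInputError(f"unknown array kind {kind!r}")
    return ArrayGeometry.from_positions(pos, center_frequency, fractional_bandwidth_6dB)


def perturb_positions(
    geometry: ArrayGeometry,
    max_shift: float,
    axes=("x", "y"),
    seed: int | None = None,
) -> ArrayGeometry:
    """Apply independent uniform offsets in [-max_shift, +max_shift] (mm).

    Emulates manufacturing error: the returned geometry keeps the original
    designed positions and stores the perturbed ones as the true/estimated
    coordinates.  Reproducible under a fixed seed.
    """
    if max_shift < 0 or not np.isfinite(max_shift):
        raise InvalidInputError("max_shift must be >= 0")
    axis_idx = {"x": 0, "y": 1, "z": 2}
    cols = [axis_idx[a] for a in axes]
    rng = np.random.default_rng(seed)
    offsets = np.zeros((len(geometry), 3))
    offsets[:, cols] = rng.uniform(-max_shift, max_shift, size=(len(geometry), len(cols)))
    return geometry.with_positions(geometry.designed_positions + offsets, kind="estimated")


def _kernel_centers(t_arr: np.ndarray, pulse: PulseModel, arrival_reference: str) -> np.ndarray:
    """Kernel center times for the chosen arrival convention.

    ``"peak"`` centers the zero-phase wavelet on the geometric arrival
    (the standard band-limited simulation convention, exact for
    reconstruction and peak-referenced picking).  ``"onset"`` delays the
    wavelet so its onset (3 envelope sigmas before the peak) sits at the
    geometric arrival, emulating a causal transducer response: a
    threshold-based first-arrival pick then lands near the true arrival,
    early or late by the threshold bias the real method also incurs.
    """
    if arrival_reference == "peak":
        return t_arr
    if arrival_reference == "onset":
        return t_arr + pulse.onset_offset
    raise InvalidInputError(f"unknown arrival_reference {arrival_reference!r}")


def _auto_window(t_min: float, t_max: float, pulse: PulseModel, sampling_rate: float):
    """Default (time_origin, duration) covering all arrivals plus pulse
    support, with a pre-arrival lead for noise statistics (~20% of the
    record)."""
    h = pulse.support_halfwidth
    span = (t_max - t_min) + 2.0 * h
    lead = 0.25 * span + 4.0 / sampling_rate
    t0 = t_min - h - lead
    duration = (t_max + h) - t0
    return t0, duration


def _accumulate_pulses(out, trace_idx, t_arr, amp, pulse, sampling_rate, time_origin):
    """Add windowed pulse contributions to flat traces ``out`` (K, T)."""
    T = out.shape[1]
    h = pulse.support_halfwidth
    W = int(np.ceil(2.0 * h * sampling_rate)) + 2
    offs = np.arange(W)
    max_chunk = max(1, int(5e7) // W)
    for lo in range(0, len(t_arr), max_chunk):
        sl = slice(lo, lo + max_chunk)
        i0 = np.floor((t_arr[sl] - h - time_origin) * sampling_rate).astype(int)
        idx = i0[:, None] + offs[None, :]
        tt = time_origin + idx / sampling_rate - t_arr[sl, None]
        vals = amp[sl, None] * pulse.kernel(tt)
        inside = (idx >= 0) & (idx < T)
        rows = np.broadcast_to(trace_idx[sl, None], idx.shape)
        np.add.at(out, (rows[inside], idx[inside]), vals[inside])


def _check_duration(time_origin, duration, t_max, pulse, label):
    if time_origin + duration < t_max + pulse.support_halfwidth:
        raise TruncationError(
            f"record of {duration:.3g} us starting at {time_origin:.3g} us "
            f"truncates the arrival at {t_max:.3g} us ({label})"
        )


def simulate_point_waveforms(
    geometry: ArrayGeometry,
    grid: PointSourceGrid,
    c: SoundSpeed,
    pulse: PulseModel | None = None,
    sampling_rate: float = 20.0,
    duration: float | None = None,
    time_origin: float | None = None,
    noise_std: float = 0.0,
    delays=None,
    toa_jitter: float = 0.0,
    arrival_reference: str = "onset",
    seed: int | None = None,
) -> WaveformSet:
    """Forward-simulate point-source records at the array's true positions.

    Each trace is the pulse kernel centered on the predicted arrival time,
    scaled by 1/distance, shifted by the per-channel receive delay and an
    optional Gaussian ToA jitter, plus white noise whose standard deviation
    is ``noise_std`` times the peak absolute amplitude of the noise-free
    set.  ``sampling_rate`` is in MHz, times in us.
    """
    if pulse is None:
        pulse = PulseModel(geometry.center_frequency, geometry.fractional_bandwidth_6dB)
    positions = geometry.actual_positions
    N, M = len(positions), len(grid)
    rng = np.random.default_rng(seed)

    dist = np.linalg.norm(grid.positions[:, None, :] - positions[None, :, :], axis=-1)
    if np.any(dist == 0):
        raise InvalidInputError("a source coincides with a transducer")
    t_arr = dist / c.value
    if delays is not None:
        delays = np.asarray(delays, dtype=float).ravel()
        if len(delays) != N:
            raise InvalidInputError("delays length must equal the channel count")
        t_arr = t_arr + delays[None, :]
    if toa_jitter > 0:
        t_arr = t_arr + rng.normal(0.0, toa_jitter, size=t_arr.shape)
    t_arr = _kernel_centers(t_arr, pulse, arrival_reference)

    m_max, n_max = np.unravel_index(np.argmax(t_arr), t_arr.shape)
    if time_origin is None or duration is None:
        t0_auto, dur_auto = _auto_window(t_arr.min(), t_arr.max(), pulse, sampling_rate)
        time_origin = t0_auto if time_origin is None else time_origin
        duration = dur_auto if duration is None else duration
    _check_duration(
        time_origin, duration, t_arr.max(), pulse,
        f"source {m_max}, transducer {n_max}",
    )

    T = max(16, int(np.ceil(duration * sampling_rate)))
    flat = np.zeros((M * N, T))
    trace_idx = np.arange(M * N)
    _accumulate_pulses(
        flat, trace_idx, t_arr.ravel(), (1.0 / dist).ravel(), pulse, sampling_rate, time_origin
    )
    if noise_std > 0:
        flat += rng.normal(0.0, noise_std * np.abs(flat).max(), size=flat.shape)
    return WaveformSet(
        samples=flat.reshape(M, N, T),
        sampling_rate=sampling_rate,
        time_origin=time_origin,
        receive_delays=delays,
        source_positions=grid.positions.copy(),
    )


def make_vessel_phantom(
    shape,
    spacing,
    n_branches: int = 4,
    width_range=(0.2, 0.5),
    seed: int | None = None,
    origin=None,
    return_centerlines: bool = False,
):
    """Random connected vessel-like phantom of curvilinear branches.

    Branches are quadratic Bezier curves; after the first (which starts
    near the volume center) each new branch sprouts from a random point of
    an existing one, so the structure is connected.  Voxel intensity falls
    off parabolically from each centerline and reaches zero at half the
    branch width.  Axes of size 1 give a planar phantom; non-singleton
    axes must have at least 32 voxels.  Deterministic under a fixed seed.
    With ``return_centerlines`` the sampled centerline polylines and
    widths are returned alongside the phantom.
    """
    shape = tuple(int(n) for n in np.broadcast_to(np.asarray(shape), (3,)))
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float).ravel(), (3,)).copy()
    for n in shape:
        if n != 1 and n < 32:
            raise InvalidInputError("non-singleton phantom axes need >= 32 voxels")
    if n_branches < 0:
        raise InvalidInputError("n_branches must be >= 0")
    wlo, whi = width_range
    if not (0 < wlo <= whi):
        raise InvalidInputError("width_range must satisfy 0 < low <= high")

    extent = np.array(shape) * spacing
    if origin is None:
        origin = -(np.array(shape) - 1) * spacing / 2.0
    origin = np.asarray(origin, dtype=float).reshape(3)
    values = np.zeros(shape)
    if n_branches == 0:
        phantom = Phantom(values, origin, spacing)
        return (phantom, []) if return_centerlines else phantom

    rng = np.random.default_rng(seed)
    flat_axes = np.array(shape) == 1
    half = extent / 2.0
    center = origin + (np.array(shape) - 1) * spacing / 2.0

    def random_dir():
        v = rng.standard_normal(3)
        v[flat_axes] = 0.0
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.array([1.0, 0.0, 0.0])

    idx = np.indices(shape).reshape(3, -1).T
    vox = origin + idx * spacing
    curves = []  # (points, width)
    anchors = [center + 0.1 * half * random_dir()]
    for _ in range(n_branches):
        start = anchors[rng.integers(len(anchors))]
        d0 = random_dir()
        length = rng.uniform(0.4, 0.8) * float(np.min(half[~flat_axes]))
        p0 = start
        p2 = start + length * d0
        p1 = start + 0.5 * length * d0 + 0.35 * length * random_dir()
        s = np.linspace(0.0, 1.0, max(8, int(length / np.min(spacing) * 2)))[:, None]
        pts = (1 - s) ** 2 * p0 + 2 * s * (1 - s) * p1 + s**2 * p2
        pts = np.clip(pts, origin - 0.01 * spacing, origin + (np.array(shape) - 1) * spacing)
        width = rng.uniform(wlo, whi)
        curves.append((pts, width))
        anchors.append(pts[rng.integers(len(pts) // 2, len(pts))])

    for pts, width in curves:
        tree = cKDTree(pts)
        d, _ = tree.query(vox)
        profile = np.clip(1.0 - (2.0 * d / width) ** 2, 0.0, None)
        values = np.maximum(values, profile.reshape(shape))
    phantom = Phantom(values, origin, spacing)
    return (phantom, curves) if return_centerlines else phantom


def simulate_phantom_waveforms(
    geometry: ArrayGeometry,
    phantom: Phantom,
    c: SoundSpeed,
    pulse: PulseModel | None = None,
    sampling_rate: float = 20.0,
    duration: float | None = None,
    time_origin: float | None = None,
    noise_std: float = 0.0,
    arrival_reference: str = "peak",
    seed: int | None = None,
) -> WaveformSet:
    """Forward-simulate an extended source as a superposition of voxels.

    Every nonzero voxel contributes a pulse delayed by its travel time and
    weighted by ``value / distance``; the result is exactly the sum of
    :func:`simulate_point_waveforms` outputs over the voxels (superposition
    holds to machine precision for a shared time window).
    """
    if pulse is None:
        pulse = PulseModel(
            geometry.center_frequency,
            geometry.fractional_bandwidth_6dB,
            kind="n_shape_bandpassed",
        )
    positions = geometry.actual_positions
    N = len(positions)
    mask = phantom.values > 0
    if not np.any(mask):
        raise InvalidInputError("phantom has no nonzero voxels")
    src = phantom.voxel_centers(mask)
    weights = phantom.values[mask]

    dist = np.linalg.norm(src[:, None, :] - positions[None, :, :], axis=-1)
    if np.any(dist == 0):
        raise InvalidInputError("a phantom voxel coincides with a transducer")
    t_arr = _kernel_centers(dist / c.value, pulse, arrival_reference)
    if time_origin is None or duration is None:
        t0_auto, dur_auto = _auto_window(t_arr.min(), t_arr.max(), pulse, sampling_rate)
        time_origin = t0_auto if time_origin is None else time_origin
        duration = dur_auto if duration is None else duration
    v_max, n_max = np.unravel_index(np.argmax(t_arr), t_arr.shape)
    _check_duration(
        time_origin, duration, t_arr.max(), pulse, f"voxel {v_max}, transducer {n_max}"
    )

    T = max(16, int(np.ceil(duration * sampling_rate)))
    flat = np.zeros((N, T))
    trace_idx = np.broadcast_to(np.arange(N)[None, :], t_arr.shape).ravel()
    amp = (weights[:, None] / dist).ravel()
    _accumulate_pulses(flat, trace_idx, t_arr.ravel(), amp, pulse, sampling_rate, time_origin)
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        flat += rng.normal(0.0, noise_std * np.abs(flat).max(), size=flat.shape)
    return WaveformSet(
        samples=flat[np.newaxis],
        sampling_rate=sampling_rate,
        time_origin=time_origin,
    )
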