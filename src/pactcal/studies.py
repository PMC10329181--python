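"""Canonical replication studies at their reference configurations.

These functions bundle the two headline computations of the package with
the configurations they are quoted for, so scripts and tests exercise one
definition:

* predicted per-axis calibration error for the experimental point-source
  arrangement (6 x 6 x 3 grid, 0.254 mm pitch) under the stated error
  budget;
* size and spread of a noiseless simulated point source imaged by the
  2.25 MHz, 98%-bandwidth rotated-arc system and reconstructed with UBP.

Assumed quantities that the system description does not fix are set here
once: the hemispherical radius (120 mm), the nominal element at the arc
midpoint (45 degrees elevation), 16 rotation stops over the 90-degree
sweep (converged: doubling changes the metrics by < 1%), and a 64^3
reconstruction region of 0.1 mm voxels (~lambda0/6) centered on the
source.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import PointSourceGrid, SoundSpeed
from .errors import ErrorBudget, predict_position_covariance
from .exceptions import CoverageWarning
from .metrics import compute_size_spread
from .reconstruction import solid_angle_weights, ubp_reconstruct
from .synthetic import Phantom, make_array_geometry, simulate_phantom_waveforms

__all__ = [
    "EXPERIMENTAL_SOUND_SPEED",
    "ARC_CENTER_FREQUENCY",
    "experimental_grid",
    "nominal_arc_element",
    "predicted_axis_errors",
    "simulated_point_source_metrics",
]

# speed of sound inferred from the measured water temperature, mm/us
EXPERIMENTAL_SOUND_SPEED = 1.4829
ARC_CENTER_FREQUENCY = 2.25  # MHz
ARC_BANDWIDTH = 0.98  # one-way 6 dB fractional
HEMISPHERE_RADIUS = 120.0  # mm (assumed; the system dimension is not fixed here)


def experimental_grid() -> PointSourceGrid:
    """The 6 x 6 x 3 point-source arrangement with 0.254 mm pitch."""
    return PointSourceGrid.regular((6, 6, 3), 0.254, center=True)


def nominal_arc_element(
    distance: float = HEMISPHERE_RADIUS, elevation_deg: float = 45.0,
    azimuth_deg: float = 45.0,
) -> np.ndarray:
    """A representative transducer position on a hemispherical arc.

    Defaults to the geometric midpoint of a pole-to-equator arc at the
    assumed radius.
    """
    el, az = np.deg2rad(elevation_deg), np.deg2rad(azimuth_deg)
    return distance * np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )


def predicted_axis_errors(
    budget: ErrorBudget | None = None,
    c: SoundSpeed | None = None,
    nominal_position=None,
) -> np.ndarray:
    """Per-axis standard error (mm) of one calibrated transducer position
    for the experimental grid under the stated error budget."""
    if budget is None:
        budget = ErrorBudget()  # 0.3 m/s, 0.45 us systematic, per-equation
    if c is None:
        c = SoundSpeed(EXPERIMENTAL_SOUND_SPEED)
    if nominal_position is None:
        nominal_position = nominal_arc_element()
    cov = predict_position_covariance(experimental_grid(), nominal_position, c, budget)
    return np.sqrt(np.diag(cov))


def simulated_point_source_metrics(
    n_voxels: int = 64,
    voxel_mm: float = 0.1,
    n_rotation_stops: int = 16,
    sampling_rate: float = 20.0,
    radius: float = HEMISPHERE_RADIUS,
):
    """Size (mm^3) and spread (mm) of a simulated point source imaged by
    the rotated 256-element arc and reconstructed with UBP.

    Returns ``(size, spread, volume)``.  Deterministic: the simulation is
    noise-free and the reconstruction has no random element.
    """
    c = SoundSpeed(EXPERIMENTAL_SOUND_SPEED)
    geometry = make_array_geometry(
        "hemisphere_arcs",
        radius=radius,
        n_elements=256,
        n_arcs=1,
        rotation_angles_deg=tuple(np.linspace(0.0, 90.0, n_rotation_stops)),
        center_frequency=ARC_CENTER_FREQUENCY,
        fractional_bandwidth_6dB=ARC_BANDWIDTH,
    )
    source = Phantom(np.ones((1, 1, 1)), origin=(0.0, 0.0, 0.0), spacing=voxel_mm)
    waves = simulate_phantom_waveforms(
        geometry, source, c, sampling_rate=sampling_rate, arrival_reference="peak"
    )
    origin = -(n_voxels - 1) * voxel_mm / 2.0 * np.ones(3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CoverageWarning)
        volume = ubp_reconstruct(
            waves,
            geometry.actual_positions,
            c,
            origin,
            (n_voxels, n_voxels, n_voxels),
            voxel_mm,
            weights=solid_angle_weights(geometry.actual_positions),
        )
    size, spread, _ = compute_size_spread(volume)
    return size, spread, volume
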