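"""Geometric types and the pairwise linear calibration model.

A point photoacoustic source at ``x'`` (mm, stage frame) illuminated at
``t = 0`` produces a wavefront that reaches a transducer at ``x`` after

    t = ||x - x'|| / c,

with ``c`` the speed of sound in water (mm/us).  Squaring the relation for
two sources and subtracting cancels the quadratic term ``||x||^2``, leaving
an equation that is *linear* in the transducer coordinates:

    (x'_j - x'_i) . x = (d_i^2 - d_j^2 + r'_j^2 - r'_i^2) / 2,

where ``d = c t`` and ``r'^2 = ||x'||^2``.  Stacking one such equation per
source pair gives ``A x = b``; the transducer position is the least-squares
solution ``x_hat = (A^T A)^{-1} A^T b``, solved independently per element.

Canonical internal units are mm and us (so ``c`` is in mm/us and
frequencies are in MHz); converters accept m/s at the boundary.  This keeps
design-matrix entries of order 1-100 mm and avoids float hazards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import (
    ConditioningWarning,
    DegenerateGeometryError,
    InsufficientDataError,
    InvalidInputError,
    PlausibilityWarning,
)

__all__ = [
    "SoundSpeed",
    "TransducerRecord",
    "ArrayGeometry",
    "PointSourceGrid",
    "ToAMatrix",
    "PairEquationSet",
    "CalibrationResult",
    "ArrayCalibrator",
    "predict_toa",
    "assemble_system",
    "solve_position",
    "calibrate_array",
]

_AXIS_NAMES = ("x", "y", "z")


def _as_point(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise InvalidInputError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} must be finite, got {arr}")
    return arr


@dataclass(frozen=True)
class SoundSpeed:
    """Speed of sound in the coupling medium.

    Parameters
    ----------
    value : float
        Speed in mm/us (1482.9 m/s == 1.4829 mm/us).
    temperature : float, optional
        Water temperature in degrees Celsius the value was inferred from.
    uncertainty : float, optional
        One-sigma uncertainty in mm/us.
    """

    value: float
    temperature: float | None = None
    uncertainty: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.value) or self.value <= 0:
            raise InvalidInputError(f"sound speed must be positive and finite, got {self.value}")
        if not (1.3 < self.value < 1.6):
            warnings.warn(
                f"sound speed {self.value} mm/us is outside the plausible "
                "range for water (1.3-1.6 mm/us)",
                PlausibilityWarning,
                stacklevel=2,
            )

    @classmethod
    def from_m_per_s(cls, value: float, **kwargs) -> "SoundSpeed":
        """Build from a value in m/s (1 m/s = 1e-3 mm/us)."""
        return cls(value * 1e-3, **kwargs)

    @property
    def m_per_s(self) -> float:
        return self.value * 1e3


@dataclass
class TransducerRecord:
    """One array element: designed and (optionally) estimated position, mm."""

    index: int
    designed_position: np.ndarray
    estimated_position: np.ndarray | None = None
    receive_delay: float = 0.0  # us

    def __post_init__(self):
        self.designed_position = _as_point(self.designed_position, "designed_position")
        if self.estimated_position is not None:
            self.estimated_position = _as_point(self.estimated_position, "estimated_position")
        if not np.isfinite(self.receive_delay):
            raise InvalidInputError("receive_delay must be finite")


@dataclass
class ArrayGeometry:
    """An ordered collection of transducers plus acoustic properties.

    ``center_frequency`` is in MHz and ``fractional_bandwidth_6dB`` is the
    one-way 6 dB fractional bandwidth (dimensionless, in (0, 2)).
    """

    transducers: list[TransducerRecord]
    center_frequency: float = 2.0
    fractional_bandwidth_6dB: float = 0.8

    def __post_init__(self):
        if self.center_frequency <= 0:
            raise InvalidInputError("center_frequency must be > 0 MHz")
        if not (0 < self.fractional_bandwidth_6dB < 2):
            raise InvalidInputError("fractional_bandwidth_6dB must be in (0, 2)")
        indices = [t.index for t in self.transducers]
        if len(set(indices)) != len(indices):
            raise InvalidInputError("transducer indices must be unique")

    @classmethod
    def from_positions(
        cls,
        positions,
        center_frequency: float = 2.0,
        fractional_bandwidth_6dB: float = 0.8,
        receive_delays=None,
    ) -> "ArrayGeometry":
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        delays = np.zeros(len(positions)) if receive_delays is None else np.asarray(receive_delays, float)
        records = [
            TransducerRecord(i, p, receive_delay=d)
            for i, (p, d) in enumerate(zip(positions, delays))
        ]
        return cls(records, center_frequency, fractional_bandwidth_6dB)

    def __len__(self) -> int:
        return len(self.transducers)

    @property
    def designed_positions(self) -> np.ndarray:
        return np.array([t.designed_position for t in self.transducers])

    @property
    def actual_positions(self) -> np.ndarray:
        """Estimated/true positions where known, designed otherwise."""
        return np.array(
            [
                t.designed_position if t.estimated_position is None else t.estimated_position
                for t in self.transducers
            ]
        )

    @property
    def receive_delays(self) -> np.ndarray:
        return np.array([t.receive_delay for t in self.transducers])

    def wavelength(self, c: SoundSpeed) -> float:
        """Acoustic wavelength lambda0 = c / f0 in mm."""
        return c.value / self.center_frequency

    def with_positions(self, positions, kind: str = "estimated") -> "ArrayGeometry":
        """Return a copy with per-element positions replaced."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self), 3):
            raise InvalidInputError(f"positions must have shape ({len(self)}, 3)")
        records = []
        for t, p in zip(self.transducers, positions):
            if kind == "estimated":
                records.append(TransducerRecord(t.index, t.designed_position, p, t.receive_delay))
            elif kind == "designed":
                records.append(TransducerRecord(t.index, p, t.estimated_position, t.receive_delay))
            else:
                raise InvalidInputError("kind must be 'estimated' or 'designed'")
        return ArrayGeometry(records, self.center_frequency, self.fractional_bandwidth_6dB)


@dataclass
class PointSourceGrid:
    """M point-source coordinates in the translation-stage frame (mm).

    The stage frame has its origin at the initial position of the stage;
    ``positions[i]`` is the i-th commanded source location.
    """

    positions: np.ndarray
    pitch: float | None = None
    shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InvalidInputError("positions must be an (M, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidInputError("source positions must be finite")
        if len(self.positions) < 2:
            raise InsufficientDataError("a grid needs at least 2 source positions")
        if self.shape is not None and int(np.prod(self.shape)) != len(self.positions):
            raise InvalidInputError("shape inconsistent with the number of positions")

    @classmethod
    def regular(
        cls,
        shape: tuple[int, int, int],
        pitch: float,
        origin=(0.0, 0.0, 0.0),
        center: bool = False,
    ) -> "PointSourceGrid":
        """Regular rectilinear grid of ``shape`` points with the given pitch (mm)."""
        nx, ny, nz = (int(n) for n in shape)
        if min(nx, ny, nz) < 1 or pitch <= 0:
            raise InvalidInputError("grid shape entries must be >= 1 and pitch > 0")
        axes = [np.arange(n) * pitch for n in (nx, ny, nz)]
        if center:
            axes = [a - a.mean() for a in axes]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + np.asarray(origin, float)
        return cls(pos, pitch=pitch, shape=(nx, ny, nz))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ToAMatrix:
    """M x N arrival times in us with a validity mask."""

    times: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.atleast_2d(np.asarray(self.times, dtype=float))
        if self.valid is None:
            self.valid = np.isfinite(self.times) & (self.times > 0)
        else:
            self.valid = np.atleast_2d(np.asarray(self.valid, dtype=bool))
            if self.valid.shape != self.times.shape:
                raise InvalidInputError("valid mask must match the shape of times")
        bad = self.valid & ~(np.isfinite(self.times) & (self.times > 0))
        if np.any(bad):
            raise InvalidInputError("valid entries must be positive and finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.times.shape


@dataclass
class PairEquationSet:
    """The linear system ``A x = b`` for one transducer.

    ``rows`` (Nc x 3, mm) holds source-coordinate differences, ``rhs``
    (Nc, mm^2) the corresponding half squared-range differences, and
    ``pair_index`` (Nc x 2) the source indices of each pair.
    """

    rows: np.ndarray
    rhs: np.ndarray
    pair_index: np.ndarray

    def __post_init__(self):
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        self.rhs = np.asarray(self.rhs, dtype=float).ravel()
        self.pair_index = np.atleast_2d(np.asarray(self.pair_index, dtype=int))
        if not (len(self.rows) == len(self.rhs) == len(self.pair_index)):
            raise InvalidInputError("rows, rhs and pair_index must have equal length")

    def __len__(self) -> int:
        return len(self.rhs)


@dataclass
class CalibrationResult:
    """Per-transducer estimated positions and solve diagnostics."""

    estimated_positions: np.ndarray  # (N, 3) mm
    residual_norm: np.ndarray  # (N,) mm^2
    condition_number: np.ndarray  # (N,)
    calibrated: np.ndarray  # (N,) bool: False where the solve failed
    shift_magnitude: np.ndarray | None = None  # (N,) mm vs designed
    predicted_covariance: np.ndarray | None = None  # (N, 3, 3) mm^2
    failures: dict = field(default_factory=dict)  # index -> message


def predict_toa(transducer_position, source_position, c: SoundSpeed):
    """Forward model: time of arrival ``||x - x'|| / c`` in us.

    Both positions are in mm; broadcasting over leading dimensions is
    supported (e.g. an (M, 3) block of sources against a single transducer).
    """
    x = np.asarray(transducer_position, dtype=float)
    xp = np.asarray(source_position, dtype=float)
    if x.shape[-1] != 3 or xp.shape[-1] != 3:
        raise InvalidInputError("positions must have a trailing dimension of 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(xp))):
        raise InvalidInputError("positions must be finite")
    dist = np.linalg.norm(x - xp, axis=-1)
    return dist / c.value


def assemble_system(
    grid: PointSourceGrid,
    toas_one_transducer,
    c: SoundSpeed,
    mask=None,
    pair_mode: str = "all",
    anchor: int = 0,
) -> PairEquationSet:
    """Build the pairwise linear system for a single transducer.

    For every retained source pair (i, j) the equation is

        (x'_j - x'_i) . x = (d_i^2 - d_j^2 + r'_j^2 - r'_i^2) / 2,

    with ``d = c t``.  Pairs containing an invalid ToA are dropped, as are
    pairs of coincident source positions (zero rows).

    Parameters
    ----------
    pair_mode : {"all", "anchored"}
        "all" enumerates all C(M, 2) pairs; "anchored" uses only the M - 1
        pairs containing the ``anchor`` source, which bounds memory for
        large grids.
    """
    t = np.asarray(toas_one_transducer, dtype=float).ravel()
    if len(t) != len(grid):
        raise InvalidInputError("ToA vector length must match the number of sources")
    if mask is None:
        mask = np.isfinite(t) & (t > 0)
    else:
        mask = np.asarray(mask, dtype=bool).ravel()
    valid_idx = np.flatnonzero(mask)
    if len(valid_idx) < 2:
        raise InsufficientDataError(
            f"need at least 2 valid sources, got {len(valid_idx)}"
        )

    if pair_mode == "all":
        pairs = np.array(list(combinations(valid_idx, 2)), dtype=int)
    elif pair_mode == "anchored":
        if anchor not in valid_idx:
            anchor = int(valid_idx[0])
        others = valid_idx[valid_idx != anchor]
        pairs = np.column_stack([np.full(len(others), anchor), others])
    else:
        raise InvalidInputError(f"unknown pair_mode {pair_mode!r}")

    pos = grid.positions
    d = c.value * t
    r2 = np.einsum("ij,ij->i", pos, pos)
    i, j = pairs[:, 0], pairs[:, 1]
    rows = pos[j] - pos[i]
    rhs = 0.5 * (d[i] ** 2 - d[j] ** 2 + r2[j] - r2[i])

    nonzero = np.einsum("ij,ij->i", rows, rows) > 0
    return PairEquationSet(rows[nonzero], rhs[nonzero], pairs[nonzero])


def solve_position(
    system: PairEquationSet,
    condition_limit: float = 1e6,
    rcond: float = 1e-8,
    warn_condition: float = 1e4,
):
    """Least-squares solve of one transducer's pairwise system.

    Returns ``(position, residual_norm, condition_number)`` where the
    position is the minimum-norm least-squares solution of ``A x = b``.
    Rank is decided by singular values relative to the largest one
    (``rcond``); a numerical rank below 3 or a condition number above
    ``condition_limit`` raises :class:`DegenerateGeometryError` naming the
    deficient direction.
    """
    A, b = system.rows, system.rhs
    if len(A) < 3:
        raise InsufficientDataError(f"need at least 3 equations, got {len(A)}")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > rcond * s[0]))
    cond = np.inf if s[-1] == 0 else float(s[0] / s[-1])
    if rank < 3 or cond > condition_limit:
        # the right singular vector of the smallest singular value spans the
        # unconstrained (or nearly unconstrained) direction
        deficient = Vt[-1]
        axis = _AXIS_NAMES[int(np.argmax(np.abs(deficient)))]
        raise DegenerateGeometryError(
            f"source arrangement does not constrain the {axis} direction "
            f"(singular values {s}, condition number {cond:.3g})"
        )
    if cond > warn_condition:
        warnings.warn(
            f"pairwise system condition number {cond:.3g} exceeds {warn_condition:g}",
            ConditioningWarning,
            stacklevel=2,
        )
    x = Vt.T @ ((U.T @ b) / s)
    residual = float(np.linalg.norm(A @ x - b))
    return x, residual, cond


class ArrayCalibrator(BaseEstimator):
    """Per-transducer position estimator from point-source arrival times.

    Each transducer is calibrated independently by solving the pairwise
    squared-range-difference system with the pseudo-inverse.  The class
    follows the scikit-learn estimator protocol: hyperparameters are set in
    ``__init__``, :meth:`fit` consumes the source grid and the ToA matrix,
    and fitted attributes carry a trailing underscore.

    Parameters
    ----------
    pair_mode : {"all", "anchored"}
        Pair enumeration strategy (all C(M, 2) pairs by default).
    anchor : int
        Reference source index for the anchored mode.
    condition_limit : float
        Condition-number limit above which a transducer is flagged
        degenerate.
    rcond : float
        Relative singular-value threshold for the rank decision.

    Attributes
    ----------
    positions_ : ndarray of shape (N, 3)
        Estimated positions, mm.  Transducers whose solve failed retain
        their designed position (if provided) and are flagged in
        ``calibrated_mask_``.
    residual_norms_ : ndarray of shape (N,)
    condition_numbers_ : ndarray of shape (N,)
    calibrated_mask_ : ndarray of bool, shape (N,)
    shift_magnitudes_ : ndarray of shape (N,) or None
        Euclidean shift vs the designed positions, when those are known.
    failures_ : dict
        Transducer index -> diagnostic message for failed solves.
    """

    def __init__(
        self,
        pair_mode: str = "all",
        anchor: int = 0,
        condition_limit: float = 1e6,
        rcond: float = 1e-8,
    ):
        self.pair_mode = pair_mode
        self.anchor = anchor
        self.condition_limit = condition_limit
        self.rcond = rcond

    def fit(
        self,
        X: PointSourceGrid,
        y: ToAMatrix,
        c: SoundSpeed = None,
        designed_positions=None,
        receive_delays=None,
    ):
        """Estimate all transducer positions.

        Parameters
        ----------
        X : PointSourceGrid
            The M source positions in the stage frame.
        y : ToAMatrix
            M x N arrival times (us), receive delays already subtracted
            unless ``receive_delays`` is given here.
        c : SoundSpeed
            Speed of sound used to convert times to distances.
        designed_positions : ndarray (N, 3), optional
            Fallback coordinates for degenerate transducers and reference
            for ``shift_magnitudes_``.
        receive_delays : ndarray (N,), optional
            Per-channel delays (us) subtracted from the ToAs before solving.
        """
        if c is None:
            raise InvalidInputError("a SoundSpeed is required")
        if not isinstance(y, ToAMatrix):
            y = ToAMatrix(np.asarray(y, dtype=float))
        times = y.times
        mask = y.valid
        M, N = times.shape
        if len(X) != M:
            raise InvalidInputError("grid size and ToA matrix row count differ")
        if receive_delays is not None:
            delays = np.asarray(receive_delays, dtype=float).ravel()
            if len(delays) != N:
                raise InvalidInputError("receive_delays length must match channel count")
            times = times - delays[None, :]
        if designed_positions is not None:
            designed_positions = np.asarray(designed_positions, dtype=float)
            if designed_positions.shape != (N, 3):
                raise InvalidInputError("designed_positions must have shape (N, 3)")

        positions = np.full((N, 3), np.nan)
        residuals = np.full(N, np.nan)
        conds = np.full(N, np.nan)
        ok = np.zeros(N, dtype=bool)
        failures: dict[int, str] = {}
        for n in range(N):
            try:
                system = assemble_system(
                    X, times[:, n], c, mask=mask[:, n],
                    pair_mode=self.pair_mode, anchor=self.anchor,
                )
                pos, res, cond = solve_position(
                    system, condition_limit=self.condition_limit, rcond=self.rcond
                )
            except (InsufficientDataError, DegenerateGeometryError) as exc:
                failures[n] = str(exc)
                if designed_positions is not None:
                    positions[n] = designed_positions[n]
                continue
            positions[n], residuals[n], conds[n] = pos, res, cond
            ok[n] = True
        if not np.any(ok):
            raise DegenerateGeometryError(
                "calibration failed for every transducer: "
                + "; ".join(f"[{k}] {v}" for k, v in list(failures.items())[:3])
            )

        self.positions_ = positions
        self.residual_norms_ = residuals
        self.condition_numbers_ = conds
        self.calibrated_mask_ = ok
        self.failures_ = failures
        if designed_positions is not None:
            self.shift_magnitudes_ = np.linalg.norm(positions - designed_positions, axis=1)
        else:
            self.shift_magnitudes_ = None
        return self

    def to_result(self) -> CalibrationResult:
        return CalibrationResult(
            estimated_positions=self.positions_,
            residual_norm=self.residual_norms_,
            condition_number=self.condition_numbers_,
            calibrated=self.calibrated_mask_,
            shift_magnitude=self.shift_magnitudes_,
            failures=dict(self.failures_),
        )


def calibrate_array(
    grid: PointSourceGrid,
    toas: ToAMatrix,
    c: SoundSpeed,
    geometry: ArrayGeometry | None = None,
    subtract_receive_delays: bool = False,
    **calibrator_params,
) -> CalibrationResult:
    """Calibrate every transducer of an array independently.

    Thin functional wrapper over :class:`ArrayCalibrator`.  When a
    ``geometry`` is supplied, degenerate transducers retain their designed
    coordinates (flagged in ``calibrated``) so downstream reconstruction
    always receives a complete coordinate set, and per-element shift
    magnitudes vs the design are reported.
    """
    designed = geometry.designed_positions if geometry is not None else None
    delays = None
    if subtract_receive_delays:
        if geometry is None:
            raise InvalidInputError("receive-delay subtraction requires a geometry")
        delays = geometry.receive_delays
    est = ArrayCalibrator(**calibrator_params).fit(
        grid, toas, c=c, designed_positions=designed, receive_delays=delays
    )
    return est.to_result()
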