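"""Error propagation for the pairwise calibration and grid design.

The calibration solves ``A x = b`` per transducer with
``b_ij = (d_i^2 - d_j^2 + r'_j^2 - r'_i^2) / 2`` and ``d = c t``.  Errors
in the assumed sound speed (``delta_c``) and in the estimated arrival
times (``delta_t``) perturb the right-hand side,

    delta_b_ij = d_i delta_d_i - d_j delta_d_j,
    delta_d_i  = c delta_t_i + (d_i / c) delta_c,

and propagate into the estimate through the pseudo-inverse
``P = (A^T A)^{-1} A^T`` as ``Cov(x_hat) = P Cov(b) P^T``.

Two ToA error models are supported.  Under ``systematic_per_transducer`` a
single offset is shared by all of one element's measurements (a
threshold-induced pick bias is common to every record of a channel), so
the pair term is ``c delta_t (d_i - d_j)``.  Under
``independent_per_measurement`` each source's pick error is independent.
The ``correlation`` knob selects how those pair-equation errors are
combined: ``"full"`` keeps the exact cross-equation correlations,
``"per_equation"`` treats each equation's error as independent with the
magnitude implied by the model (the classical ordinary-least-squares
standard-error assumption).  The sound-speed term comes from a single
thermometer reading and is always fully coherent.

The per-equation treatment is the default: a strictly common ToA offset
propagates, under full correlations, into a nearly pure radial shift of
magnitude ``c delta_t`` that is insensitive to the grid geometry, whereas
the geometry-dependent uncertainty that grid design can act on (error
shrinking as the pitch or the number of sources grows) is exactly the
per-equation component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import PairEquationSet, PointSourceGrid, SoundSpeed, assemble_system, solve_position
from .exceptions import DegenerateGeometryError, InvalidInputError

__all__ = [
    "ErrorBudget",
    "GridRecommendation",
    "predict_position_covariance",
    "monte_carlo_position_error",
    "design_grid",
]


@dataclass(frozen=True)
class ErrorBudget:
    """Stated error magnitudes for the calibration inputs.

    Parameters
    ----------
    sound_speed_error : float
        One-sigma error of the inferred sound speed, m/s (default 0.3,
        the local sensitivity to a 0.1 degC temperature resolution).
    toa_error : float
        One-sigma ToA estimation error, us (default 0.45, about one period
        at a 2.25 MHz center frequency).
    toa_error_model : {"systematic_per_transducer", "independent_per_measurement"}
    correlation : {"per_equation", "full"}
        Cross-equation correlation treatment for the ToA term (see module
        docstring).
    tolerance : float, optional
        Per-axis position-error tolerance in mm (e.g. lambda0 / 5).
    """

    sound_speed_error: float = 0.3
    toa_error: float = 0.45
    toa_error_model: str = "systematic_per_transducer"
    correlation: str = "per_equation"
    tolerance: float | None = None

    def __post_init__(self):
        if self.sound_speed_error < 0 or self.toa_error < 0:
            raise InvalidInputError("error magnitudes must be >= 0")
        if self.toa_error_model not in (
            "systematic_per_transducer",
            "independent_per_measurement",
        ):
            raise InvalidInputError(f"unknown toa_error_model {self.toa_error_model!r}")
        if self.correlation not in ("per_equation", "full"):
            raise InvalidInputError(f"unknown correlation {self.correlation!r}")
        if self.tolerance is not None and self.tolerance <= 0:
            raise InvalidInputError("tolerance must be > 0")

    @property
    def sound_speed_error_mm_us(self) -> float:
        return self.sound_speed_error * 1e-3


def _system_geometry(grid: PointSourceGrid, position, c: SoundSpeed):
    position = np.asarray(position, dtype=float)
    d = np.linalg.norm(position - grid.positions, axis=1)
    t = d / c.value
    system = assemble_system(grid, t, c)
    # raises DegenerateGeometryError for coplanar/collinear grids
    solve_position(system)
    return system, d


def _pseudo_inverse(system: PairEquationSet) -> np.ndarray:
    return np.linalg.pinv(system.rows)


def predict_position_covariance(
    grid: PointSourceGrid,
    nominal_transducer_position,
    c: SoundSpeed,
    budget: ErrorBudget,
) -> np.ndarray:
    """Analytic 3x3 covariance (mm^2) of one estimated transducer position.

    Linearizes the right-hand-side perturbations induced by the budget's
    sound-speed and ToA errors about the nominal geometry and pushes them
    through the pseudo-inverse of the pairwise design matrix.
    """
    system, d = _system_geometry(grid, nominal_transducer_position, c)
    P = _pseudo_inverse(system)
    i, j = system.pair_index[:, 0], system.pair_index[:, 1]
    sigma_t = budget.toa_error
    sigma_c = budget.sound_speed_error_mm_us

    # sound-speed term: one coherent delta_c, delta_b = (delta_c / c)(d_i^2 - d_j^2)
    g_c = (sigma_c / c.value) * (P @ (d[i] ** 2 - d[j] ** 2))
    cov = np.outer(g_c, g_c)

    if sigma_t > 0:
        if budget.toa_error_model == "systematic_per_transducer":
            w = c.value * sigma_t * (d[i] - d[j])
            if budget.correlation == "full":
                g_t = P @ w
                cov = cov + np.outer(g_t, g_t)
            else:
                cov = cov + (P * w**2) @ P.T
        else:  # independent_per_measurement
            if budget.correlation == "full":
                # G = P B where column k of B holds the sensitivity of every
                # pair equation to source k's ToA error; accumulate A^T B
                # directly to avoid materializing the Nc x M matrix
                AtB = np.zeros((3, len(grid)))
                np.add.at(AtB.T, i, system.rows * d[i, None])
                np.add.at(AtB.T, j, -system.rows * d[j, None])
                AtA_inv = np.linalg.inv(system.rows.T @ system.rows)
                G = c.value * sigma_t * (AtA_inv @ AtB)
                cov = cov + G @ G.T
            else:
                var = (c.value * sigma_t) ** 2 * (d[i] ** 2 + d[j] ** 2)
                cov = cov + (P * var) @ P.T
    return cov


def monte_carlo_position_error(
    grid: PointSourceGrid,
    true_position,
    c: SoundSpeed,
    budget: ErrorBudget,
    trials: int = 10_000,
    seed: int | None = None,
):
    """Empirical per-axis error of the solve under the budget's error model.

    Draws noisy inputs per the configured model (a shared or per-source ToA
    offset plus a shared sound-speed offset; or per-equation noise in the
    ``per_equation`` treatment), re-solves every trial, and returns
    ``(per_axis_std, bias)`` in mm.  The design matrix is noise-free, so
    all trials share one pseudo-inverse and the loop vectorizes over the
    right-hand sides.
    """
    if trials < 100:
        raise InvalidInputError("need at least 100 trials")
    rng = np.random.default_rng(seed)
    true_position = np.asarray(true_position, dtype=float)
    system, d = _system_geometry(grid, true_position, c)
    P = _pseudo_inverse(system)
    i, j = system.pair_index[:, 0], system.pair_index[:, 1]
    t_true = d / c.value
    sigma_t = budget.toa_error
    sigma_c = budget.sound_speed_error_mm_us

    # trials are processed in blocks so the (Nc, trials) perturbation
    # arrays stay within a fixed memory budget
    block = max(1, min(trials, int(2e7) // max(1, len(system))))
    err = np.empty((3, trials))
    done = 0
    while done < trials:
        nb = min(block, trials - done)
        delta_c = rng.normal(0.0, sigma_c, size=nb)  # c assumed minus c true
        if budget.correlation == "per_equation" and sigma_t > 0:
            if budget.toa_error_model == "systematic_per_transducer":
                scale = c.value * sigma_t * (d[i] - d[j])
            else:
                scale = c.value * sigma_t * np.sqrt(d[i] ** 2 + d[j] ** 2)
            db = scale[:, None] * rng.standard_normal((len(system), nb))
            db += np.outer((d[i] ** 2 - d[j] ** 2) / c.value, delta_c)
        else:
            if budget.toa_error_model == "systematic_per_transducer":
                delta_t = rng.normal(0.0, sigma_t, size=(1, nb))
            else:
                delta_t = rng.normal(0.0, sigma_t, size=(len(grid), nb))
            # measured times carry the pick error; the assumed sound speed
            # carries the thermometer error; distances are formed exactly
            # as the calibration would form them
            t_meas = t_true[:, None] + delta_t
            d_meas = (c.value + delta_c)[None, :] * t_meas
            db = 0.5 * (
                (d_meas[i] ** 2 - d_meas[j] ** 2) - (d[i] ** 2 - d[j] ** 2)[:, None]
            )
        err[:, done : done + nb] = P @ db
        done += nb
    return err.std(axis=1, ddof=1), err.mean(axis=1)


@dataclass
class GridRecommendation:
    """Outcome of :func:`design_grid`."""

    shape: tuple[int, int, int]
    pitch: float
    worst_axis_error: np.ndarray  # (3,) mm, worst over sampled positions
    margin: float  # tolerance - max axis error, mm
    satisfied: bool
    evaluated: list = field(default_factory=list)  # (shape, pitch, max_error)


def design_grid(
    tolerance: float,
    candidate_pitches: Sequence[float],
    candidate_shapes: Sequence[tuple[int, int, int]],
    c: SoundSpeed,
    budget: ErrorBudget,
    nominal_positions,
) -> GridRecommendation:
    """Pick the smallest source arrangement meeting a position tolerance.

    Candidates are ranked by point count M = nx*ny*nz (ties broken by
    smaller pitch, i.e. the more compact stage travel); the first whose
    worst-case per-axis predicted error over the sampled nominal transducer
    positions is <= ``tolerance`` wins.  Raises
    :class:`DegenerateGeometryError` annotated with the best achievable
    error when no candidate qualifies.
    """
    if tolerance <= 0:
        raise InvalidInputError("tolerance must be > 0")
    if not len(candidate_pitches) or not len(candidate_shapes):
        raise InvalidInputError("candidate lists must be non-empty")
    nominal_positions = np.atleast_2d(np.asarray(nominal_positions, dtype=float))

    candidates = sorted(
        ((tuple(int(n) for n in s), float(p)) for s in candidate_shapes for p in candidate_pitches),
        key=lambda sp: (int(np.prod(sp[0])), sp[1]),
    )
    evaluated = []
    best = None
    for shape, pitch in candidates:
        grid = PointSourceGrid.regular(shape, pitch, center=True)
        worst = np.zeros(3)
        try:
            for pos in nominal_positions:
                cov = predict_position_covariance(grid, pos, c, budget)
                worst = np.maximum(worst, np.sqrt(np.diag(cov)))
        except DegenerateGeometryError:
            continue
        max_err = float(worst.max())
        evaluated.append((shape, pitch, max_err))
        if best is None or max_err < best[2]:
            best = (shape, pitch, max_err, worst)
        if max_err <= tolerance:
            return GridRecommendation(
                shape=shape,
                pitch=pitch,
                worst_axis_error=worst,
                margin=tolerance - max_err,
                satisfied=True,
                evaluated=evaluated,
            )
    if best is None:
        raise DegenerateGeometryError("every candidate grid was degenerate")
    raise DegenerateGeometryError(
        f"no candidate grid meets the {tolerance} mm tolerance; best achievable "
        f"is {best[2]:.4g} mm with shape {best[0]} at pitch {best[1]} mm"
    )
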