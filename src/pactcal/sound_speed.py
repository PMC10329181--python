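"""Speed of sound in pure water as a function of temperature.

The calibration protocol measures the water temperature and infers ``c``
from a published temperature-speed relation rather than estimating it
jointly with the geometry (which would reintroduce a scale ambiguity).
The default relation is Marczak's fifth-order polynomial for pure water at
atmospheric pressure, valid on 0-95 degC; the Greenspan-Tschiegg polynomial
is available as an alternative.  No salinity or pressure terms: the
intended medium is deionized water at ambient pressure.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .core import SoundSpeed
from .exceptions import InvalidInputError

__all__ = ["speed_from_temperature", "temperature_from_speed", "RELATIONS"]

# polynomial coefficients in m/s per (degC)^k, ascending order
RELATIONS = {
    # W. Marczak, pure water, 0-95 degC
    "marczak": np.array(
        [1.402385e3, 5.038813, -5.799136e-2, 3.287156e-4, -1.398845e-6, 2.787860e-9]
    ),
    # Greenspan & Tschiegg, distilled water, 0-100 degC
    "greenspan": np.array(
        [1.402736e3, 5.03358, -5.79506e-2, 3.31636e-4, -1.45262e-6, 3.0449e-9]
    ),
}

_VALID_RANGE = (0.0, 95.0)
# c(T) increases up to ~74 degC then decreases; restrict the inverse to the
# strictly increasing branch
_INVERSE_RANGE = (0.0, 74.0)


def _poly(relation: str) -> np.ndarray:
    try:
        return RELATIONS[relation]
    except KeyError:
        raise InvalidInputError(
            f"unknown relation {relation!r}; choose from {sorted(RELATIONS)}"
        ) from None


def _eval_m_per_s(temperature: float, coeffs: np.ndarray) -> float:
    return float(np.polynomial.polynomial.polyval(temperature, coeffs))


def _deriv_m_per_s(temperature: float, coeffs: np.ndarray) -> float:
    dc = np.polynomial.polynomial.polyder(coeffs)
    return float(np.polynomial.polynomial.polyval(temperature, dc))


def speed_from_temperature(
    temperature: float,
    temperature_resolution: float = 0.1,
    relation: str = "marczak",
) -> SoundSpeed:
    """Infer the speed of sound in water from its temperature.

    Parameters
    ----------
    temperature : float
        Water temperature in degrees Celsius, within [0, 95].
    temperature_resolution : float
        One-sigma resolution of the thermometer (degC); propagated locally
        as ``delta_c = |dc/dT| * delta_T``.  At 20 degC and 0.1 degC this
        gives ~0.3 m/s.
    relation : {"marczak", "greenspan"}

    Returns
    -------
    SoundSpeed
        With ``value`` in mm/us and ``uncertainty`` filled in.
    """
    temperature = float(temperature)
    if not np.isfinite(temperature) or not (_VALID_RANGE[0] <= temperature <= _VALID_RANGE[1]):
        raise InvalidInputError(
            f"temperature {temperature} degC outside the validity range {_VALID_RANGE}"
        )
    coeffs = _poly(relation)
    c_mps = _eval_m_per_s(temperature, coeffs)
    dc_dT = _deriv_m_per_s(temperature, coeffs)
    uncertainty_mps = abs(dc_dT) * float(temperature_resolution)
    return SoundSpeed(
        value=c_mps * 1e-3,
        temperature=temperature,
        uncertainty=uncertainty_mps * 1e-3,
    )


def temperature_from_speed(c, relation: str = "marczak") -> float:
    """Invert the temperature-speed relation by bisection.

    Accepts a :class:`SoundSpeed` or a value in mm/us and returns the
    temperature (degC) on the strictly increasing branch (0-74 degC).
    """
    value = c.value if isinstance(c, SoundSpeed) else float(c)
    c_mps = value * 1e3
    coeffs = _poly(relation)
    lo, hi = _INVERSE_RANGE
    c_lo, c_hi = _eval_m_per_s(lo, coeffs), _eval_m_per_s(hi, coeffs)
    if not (c_lo <= c_mps <= c_hi):
        raise InvalidInputError(
            f"speed {c_mps:.1f} m/s outside the invertible range "
            f"[{c_lo:.1f}, {c_hi:.1f}] m/s"
        )
    return float(brentq(lambda T: _eval_m_per_s(T, coeffs) - c_mps, lo, hi, xtol=1e-9))
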