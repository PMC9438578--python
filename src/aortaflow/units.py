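"""Unit conversions.

Clinical inputs arrive in mmHg, mm and ml/mmHg; the library works in SI
(Pa, m, m³/Pa) everywhere. Conversions are exact constant multiplications
and round-trip to 1e-12 relative.
"""

from __future__ import annotations

import math

from .errors import ConfigurationError

#: Pascals per millimetre of mercury (conventional value).
MMHG_TO_PA: float = 133.322

#: Standard gravitational acceleration [m/s²].
STANDARD_GRAVITY: float = 9.80665

_PRESSURE_FACTORS = {
    "mmHg": MMHG_TO_PA,
    "kPa": 1000.0,
    "Pa": 1.0,
}


def convert_pressure(value: float, unit: str) -> float:
    """Convert a pressure reading to pascals.

    Parameters
    ----------
    value:
        Pressure magnitude in the given unit. Must be finite.
    unit:
        One of ``"mmHg"``, ``"kPa"``, ``"Pa"``.
    """
    if not math.isfinite(value):
        raise ConfigurationError(f"pressure value must be finite, got {value!r}")
    try:
        factor = _PRESSURE_FACTORS[unit]
    except KeyError:
        known = ", ".join(sorted(_PRESSURE_FACTORS))
        raise ConfigurationError(
            f"unknown pressure unit {unit!r}; expected one of: {known}"
        ) from None
    return value * factor


def mmhg(value: float) -> float:
    """mmHg → Pa shorthand."""
    return value * MMHG_TO_PA


def pa_to_mmhg(value: float) -> float:
    """Pa → mmHg shorthand."""
    return value / MMHG_TO_PA


def mm(value: float) -> float:
    """mm → m shorthand."""
    return value * 1e-3


def ml_per_mmhg(value: float) -> float:
    """Volumetric compliance ml/mmHg → m³/Pa."""
    return value * 1e-6 / MMHG_TO_PA
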