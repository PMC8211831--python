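"""Moist-gas (psychrometric) relations.

Converts temperature / relative-humidity / pressure measurements into water
mole fractions, humid<->dry molar conversion factors, and dew points.  The
saturation vapor pressure of water over liquid uses the Arden Buck (1981)
formulation, which is accurate to a few hundredths of a hPa over the
sensor-plausible range handled here (-20..60 degC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import DomainError, InvalidStateError

__all__ = [
    "PsychroState",
    "saturation_vapor_pressure",
    "water_mole_fraction",
    "humid_to_dry_factor",
    "dew_point",
    "TEMP_MIN_C",
    "TEMP_MAX_C",
]

#: Arden Buck (1981) constants, over liquid water.
BUCK_A_HPA = 6.1121
BUCK_B = 18.678
BUCK_C = 234.5
BUCK_D = 257.14

#: Sensor-plausible temperature range (degC), exclusive bounds.
TEMP_MIN_C = -20.0
TEMP_MAX_C = 60.0


def saturation_vapor_pressure(temp_c: float) -> float:
    """Saturation vapor pressure of water over liquid, in hPa.

    Arden Buck (1981):  es(T) = 6.1121 * exp((18.678 - T/234.5) * T / (257.14 + T))

    Strictly increasing on the supported range.

    Parameters
    ----------
    temp_c : float
        Gas temperature in degrees Celsius, -20 < temp_c < 60.
    """
    if not TEMP_MIN_C < temp_c < TEMP_MAX_C:
        raise DomainError(
            f"temperature {temp_c} degC outside supported range "
            f"({TEMP_MIN_C}, {TEMP_MAX_C})"
        )
    return BUCK_A_HPA * math.exp((BUCK_B - temp_c / BUCK_C) * temp_c / (BUCK_D + temp_c))


@dataclass(frozen=True)
class PsychroState:
    """Temperature, relative humidity and total pressure of a gas sample.

    Attributes
    ----------
    temp_c : float
        Gas temperature in degC; must lie in (-20, 60).
    rh : float
        Relative humidity as a fraction in [0, 1].  Table-style inputs in
        percent are converted at the I/O boundary, not here.
    pressure_hpa : float
        Total pressure in hPa; must be positive.
    """

    temp_c: float
    rh: float
    pressure_hpa: float

    def __post_init__(self) -> None:
        if not TEMP_MIN_C < self.temp_c < TEMP_MAX_C:
            raise DomainError(f"temp_c {self.temp_c} outside ({TEMP_MIN_C}, {TEMP_MAX_C})")
        if not 0.0 <= self.rh <= 1.0:
            raise DomainError(f"rh {self.rh} must be a fraction in [0, 1]")
        if not self.pressure_hpa > 0:
            raise DomainError(f"pressure_hpa {self.pressure_hpa} must be positive")

    @classmethod
    def dry(cls, temp_c: float = 20.0, pressure_hpa: float = 1013.25) -> "PsychroState":
        """A zero-humidity state (identity for all moist-gas conversions)."""
        return cls(temp_c=temp_c, rh=0.0, pressure_hpa=pressure_hpa)

    @property
    def is_dry(self) -> bool:
        return self.rh == 0.0


def water_mole_fraction(state: PsychroState) -> float:
    """Mole fraction of water vapor in the sample: rh * es(T) / P.

    Returns a fraction in [0, 1]; zero iff rh = 0, and 1.0 only in the
    pure-saturated-steam limit (rh = 1 with P = es(T)).  A vapor partial
    pressure exceeding the total pressure is physically impossible and
    raises :class:`InvalidStateError`.
    """
    p_water = state.rh * saturation_vapor_pressure(state.temp_c)
    if p_water > state.pressure_hpa:
        raise InvalidStateError(
            f"water partial pressure {p_water:.4f} hPa exceeds total "
            f"pressure {state.pressure_hpa:.4f} hPa"
        )
    return p_water / state.pressure_hpa


def humid_to_dry_factor(state: PsychroState) -> float:
    """Molar conversion factor from humid to dry gas: 1 / (1 - x_water).

    Always >= 1; equals 1 iff the gas is dry.
    """
    x_w = water_mole_fraction(state)
    if x_w >= 1.0:
        raise InvalidStateError("pure water vapor has no dry-gas equivalent")
    return 1.0 / (1.0 - x_w)


def dew_point(state: PsychroState) -> float:
    """Dew point: the temperature at which es(Td) = rh * es(T).

    Solved by root bracketing on the Buck formula.  Td <= T with equality
    iff rh = 1.  Undefined for perfectly dry gas.
    """
    if state.rh == 0.0:
        raise DomainError("dew point undefined for rh = 0")
    if state.rh == 1.0:
        return state.temp_c
    target = state.rh * saturation_vapor_pressure(state.temp_c)
    lo = TEMP_MIN_C + 1e-9
    if target <= saturation_vapor_pressure(lo):
        raise DomainError("dew point below supported temperature range")
    return brentq(
        lambda t: saturation_vapor_pressure(t) - target,
        lo,
        state.temp_c,
        xtol=1e-10,
    )
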