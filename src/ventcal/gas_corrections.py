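"""Corrections applied to raw gas-sensor readings.

Four corrections, applied in this order by :func:`correct_reading`:

1. pressure standardization — sensors calibrated at ambient pressure read
   partial pressure, so a reading taken in-circuit (10-15 mmHg above
   ambient) is rescaled by p_calib / p_circuit;
2. CO2/O2 cross-sensitivity — the CO2 sensor under-reads linearly with the
   O2 level: CO2 = measured_CO2 / (1 - 0.00072 * measured_O2), operands in
   percent, using the already pressure-standardized O2;
3. wet-to-dry conversion — fractions of a humid sample are divided by
   (1 - water mole fraction);
4. pre/post FIO2 drift — linear interpolation between the dry FIO2 records
   bracketing the expired-gas measurement window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import DomainError, InconsistentInputsError
from .psychrometry import PsychroState, water_mole_fraction

__all__ = [
    "GasReading",
    "correct_co2_cross_sensitivity",
    "inverse_co2_cross_sensitivity",
    "standardize_pressure",
    "wet_to_dry_fraction",
    "interpolate_fio2",
    "average_window",
    "correct_reading",
    "read_gas_timeseries",
    "MMHG_TO_HPA",
    "CO2_O2_COEFF",
]

#: Linear CO2-sensor cross-sensitivity coefficient per percent O2.
CO2_O2_COEFF = 0.00072

#: Exact-enough conversion used at parse time; all internal pressures in hPa.
MMHG_TO_HPA = 1.333224


@dataclass(frozen=True)
class GasReading:
    """One gas-concentration record with its pressure and humidity context.

    ``psychro=None`` marks a dry sample (calibration gases, dried FIO2 line).
    """

    o2_frac: float
    co2_frac: float
    p_calib_hpa: float
    p_circuit_hpa: float
    psychro: Optional[PsychroState] = None
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.o2_frac <= 1.0:
            raise DomainError(f"o2_frac {self.o2_frac} outside [0, 1]")
        if not 0.0 <= self.co2_frac <= 1.0:
            raise DomainError(f"co2_frac {self.co2_frac} outside [0, 1]")
        if self.o2_frac + self.co2_frac > 1.0 + 1e-12:
            raise DomainError("o2_frac + co2_frac exceeds 1")
        if self.p_calib_hpa <= 0 or self.p_circuit_hpa <= 0:
            raise DomainError("pressures must be positive")


def correct_co2_cross_sensitivity(co2_measured_pct: float, o2_measured_pct: float) -> float:
    """Undo the CO2 sensor's linear O2 cross-sensitivity (operands in percent).

    CO2 = measured_CO2 / (1 - 0.00072 * measured_O2); the corrected value is
    >= the measured one, with equality iff O2 = 0.
    """
    if not 0.0 <= o2_measured_pct <= 100.0:
        raise DomainError(f"o2_measured_pct {o2_measured_pct} outside [0, 100]")
    if not 0.0 <= co2_measured_pct <= 20.0:
        raise DomainError(f"co2_measured_pct {co2_measured_pct} outside sensor range [0, 20]")
    return co2_measured_pct / (1.0 - CO2_O2_COEFF * o2_measured_pct)


def inverse_co2_cross_sensitivity(co2_true_pct: float, o2_measured_pct: float) -> float:
    """Forward sensor distortion: what the CO2 sensor would read.

    Exact algebraic inverse of :func:`correct_co2_cross_sensitivity`; used by
    the simulator to fabricate raw readings.
    """
    if not 0.0 <= o2_measured_pct <= 100.0:
        raise DomainError(f"o2_measured_pct {o2_measured_pct} outside [0, 100]")
    return co2_true_pct * (1.0 - CO2_O2_COEFF * o2_measured_pct)


def standardize_pressure(frac_read: float, p_calib_hpa: float, p_circuit_hpa: float) -> float:
    """Rescale a partial-pressure-type reading to the in-circuit pressure.

    Returns frac_read * p_calib / p_circuit; identity when the pressures are
    equal.  In-circuit pressure above calibration pressure lowers the
    reading.
    """
    if p_calib_hpa <= 0 or p_circuit_hpa <= 0:
        raise DomainError("pressures must be positive")
    return frac_read * p_calib_hpa / p_circuit_hpa


def wet_to_dry_fraction(frac_wet: float, psychro: Optional[PsychroState]) -> float:
    """Convert a fraction of a humid sample to the dry-gas basis.

    frac_dry = frac_wet / (1 - x_water) >= frac_wet.  ``psychro=None`` (or a
    dry state) is the identity.
    """
    if psychro is None or psychro.is_dry:
        return frac_wet
    frac_dry = frac_wet / (1.0 - water_mole_fraction(psychro))
    if frac_dry > 1.0 + 1e-12:
        raise InconsistentInputsError(
            f"dry fraction {frac_dry:.6f} exceeds 1; humidity inconsistent with reading"
        )
    return frac_dry


def interpolate_fio2(pre_value: float, post_value: float, t_frac: float) -> float:
    """Linear drift interpolation between pre- and post-measurement dry FIO2."""
    if not 0.0 <= t_frac <= 1.0:
        raise DomainError(f"t_frac {t_frac} outside [0, 1]")
    return pre_value + (post_value - pre_value) * t_frac


def average_window(readings: Sequence[GasReading], window_s: float = 60.0) -> GasReading:
    """Arithmetic mean of the readings whose timestamps fall in the window.

    The window starts at the first reading's timestamp.  Pressures are
    averaged alongside the fractions; the humidity context of the first
    reading is carried over (it is slowly varying relative to 60 s).
    """
    if not readings:
        raise DomainError("cannot average an empty window")
    t0 = readings[0].timestamp_s
    inside = [r for r in readings if t0 <= r.timestamp_s <= t0 + window_s]
    if not inside:
        raise DomainError("no readings within the averaging window")
    n = len(inside)
    return GasReading(
        o2_frac=sum(r.o2_frac for r in inside) / n,
        co2_frac=sum(r.co2_frac for r in inside) / n,
        p_calib_hpa=sum(r.p_calib_hpa for r in inside) / n,
        p_circuit_hpa=sum(r.p_circuit_hpa for r in inside) / n,
        psychro=inside[0].psychro,
        timestamp_s=sum(r.timestamp_s for r in inside) / n,
    )


def correct_reading(reading: GasReading) -> tuple[float, float]:
    """Run the full correction chain on one reading.

    Order: pressure standardization, then the CO2 cross-sensitivity fix
    using the standardized O2, then wet-to-dry conversion of both fractions.
    Returns ``(o2_dry_frac, co2_dry_frac)``.
    """
    o2_std = standardize_pressure(reading.o2_frac, reading.p_calib_hpa, reading.p_circuit_hpa)
    co2_std = standardize_pressure(reading.co2_frac, reading.p_calib_hpa, reading.p_circuit_hpa)
    co2_corr = correct_co2_cross_sensitivity(co2_std * 100.0, o2_std * 100.0) / 100.0
    o2_dry = wet_to_dry_fraction(o2_std, reading.psychro)
    co2_dry = wet_to_dry_fraction(co2_corr, reading.psychro)
    return o2_dry, co2_dry


def read_gas_timeseries(path: str | Path) -> list[GasReading]:
    """Read a delimited time series of raw gas readings.

    Expected columns: ``t_s, o2_pct, co2_pct, p_circuit_mmhg_gauge,
    p_ambient_hpa, temp_c, rh_pct``.  Gauge circuit pressure (mmHg) is added
    to the ambient pressure at parse time; the sensors are taken to have
    been calibrated at ambient pressure.
    """
    df = pd.read_csv(path)
    required = {"t_s", "o2_pct", "co2_pct", "p_circuit_mmhg_gauge", "p_ambient_hpa", "temp_c", "rh_pct"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"gas time series missing columns: {sorted(missing)}")
    readings = []
    for row in df.itertuples(index=False):
        rh = row.rh_pct / 100.0
        psychro = None
        if rh > 0:
            psychro = PsychroState(
                temp_c=row.temp_c,
                rh=rh,
                pressure_hpa=row.p_ambient_hpa + row.p_circuit_mmhg_gauge * MMHG_TO_HPA,
            )
        readings.append(
            GasReading(
                o2_frac=row.o2_pct / 100.0,
                co2_frac=row.co2_pct / 100.0,
                p_calib_hpa=row.p_ambient_hpa,
                p_circuit_hpa=row.p_ambient_hpa + row.p_circuit_mmhg_gauge * MMHG_TO_HPA,
                psychro=psychro,
                timestamp_s=row.t_s,
            )
        )
    return readings
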