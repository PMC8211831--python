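"""Metabolic rates from corrected gas measurements.

With the measured molar inhalation/exhalation ratio R = VI/VE and dry gas
fractions,

    VO2 = (R * FIO2 - FEO2) * VE
    VCO2 = VE * FECO2 - VI * FICO2      (FICO2 = 0 for CO2-free inspirate)
    RQ  = VCO2 / VO2

with VE the dry expired minute volume at STPD (273.15 K, 1013.25 hPa, dry).
The Haldane transformation, VI/VE = (1 - FEO2 - FECO2)/(1 - FIO2), is
provided as the conventional nitrogen-conservation alternative to the
directly measured R; it is singular at FIO2 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import (
    DomainError,
    InconsistentInputsError,
    NonPositiveUptakeError,
    PipelineStageError,
)
from .gas_corrections import GasReading, correct_reading
from .molar_ratio import BagTiming, dry_ratio, ratio_from_timing
from .psychrometry import PsychroState, water_mole_fraction

__all__ = [
    "VentilationSetting",
    "MetabolicResult",
    "vo2",
    "vco2",
    "rq",
    "haldane_ratio",
    "ve_to_stpd",
    "per_kg",
    "full_pipeline",
    "STPD_PRESSURE_HPA",
    "STPD_TEMP_K",
]

STPD_PRESSURE_HPA = 1013.25
STPD_TEMP_K = 273.15


@dataclass(frozen=True)
class VentilationSetting:
    """Ventilator configuration and subject mass."""

    mvv_ml_min: float
    rr_per_min: float
    peep_cmh2o: float
    mass_kg: float

    def __post_init__(self) -> None:
        for name in ("mvv_ml_min", "rr_per_min", "peep_cmh2o", "mass_kg"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")


@dataclass(frozen=True)
class MetabolicResult:
    """VI/VE with STPD volumes and per-mass metabolic rates."""

    r: float
    ve_stpd_ml_min: float
    vi_stpd_ml_min: float
    vo2_ml_kg_min: float
    vco2_ml_kg_min: float
    rq: float


def vo2(r: float, fio2: float, feo2: float, ve_stpd: float) -> float:
    """O2 uptake: (R * FIO2 - FEO2) * VE, in the units of ``ve_stpd``."""
    if not 0.0 <= fio2 <= 1.0 or not 0.0 <= feo2 <= 1.0:
        raise DomainError("fractions must lie in [0, 1]")
    if not 0.9 < r < 1.1:
        raise DomainError(f"r={r} outside plausible range (0.9, 1.1)")
    extraction = r * fio2 - feo2
    if extraction <= 0:
        raise NonPositiveUptakeError(
            f"r*fio2 - feo2 = {extraction:.6f} <= 0: inconsistent inputs"
        )
    return extraction * ve_stpd


def vco2(feco2: float, ve_stpd: float, fico2: float = 0.0, vi_stpd: float = 0.0) -> float:
    """CO2 output: VE * FECO2 - VI * FICO2 (reduces to VE * FECO2 for FICO2 = 0)."""
    if not 0.0 <= feco2 <= 1.0 or not 0.0 <= fico2 <= 1.0:
        raise DomainError("fractions must lie in [0, 1]")
    out = ve_stpd * feco2 - vi_stpd * fico2
    if out < 0:
        raise InconsistentInputsError(f"negative VCO2 ({out:.6f})")
    return out


def rq(vco2_rate: float, vo2_rate: float) -> float:
    """Respiratory quotient VCO2/VO2."""
    if vo2_rate <= 0:
        raise DomainError("vo2 must be positive")
    return vco2_rate / vo2_rate


def haldane_ratio(fio2: float, feo2: float, feco2: float) -> float:
    """Nitrogen-conservation estimate of VI/VE: (1 - FEO2 - FECO2)/(1 - FIO2).

    Singular at FIO2 = 1 (the denominator vanishes with pure-O2 inspirate),
    which is precisely why a directly measured R is needed there.
    """
    if fio2 >= 1.0:
        raise DomainError("Haldane transformation undefined at FIO2 >= 1 (zero denominator)")
    if not 0.0 <= fio2 < 1.0 or not 0.0 <= feo2 <= 1.0 or not 0.0 <= feco2 <= 1.0:
        raise DomainError("fractions must lie in [0, 1]")
    return (1.0 - feo2 - feco2) / (1.0 - fio2)


def ve_to_stpd(ve_measured_ml_min: float, psychro: PsychroState) -> float:
    """Convert a measured expired minute volume to dry STPD.

    ve * (1 - x_water) * (P / 1013.25) * (273.15 / (273.15 + T)).
    Identity at 0 degC, dry, 1013.25 hPa.
    """
    if ve_measured_ml_min < 0:
        raise DomainError("ve must be non-negative")
    x_w = water_mole_fraction(psychro)
    return (
        ve_measured_ml_min
        * (1.0 - x_w)
        * (psychro.pressure_hpa / STPD_PRESSURE_HPA)
        * (STPD_TEMP_K / (STPD_TEMP_K + psychro.temp_c))
    )


def per_kg(rate_ml_min: float, mass_kg: float) -> float:
    """Normalize a rate by subject mass."""
    if mass_kg <= 0:
        raise DomainError("mass_kg must be positive")
    return rate_ml_min / mass_kg


def full_pipeline(
    inhale: GasReading,
    exhale: GasReading,
    timing: BagTiming,
    bag_psychro: PsychroState,
    ve_measured_ml_min: float,
    ve_psychro: PsychroState,
    vent: VentilationSetting,
    use_haldane: bool = False,
) -> MetabolicResult:
    """End-to-end metabolic computation from raw averaged readings.

    Stages (any failure raises :class:`PipelineStageError` naming the stage):

    1. ``gas_corrections`` — correct inspired and expired readings to dry
       fractions;
    2. ``molar_ratio`` — te/ti ratio, then humid->dry conversion with the
       bag conditions (skipped if ``use_haldane``: R is then estimated from
       the gas fractions by nitrogen conservation);
    3. ``ve_stpd`` — expired minute volume to dry STPD;
    4. ``metabolism`` — VO2, VCO2, RQ, per-kg normalization.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, exc) from exc

    fio2_dry, fico2_dry = stage("gas_corrections", correct_reading, inhale)
    feo2_dry, feco2_dry = stage("gas_corrections", correct_reading, exhale)

    if use_haldane:
        r = stage("molar_ratio", haldane_ratio, fio2_dry, feo2_dry, feco2_dry)
    else:
        r_humid = stage("molar_ratio", ratio_from_timing, timing)
        r = stage("molar_ratio", dry_ratio, r_humid, bag_psychro)

    ve_stpd = stage("ve_stpd", ve_to_stpd, ve_measured_ml_min, ve_psychro)
    vi_stpd = r * ve_stpd

    vo2_rate = stage("metabolism", vo2, r, fio2_dry, feo2_dry, ve_stpd)
    vco2_rate = stage("metabolism", vco2, feco2_dry, ve_stpd, fico2_dry, vi_stpd)
    rq_val = stage("metabolism", rq, vco2_rate, vo2_rate)

    return MetabolicResult(
        r=r,
        ve_stpd_ml_min=ve_stpd,
        vi_stpd_ml_min=vi_stpd,
        vo2_ml_kg_min=per_kg(vo2_rate, vent.mass_kg),
        vco2_ml_kg_min=per_kg(vco2_rate, vent.mass_kg),
        rq=rq_val,
    )
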