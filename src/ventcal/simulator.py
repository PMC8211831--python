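"""Mass-balance simulator of a ventilated subject.

Forward model (dry volumes at STPD, mL/min):

    vo2_total = mass * (vo2_mito + k_p450 * fio2 + k_skin * max(0, fio2 - 0.21))
    vco2      = mass * rq_tissue * vo2_mito
    VE_dry    = VI - vo2_total + vco2 + dn2
    FEO2      = (VI * fio2 - vo2_total) / VE_dry
    FECO2     = vco2 / VE_dry
    R_dry     = VI / VE_dry

``vo2_mito`` is the mitochondrial (CO2-producing) uptake; the two sink
terms consume O2 without producing CO2 — an oxidase-type sink scaling with
the inspired fraction and a diffusive transcutaneous loss driven by the
excess of fio2 over room air.  ``dn2`` is a net nitrogen imbalance that
breaks the Haldane identity by exactly that flux; with dn2 = 0 the model
conserves N2 and R_dry equals the Haldane ratio of its own fractions.

:func:`simulate_measurement` fabricates the raw sensor records (pressure
offsets, CO2 cross-sensitivity distortion, humidification, multiplicative
noise, bag timings) in precisely the order the analysis pipeline inverts,
so a zero-noise measurement is recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, InfeasibleSubjectError
from .error_budget import ErrorModel
from .gas_corrections import (
    MMHG_TO_HPA,
    GasReading,
    inverse_co2_cross_sensitivity,
)
from .metabolism import (
    STPD_PRESSURE_HPA,
    STPD_TEMP_K,
    MetabolicResult,
    VentilationSetting,
    full_pipeline,
)
from .molar_ratio import BagTiming
from .psychrometry import PsychroState, water_mole_fraction

__all__ = [
    "VirtualSubject",
    "GasState",
    "SimulatedMeasurement",
    "forward_model",
    "simulate_measurement",
    "recover",
    "generate_cohort",
    "default_cohort_config",
]

ROOM_AIR_FIO2 = 0.21


@dataclass(frozen=True)
class VirtualSubject:
    """Ground-truth gas-exchange parameters of a simulated subject.

    Rates are per kg unless suffixed ``_ml_min``.  ``k_p450_ml_kg_min`` is
    the non-CO2-producing O2 sink per unit inspired fraction;
    ``k_skin_ml_kg_min`` the diffusive loss per unit (fio2 - 0.21) excess.
    """

    mass_kg: float = 0.45
    fio2: float = 0.3
    mvv_ml_min: float = 180.0
    vo2_mito_ml_kg_min: float = 13.0
    rq_tissue: float = 0.93
    k_p450_ml_kg_min: float = 0.0
    k_skin_ml_kg_min: float = 0.0
    dn2_ml_min: float = 0.0
    body_temp_c: float = 37.0
    exhalation_rh: float = 0.92
    ambient_temp_c: float = 22.8
    ambient_hpa: float = 1008.0
    circuit_gauge_mmhg: float = 12.5

    def __post_init__(self) -> None:
        if not ROOM_AIR_FIO2 <= self.fio2 <= 1.0:
            raise InfeasibleSubjectError(f"fio2 {self.fio2} outside [0.21, 1.0]")
        for name in ("mass_kg", "mvv_ml_min"):
            if getattr(self, name) <= 0:
                raise InfeasibleSubjectError(f"{name} must be positive")
        for name in (
            "vo2_mito_ml_kg_min",
            "rq_tissue",
            "k_p450_ml_kg_min",
            "k_skin_ml_kg_min",
        ):
            if getattr(self, name) < 0:
                raise InfeasibleSubjectError(f"{name} must be non-negative")
        if not 0.0 <= self.exhalation_rh <= 1.0:
            raise InfeasibleSubjectError("exhalation_rh must lie in [0, 1]")

    @property
    def p_circuit_hpa(self) -> float:
        return self.ambient_hpa + self.circuit_gauge_mmhg * MMHG_TO_HPA


@dataclass(frozen=True)
class GasState:
    """Noiseless gas-exchange state implied by a subject's parameters."""

    vi_stpd_ml_min: float
    ve_dry_stpd_ml_min: float
    feo2: float
    feco2: float
    r_dry: float
    r_humid: float
    vo2_total_ml_min: float
    vco2_ml_min: float
    bag_psychro: PsychroState


@dataclass(frozen=True)
class SimulatedMeasurement:
    """One fabricated measurement set, ready for the analysis pipeline."""

    inhale: GasReading
    exhale: GasReading
    timing: BagTiming
    bag_psychro: PsychroState
    ve_measured_ml_min: float
    ve_psychro: PsychroState
    vent: VentilationSetting
    truth: GasState
    subject: VirtualSubject
    seed: Optional[int]


def forward_model(subject: VirtualSubject) -> GasState:
    """Noiseless gas state from the mass balance; raises if infeasible."""
    m = subject.mass_kg
    vo2_total = m * (
        subject.vo2_mito_ml_kg_min
        + subject.k_p450_ml_kg_min * subject.fio2
        + subject.k_skin_ml_kg_min * max(0.0, subject.fio2 - ROOM_AIR_FIO2)
    )
    vco2 = m * subject.rq_tissue * subject.vo2_mito_ml_kg_min
    vi = subject.mvv_ml_min
    ve_dry = vi - vo2_total + vco2 + subject.dn2_ml_min
    if ve_dry <= 0:
        raise InfeasibleSubjectError(f"VE_dry {ve_dry:.3f} mL/min <= 0")
    feo2 = (vi * subject.fio2 - vo2_total) / ve_dry
    feco2 = vco2 / ve_dry
    # at fio2 = 1 with dn2 = 0 the expired gas is O2 + CO2 only, so the
    # fraction sum legitimately reaches 1 exactly
    if feo2 <= 0 or feo2 + feco2 > 1.0 + 1e-9:
        raise InfeasibleSubjectError(
            f"infeasible expired fractions FEO2={feo2:.4f}, FECO2={feco2:.4f}"
        )
    bag_psychro = PsychroState(
        temp_c=subject.ambient_temp_c,
        rh=subject.exhalation_rh,
        pressure_hpa=subject.ambient_hpa,
    )
    r_dry = vi / ve_dry
    return GasState(
        vi_stpd_ml_min=vi,
        ve_dry_stpd_ml_min=ve_dry,
        feo2=feo2,
        feco2=feco2,
        r_dry=r_dry,
        r_humid=r_dry * (1.0 - water_mole_fraction(bag_psychro)),
        vo2_total_ml_min=vo2_total,
        vco2_ml_min=vco2,
        bag_psychro=bag_psychro,
    )


def _from_stpd(ve_stpd: float, psychro: PsychroState) -> float:
    """Inverse of metabolism.ve_to_stpd: STPD dry volume -> as-measured volume."""
    x_w = water_mole_fraction(psychro)
    return ve_stpd / (
        (1.0 - x_w)
        * (psychro.pressure_hpa / STPD_PRESSURE_HPA)
        * (STPD_TEMP_K / (STPD_TEMP_K + psychro.temp_c))
    )


def simulate_measurement(
    subject: VirtualSubject,
    error_model: Optional[ErrorModel] = None,
    seed: Optional[int] = None,
    te_s: float = 600.0,
) -> SimulatedMeasurement:
    """Fabricate one raw measurement set for a subject.

    Sensor distortions are the exact forward images of the pipeline's
    corrections: expired fractions are humidified (wet basis), the CO2
    channel gets the inverse cross-sensitivity distortion at the simulated
    O2 level, and both channels are rescaled from the calibration to the
    in-circuit pressure.  Noise (if ``error_model`` is given) is
    multiplicative Gaussian on the O2 readings and on the pump-out time ti;
    the collection time te is a controlled duration and stays fixed.
    """
    truth = forward_model(subject)
    rng = np.random.default_rng(seed)

    def o2_noise() -> float:
        if error_model is None:
            return 1.0
        return 1.0 + error_model.sigma_o2_rel * float(rng.standard_normal())

    p_calib = subject.ambient_hpa
    p_circuit = subject.p_circuit_hpa
    exhale_psychro = PsychroState(
        temp_c=subject.ambient_temp_c,
        rh=subject.exhalation_rh,
        pressure_hpa=p_circuit,
    )

    # Inspired line: dried, and recorded at the inhalation port before the
    # circuit is switched, i.e. at ambient (= calibration) pressure.  Its
    # long pre/post averaging window makes random error negligible next to
    # the 60-s expired reading, so noise is applied to the expired O2 only.
    inhale = GasReading(
        o2_frac=subject.fio2,
        co2_frac=0.0,
        p_calib_hpa=p_calib,
        p_circuit_hpa=p_calib,
        psychro=None,
    )

    x_w = water_mole_fraction(exhale_psychro)
    feo2_wet = truth.feo2 * (1.0 - x_w)
    feco2_wet = truth.feco2 * (1.0 - x_w)
    feco2_distorted = (
        inverse_co2_cross_sensitivity(feco2_wet * 100.0, feo2_wet * 100.0) / 100.0
    )
    exhale = GasReading(
        o2_frac=feo2_wet * p_circuit / p_calib * o2_noise(),
        co2_frac=feco2_distorted * p_circuit / p_calib,
        p_calib_hpa=p_calib,
        p_circuit_hpa=p_circuit,
        psychro=exhale_psychro,
    )

    ti_true = te_s / truth.r_humid
    ti = ti_true
    if error_model is not None:
        ti = ti_true * (1.0 + error_model.sigma_r_rel * float(rng.standard_normal()))
    timing = BagTiming(te_s=te_s, ti_s=ti, equilibrated=True)

    ve_psychro = PsychroState(
        temp_c=subject.ambient_temp_c,
        rh=subject.exhalation_rh,
        pressure_hpa=subject.ambient_hpa,
    )
    vent = VentilationSetting(
        mvv_ml_min=subject.mvv_ml_min,
        rr_per_min=45.0,
        peep_cmh2o=2.0,
        mass_kg=subject.mass_kg,
    )
    return SimulatedMeasurement(
        inhale=inhale,
        exhale=exhale,
        timing=timing,
        bag_psychro=truth.bag_psychro,
        ve_measured_ml_min=_from_stpd(truth.ve_dry_stpd_ml_min, ve_psychro),
        ve_psychro=ve_psychro,
        vent=vent,
        truth=truth,
        subject=subject,
        seed=seed,
    )


def recover(measurement: SimulatedMeasurement, use_haldane: bool = False) -> MetabolicResult:
    """Run the analysis pipeline on a simulated measurement."""
    return full_pipeline(
        inhale=measurement.inhale,
        exhale=measurement.exhale,
        timing=measurement.timing,
        bag_psychro=measurement.bag_psychro,
        ve_measured_ml_min=measurement.ve_measured_ml_min,
        ve_psychro=measurement.ve_psychro,
        vent=measurement.vent,
        use_haldane=use_haldane,
    )


def default_cohort_config() -> dict:
    """2x2 preset (anesthetic x FIO2) with sink terms tuned to the reported
    group-mean VO2/VCO2 scales: intravenous-anesthesia groups get a strong
    fio2-dependent sink (VO2 15.4 -> 21.0 mL/kg/min from FIO2 0.3 to 1.0),
    volatile-anesthesia groups a mild one (15.4 -> 17.2), with VCO2 ~12.1
    in all groups."""
    iv = {
        "vo2_mito_ml_kg_min": {"mean": 13.0, "sd": 0.7},
        "rq_tissue": {"mean": 0.931, "sd": 0.03},
        "k_p450_ml_kg_min": 8.0,
        "k_skin_ml_kg_min": 0.0,
    }
    vol = {
        "vo2_mito_ml_kg_min": {"mean": 14.63, "sd": 0.7},
        "rq_tissue": {"mean": 0.827, "sd": 0.03},
        "k_p450_ml_kg_min": 2.571,
        "k_skin_ml_kg_min": 0.0,
    }
    return {
        "mass_kg": {"mean": 0.45, "sd": 0.025},
        "dn2_ml_min": 1.4,
        "mvv_ml_min": 180.0,
        "noise": {"sigma_r_rel": 0.003, "sigma_o2_rel": 0.002},
        "ambient": {
            "temp_c": [22.4, 23.5],
            "pressure_hpa": [993.0, 1027.0],
            "rh": [0.895, 0.925],
        },
        "groups": [
            {"label": "a", "n": 6, "fio2": 0.3, **iv},
            {"label": "b", "n": 6, "fio2": 1.0, **iv},
            {"label": "c", "n": 6, "fio2": 0.3, **vol},
            {"label": "d", "n": 6, "fio2": 1.0, **vol},
        ],
    }


def _draw(spec, rng: np.random.Generator) -> float:
    """Draw from a scalar or {mean, sd} parameter specification."""
    if isinstance(spec, dict):
        return float(rng.normal(spec["mean"], spec.get("sd", 0.0)))
    return float(spec)


_MAX_REJECTIONS = 1000


def generate_cohort(config: Optional[dict] = None, seed: int = 0) -> pd.DataFrame:
    """Simulate a cohort and emit a measurement table.

    Columns follow the ratio-CSV schema (``group, r_test_lung, r_humid,
    pressure_hpa, temp_c, rh_pct``) extended with ground truth
    ``true_vo2, true_vco2, true_rq`` (per kg) and ``seed``.  Infeasible
    parameter draws are resampled; more than 1000 rejections raise
    :class:`ConfigError`.  Deterministic for a given seed.
    """
    if config is None:
        config = default_cohort_config()
    rng = np.random.default_rng(seed)
    noise_cfg = config.get("noise", {})
    error_model = ErrorModel(
        sigma_r_rel=float(noise_cfg.get("sigma_r_rel", 0.003)),
        sigma_o2_rel=float(noise_cfg.get("sigma_o2_rel", 0.002)),
    )
    ambient = config.get("ambient", {})
    rows = []
    rejections = 0
    last_error: Optional[Exception] = None
    for group in config.get("groups", []):
        for _ in range(int(group["n"])):
            while True:
                if rejections > _MAX_REJECTIONS:
                    raise ConfigError(
                        f"more than {_MAX_REJECTIONS} infeasible parameter draws; "
                        f"check the cohort configuration (last error: {last_error})"
                    )
                try:
                    subject = VirtualSubject(
                        mass_kg=_draw(config.get("mass_kg", 0.45), rng),
                        fio2=float(group["fio2"]),
                        mvv_ml_min=_draw(config.get("mvv_ml_min", 180.0), rng),
                        vo2_mito_ml_kg_min=_draw(group["vo2_mito_ml_kg_min"], rng),
                        rq_tissue=_draw(group["rq_tissue"], rng),
                        k_p450_ml_kg_min=_draw(group.get("k_p450_ml_kg_min", 0.0), rng),
                        k_skin_ml_kg_min=_draw(group.get("k_skin_ml_kg_min", 0.0), rng),
                        dn2_ml_min=_draw(config.get("dn2_ml_min", 0.0), rng),
                        ambient_temp_c=float(rng.uniform(*ambient.get("temp_c", [22.4, 23.5]))),
                        ambient_hpa=float(rng.uniform(*ambient.get("pressure_hpa", [993.0, 1027.0]))),
                        exhalation_rh=float(rng.uniform(*ambient.get("rh", [0.895, 0.925]))),
                    )
                    sub_seed = int(rng.integers(0, 2**31 - 1))
                    meas = simulate_measurement(subject, error_model, seed=sub_seed)
                except (InfeasibleSubjectError, ValueError) as exc:
                    last_error = exc
                    rejections += 1
                    continue
                break
            r_humid_measured = meas.timing.te_s / meas.timing.ti_s
            # Test lung: same rig, no gas exchange -> true R = 1 + timing noise.
            r_test_lung = 1.0 + error_model.sigma_r_rel * float(rng.standard_normal())
            truth = meas.truth
            rows.append(
                {
                    "group": group["label"],
                    "r_test_lung": r_test_lung,
                    "r_humid": r_humid_measured,
                    "pressure_hpa": subject.ambient_hpa,
                    "temp_c": subject.ambient_temp_c,
                    "rh_pct": subject.exhalation_rh * 100.0,
                    "true_vo2": truth.vo2_total_ml_min / subject.mass_kg,
                    "true_vco2": truth.vco2_ml_min / subject.mass_kg,
                    "true_rq": truth.vco2_ml_min / truth.vo2_total_ml_min,
                    "seed": sub_seed,
                }
            )
    columns = [
        "group", "r_test_lung", "r_humid", "pressure_hpa", "temp_c", "rh_pct",
        "true_vo2", "true_vco2", "true_rq", "seed",
    ]
    return pd.DataFrame(rows, columns=columns)
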