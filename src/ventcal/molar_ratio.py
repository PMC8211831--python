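"""Molecular ratio R of inhalation to exhalation.

R is measured by timing a constant-rate pump that first fills a gasbag with
exhaled gas (duration te) and then empties it (duration ti): with the bag
equilibrated to ambient temperature and pressure during both counts,
R = VI/VE = te/ti.  The humid ratio measured from the bag is converted to a
dry-gas ratio with the psychrometric humid->dry factor.  Test-lung runs
(no gas exchange, true R = 1) serve as per-experiment quality control.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import ChecksumError, DomainError, UnequilibratedError
from .psychrometry import PsychroState, humid_to_dry_factor

__all__ = [
    "BagTiming",
    "RatioRecord",
    "ratio_from_timing",
    "dry_ratio",
    "test_lung_qc",
    "process_table",
    "load_table1",
    "read_ratio_csv",
    "write_ratio_csv",
    "QC_TOLERANCE",
]

#: Test-lung pass band around 1.0 (observed spread + stated method error).
QC_TOLERANCE = 0.005

#: SHA-256 of the packaged Table-1 fixture (integrity gate for golden tests).
TABLE1_SHA256 = "d59a1667239d2e1a08d2981f52393a11f41ac73516631c3babe7811c13684a96"

GROUP_LABELS = ("a", "b", "c", "d")


@dataclass(frozen=True)
class BagTiming:
    """Gas-collection time te and pump-out time ti, in seconds.

    ``equilibrated`` records whether bag temperature and pressure matched
    ambient during both counts; if not, the measurement is invalid and must
    be dismissed.
    """

    te_s: float
    ti_s: float
    equilibrated: bool = True

    def __post_init__(self) -> None:
        if self.te_s <= 0 or self.ti_s <= 0:
            raise DomainError("te_s and ti_s must be positive")


@dataclass
class RatioRecord:
    """One measurement row: test-lung QC ratio, animal humid ratio, bag conditions.

    ``r_dry`` holds a ratio as printed/provided by the source table (may be
    absent); ``r_dry_computed`` and ``qc_pass`` are filled by
    :func:`process_table`.
    """

    group: str
    r_test_lung: float
    r_humid: float
    psychro: PsychroState
    r_dry: Optional[float] = None
    r_dry_computed: Optional[float] = None
    qc_pass: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise DomainError(f"group {self.group!r} not one of {GROUP_LABELS}")
        for name in ("r_test_lung", "r_humid"):
            v = getattr(self, name)
            if not 0.9 < v < 1.1:
                raise DomainError(f"{name}={v} outside plausible ratio range (0.9, 1.1)")


def ratio_from_timing(timing: BagTiming) -> float:
    """Raw molecular ratio VI/VE = te/ti from an equilibrated bag timing."""
    if not timing.equilibrated:
        raise UnequilibratedError(
            "bag temperature/pressure not equilibrated: technical error, data dismissed"
        )
    return timing.te_s / timing.ti_s


def dry_ratio(r_humid: float, psychro: PsychroState) -> float:
    """Convert a humid molecular ratio to the dry-gas basis.

    r_dry = r_humid / (1 - water mole fraction of the bag gas) >= r_humid.
    """
    return r_humid * humid_to_dry_factor(psychro)


def test_lung_qc(r_test_lung: float, tolerance: float = QC_TOLERANCE) -> bool:
    """Pass iff the test-lung ratio is within ``tolerance`` of 1.0."""
    if r_test_lung <= 0:
        raise DomainError("test-lung ratio must be positive")
    return abs(r_test_lung - 1.0) <= tolerance


def process_table(records: Iterable[RatioRecord]) -> list[RatioRecord]:
    """Fill ``r_dry_computed`` and ``qc_pass`` for every record.

    Returns new records; the inputs are not mutated.
    """
    out = []
    for rec in records:
        out.append(
            replace(
                rec,
                r_dry_computed=dry_ratio(rec.r_humid, rec.psychro),
                qc_pass=test_lung_qc(rec.r_test_lung),
            )
        )
    return out


def _records_from_frame(df: pd.DataFrame) -> tuple[list[RatioRecord], list[tuple[int, str]]]:
    records: list[RatioRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            psychro = PsychroState(
                temp_c=float(row.temp_c),
                rh=float(row.rh_pct) / 100.0,
                pressure_hpa=float(row.pressure_hpa),
            )
            r_dry = getattr(row, "r_dry", None)
            records.append(
                RatioRecord(
                    group=str(row.group),
                    r_test_lung=float(row.r_test_lung),
                    r_humid=float(row.r_humid),
                    psychro=psychro,
                    r_dry=None if r_dry is None or pd.isna(r_dry) else float(r_dry),
                )
            )
        except (DomainError, ValueError, TypeError) as exc:
            errors.append((i, str(exc)))
    return records, errors


def read_ratio_csv(path: str | Path) -> tuple[list[RatioRecord], list[tuple[int, str]]]:
    """Read the ratio-table CSV schema.

    Columns: ``group, r_test_lung, r_humid, pressure_hpa, temp_c, rh_pct``
    plus optional ``r_dry``.  Malformed rows are reported with their index;
    valid rows are still returned.
    """
    df = pd.read_csv(path)
    required = {"group", "r_test_lung", "r_humid", "pressure_hpa", "temp_c", "rh_pct"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"ratio CSV missing columns: {sorted(missing)}")
    return _records_from_frame(df)


def write_ratio_csv(records: Iterable[RatioRecord], path: str | Path) -> None:
    """Write records in the input schema plus ``r_dry_computed, qc_pass``."""
    rows = []
    for rec in records:
        rows.append(
            {
                "group": rec.group,
                "r_test_lung": rec.r_test_lung,
                "r_humid": rec.r_humid,
                "pressure_hpa": rec.psychro.pressure_hpa,
                "temp_c": rec.psychro.temp_c,
                "rh_pct": rec.psychro.rh * 100.0,
                "r_dry": rec.r_dry,
                "r_dry_computed": None
                if rec.r_dry_computed is None
                else round(rec.r_dry_computed, 5),
                "qc_pass": rec.qc_pass,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _table1_bytes() -> bytes:
    return resources.files("ventcal.data").joinpath("table1.csv").read_bytes()


def load_table1(verify_checksum: bool = True) -> list[RatioRecord]:
    """Load the packaged 24-row reference measurement table.

    Four groups of six rows each: (a)/(b) intravenous anesthesia at FIO2
    0.3/1.0, (c)/(d) volatile anesthesia at FIO2 0.3/1.0.  The ``r_dry``
    column carries the source table's printed dry ratios.
    """
    raw = _table1_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != TABLE1_SHA256:
            raise ChecksumError(f"table1 fixture checksum mismatch: {digest}")
    import io

    records, errors = _records_from_frame(pd.read_csv(io.BytesIO(raw)))
    if errors:
        raise ChecksumError(f"table1 fixture contains malformed rows: {errors}")
    return records
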