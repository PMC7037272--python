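"""Shared data model, CSV readers/writers, study-design validation and configuration.

All pipeline stages consume one long (tidy) measurement table: every peak-area
observation is a :class:`MeasurementRecord` whose ``role`` says which
experiment block it belongs to (calibrant, QC, blank, carry-over blank,
pre/post-extraction spike, stability, CRM, real sample, reference).
Concentrations are ng analyte per g dry sediment throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a data-model invariant."""


class Analyte(str, enum.Enum):
    TBT = "TBT"
    TPHT = "TPhT"
    TBT_D27 = "TBT_d27"


class Role(str, enum.Enum):
    BLANK = "blank"
    CALIBRANT = "calibrant"
    QC = "qc"
    CRM = "crm"
    REAL = "real"
    SPIKE_PRE = "spike_pre"
    SPIKE_POST = "spike_post"
    STABILITY = "stability"
    CARRYOVER_BLANK = "carryover_blank"
    REFERENCE = "reference"


class Medium(str, enum.Enum):
    WATER = "water"
    MATRIX = "matrix"


ANALYTES = tuple(a.value for a in Analyte)
ROLES = tuple(r.value for r in Role)

MEASUREMENT_COLUMNS = (
    "sample_id",
    "analyte",
    "role",
    "run_id",
    "replicate",
    "nominal_conc",
    "peak_area",
    "is_area",
    "noise_sd",
    "matrix_id",
    "condition",
    "medium",
)

SEDIMENT_COLUMNS = (
    "matrix_id",
    "pH",
    "conductivity",
    "toc",
    "n",
    "h",
    "avs",
    "p",
    "heavy_metals",
    "pah",
    "sand",
    "silt",
    "clay",
)

#: sediment columns holding percentages (bounded to [0, 100])
_PERCENT_COLUMNS = ("toc", "n", "h", "avs", "p", "sand", "silt", "clay")


@dataclass(frozen=True)
class MeasurementRecord:
    """One MRM peak-area observation and its place in the study design."""

    sample_id: str
    analyte: str
    role: str
    run_id: str
    replicate: int
    peak_area: float
    nominal_conc: Optional[float] = None
    is_area: Optional[float] = None
    noise_sd: Optional[float] = None
    matrix_id: Optional[str] = None
    condition: Optional[str] = None
    medium: str = Medium.MATRIX.value

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValidationError(f"unknown analyte {self.analyte!r}")
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.medium not in (m.value for m in Medium):
            raise ValidationError(f"unknown medium {self.medium!r}")
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")
        if not math.isfinite(self.peak_area) or self.peak_area < 0:
            raise ValidationError(f"peak_area must be >= 0, got {self.peak_area}")
        if self.is_area is not None and self.is_area < 0:
            raise ValidationError("is_area must be >= 0")
        if self.nominal_conc is not None and self.nominal_conc < 0:
            raise ValidationError("nominal_conc must be >= 0")
        if self.role == Role.CALIBRANT.value and self.nominal_conc is None:
            raise ValidationError("calibrant records require nominal_conc")
        if self.role in (Role.SPIKE_PRE.value, Role.SPIKE_POST.value) and not self.matrix_id:
            raise ValidationError(f"{self.role} records require matrix_id")


@dataclass(frozen=True)
class SedimentProfile:
    """Physicochemical profile of one sediment matrix.

    ``None`` marks a value the laboratory did not report ("no data"); it is
    never silently treated as zero downstream.
    """

    matrix_id: str
    pH: Optional[float] = None
    conductivity: Optional[float] = None  # mS
    toc: Optional[float] = None  # %
    n: Optional[float] = None  # %
    h: Optional[float] = None  # %
    avs: Optional[float] = None  # %
    p: Optional[float] = None  # %
    heavy_metals: Optional[float] = None  # mg/kg
    pah: Optional[float] = None  # ug/kg
    sand: Optional[float] = None  # % of 0.063-1 mm grains
    silt: Optional[float] = None  # % of 0.002-0.063 mm grains
    clay: Optional[float] = None  # % of <0.002 mm grains

    def __post_init__(self) -> None:
        for name in _PERCENT_COLUMNS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name} out of [0, 100] for {self.matrix_id}: {v}")
        parts = (self.sand, self.silt, self.clay)
        if all(v is not None for v in parts):
            total = sum(parts)  # type: ignore[arg-type]
            if not (95.0 <= total <= 105.0):
                raise ValidationError(
                    f"grain-size fractions of {self.matrix_id} sum to {total:.1f}%, expected ~100%"
                )


# ---------------------------------------------------------------------------
# configuration


class AcceptanceThresholds(BaseModel):
    """EMA-style acceptance windows applied by the validation suite."""

    precision_max: float = 15.0  # CV %, QC levels
    precision_max_lloq: float = 20.0  # CV %, at the LLOQ
    accuracy_window: tuple[float, float] = (85.0, 115.0)  # % of nominal
    accuracy_window_lloq: tuple[float, float] = (80.0, 120.0)
    carryover_max_analyte: float = 20.0  # % of the LLOQ signal
    carryover_max_is: float = 5.0
    selectivity_max_analyte: float = 20.0
    selectivity_max_is: float = 5.0
    stability_window: tuple[float, float] = (85.0, 115.0)  # % of reference
    me_r_max: float = 15.0  # CV % across matrices
    sn_min_lloq: float = 5.0
    sn_lod: float = 3.0

    @field_validator("accuracy_window", "accuracy_window_lloq", "stability_window")
    @classmethod
    def _symmetric(cls, w: tuple[float, float]) -> tuple[float, float]:
        lo, hi = w
        if lo >= hi:
            raise ValueError("window must be (low, high) with low < high")
        if abs((lo + hi) / 2.0 - 100.0) > 1e-9:
            raise ValueError("acceptance window must be symmetric about 100%")
        return w


class AnalyteSettings(BaseModel):
    """Per-analyte study levels (ng/g) and CRM certificate values."""

    lloq_candidates: list[float]
    qc_levels: list[float]
    calibration_levels: list[float]
    crm_certified: Optional[float] = None  # ng/g
    crm_u_ref: Optional[float] = None  # ng/g standard uncertainty

    @field_validator("lloq_candidates", "qc_levels", "calibration_levels")
    @classmethod
    def _positive(cls, v: list[float]) -> list[float]:
        if any(x <= 0 for x in v):
            raise ValueError("levels must be positive")
        return v


class StudyConfig(BaseModel):
    """Whole-study configuration: analytes, levels, thresholds, regression."""

    analytes: dict[str, AnalyteSettings]
    internal_standard: str = Analyte.TBT_D27.value
    thresholds: AcceptanceThresholds = Field(default_factory=AcceptanceThresholds)
    weighting: str = "one_over_x"  # none | one_over_x | one_over_x2
    coverage_k: float = 2.0
    seed: int = 0

    @field_validator("coverage_k")
    @classmethod
    def _k_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("coverage factor k must be > 0")
        return v

    @field_validator("weighting")
    @classmethod
    def _weighting_known(cls, v: str) -> str:
        if v not in ("none", "one_over_x", "one_over_x2"):
            raise ValueError(f"unknown weighting scheme {v!r}")
        return v

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def default_config() -> StudyConfig:
    """Study configuration mirroring the validated organotin method.

    TBT is quantified over 1-4000 ng/g (LLOQ 1 ng/g, QCs 3/2500/4000) and
    TPhT over 5-4000 ng/g (LLOQ 5 ng/g, QCs 15/2500/4000), with deuterated
    TBT as internal standard, 1/x-weighted calibration and k = 2 coverage
    for CRM trueness (BCR 646: 480 +/- 40 ng TBT/g, 29 +/- 5.5 ng TPhT/g).
    """
    return StudyConfig(
        analytes={
            "TBT": AnalyteSettings(
                lloq_candidates=[1.0],
                qc_levels=[3.0, 2500.0, 4000.0],
                calibration_levels=[1.0, 5.0, 25.0, 100.0, 500.0, 2000.0, 4000.0],
                crm_certified=480.0,
                crm_u_ref=40.0,
            ),
            "TPhT": AnalyteSettings(
                lloq_candidates=[5.0],
                qc_levels=[15.0, 2500.0, 4000.0],
                calibration_levels=[5.0, 10.0, 50.0, 150.0, 500.0, 2000.0, 4000.0],
                crm_certified=29.0,
                crm_u_ref=5.5,
            ),
        },
    )


# ---------------------------------------------------------------------------
# measurement table IO

_OPTIONAL_FLOAT = ("nominal_conc", "is_area", "noise_sd")
_OPTIONAL_TEXT = ("matrix_id", "condition")


def _parse_optional_float(value: object) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "no data"):
        return None
    return float(s)


def read_measurements(
    path: str | Path, config: StudyConfig | None = None
) -> list[MeasurementRecord]:
    """Read a long-format measurement CSV into validated records.

    Raises :class:`SchemaError` if a required column is missing and
    :class:`ValidationError` (with the offending row number) if any row
    violates a record invariant.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = set(MEASUREMENT_COLUMNS) - set(_OPTIONAL_FLOAT) - set(_OPTIONAL_TEXT)
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: list[MeasurementRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        data = row._asdict()
        try:
            rec = MeasurementRecord(
                sample_id=str(data["sample_id"]),
                analyte=str(data["analyte"]),
                role=str(data["role"]),
                run_id=str(data["run_id"]),
                replicate=int(float(data["replicate"])),
                peak_area=float(data["peak_area"]),
                nominal_conc=_parse_optional_float(data.get("nominal_conc")),
                is_area=_parse_optional_float(data.get("is_area")),
                noise_sd=_parse_optional_float(data.get("noise_sd")),
                matrix_id=(str(data["matrix_id"]).strip() or None)
                if "matrix_id" in data
                else None,
                condition=(str(data["condition"]).strip() or None)
                if "condition" in data
                else None,
                medium=str(data.get("medium") or Medium.MATRIX.value),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_measurements(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    """Write records back to the long CSV layout (lossless round trip)."""
    rows = []
    for rec in records:
        row = {name: getattr(rec, name) for name in MEASUREMENT_COLUMNS}
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    df.to_csv(path, index=False)


def measurements_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a record collection (for joins and groupbys)."""
    return pd.DataFrame(
        [{name: getattr(rec, name) for name in MEASUREMENT_COLUMNS} for rec in records],
        columns=list(MEASUREMENT_COLUMNS),
    )


def read_sediment_profiles(path: str | Path) -> list[SedimentProfile]:
    """Read sediment physicochemistry; "no data"/empty cells become missing."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "matrix_id" not in df.columns:
        raise SchemaError("missing required column(s): matrix_id")
    profiles: list[SedimentProfile] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        data = row._asdict()
        mid = str(data["matrix_id"]).strip()
        if mid in seen:
            raise ValidationError(f"row {i}: duplicated matrix_id {mid!r}")
        seen.add(mid)
        kwargs = {
            name: _parse_optional_float(data.get(name))
            for name in SEDIMENT_COLUMNS
            if name != "matrix_id" and name in data
        }
        try:
            profiles.append(SedimentProfile(matrix_id=mid, **kwargs))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return profiles


def write_sediment_profiles(profiles: Iterable[SedimentProfile], path: str | Path) -> None:
    rows = [{name: getattr(p, name) for name in SEDIMENT_COLUMNS} for p in profiles]
    pd.DataFrame(rows, columns=list(SEDIMENT_COLUMNS)).to_csv(path, index=False)


def profiles_to_frame(profiles: Sequence[SedimentProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [{name: getattr(p, name) for name in SEDIMENT_COLUMNS} for p in profiles],
        columns=list(SEDIMENT_COLUMNS),
    ).set_index("matrix_id")


# ---------------------------------------------------------------------------
# study-design validation


@dataclass
class BlockStatus:
    name: str
    runnable: bool
    detail: str


@dataclass
class DesignReport:
    """Report-only audit of whether each pipeline stage can run."""

    per_analyte: dict[str, dict[str, object]] = field(default_factory=dict)
    blocks: list[BlockStatus] = field(default_factory=list)

    @property
    def all_runnable(self) -> bool:
        return all(b.runnable for b in self.blocks)

    def block(self, name: str) -> BlockStatus:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)


def validate_study_design(
    records: Sequence[MeasurementRecord], config: StudyConfig
) -> DesignReport:
    """Audit the replicate/role structure of a study without mutating it.

    Flags (never raises) any experiment block the downstream stages could not
    run: calibration needs >=3 levels, accuracy/precision needs >=2 replicates
    per QC level, matrix effects need both pre- and post-extraction spikes,
    trueness needs >=2 CRM replicates, and so on.
    """
    if not records:
        raise ValidationError("records must be non-empty")
    df = measurements_to_frame(records)
    report = DesignReport()

    analytes = [a for a in config.analytes]
    for analyte in analytes:
        sub = df[df.analyte == analyte]
        cal = sub[sub.role == Role.CALIBRANT.value]
        levels = sorted(cal.nominal_conc.dropna().unique())
        reps = (
            int(cal.groupby("nominal_conc").size().min()) if len(cal) else 0
        )
        qc = sub[sub.role == Role.QC.value]
        report.per_analyte[analyte] = {
            "n_calibration_levels": len(levels),
            "calibration_levels": levels,
            "replicates_per_level": reps,
            "qc_levels": sorted(qc.nominal_conc.dropna().unique()),
            "n_blanks": int((sub.role == Role.BLANK.value).sum()),
            "n_crm": int((sub.role == Role.CRM.value).sum()),
            "n_spike_pre": int((sub.role == Role.SPIKE_PRE.value).sum()),
            "n_spike_post": int((sub.role == Role.SPIKE_POST.value).sum()),
        }

    def has(role: Role, analyte: str | None = None) -> int:
        sub = df[df.role == role.value]
        if analyte is not None:
            sub = sub[sub.analyte == analyte]
        return len(sub)

    cal_ok = all(
        report.per_analyte[a]["n_calibration_levels"] >= 3 for a in analytes
    )
    report.blocks.append(
        BlockStatus("calibration", cal_ok, "needs >=3 calibrant levels per analyte")
    )
    qc_ok = all(len(report.per_analyte[a]["qc_levels"]) > 0 for a in analytes) and all(
        report.per_analyte[a]["replicates_per_level"] >= 2 for a in analytes
    )
    report.blocks.append(
        BlockStatus("accuracy_precision", qc_ok and has(Role.QC) > 0, "needs replicated QC records")
    )
    report.blocks.append(
        BlockStatus("selectivity", has(Role.BLANK) > 0, "needs blank records")
    )
    report.blocks.append(
        BlockStatus(
            "carry_over", has(Role.CARRYOVER_BLANK) > 0, "needs blanks injected after high standards"
        )
    )
    report.blocks.append(
        BlockStatus(
            "stability",
            has(Role.STABILITY) > 0 and has(Role.REFERENCE) > 0,
            "needs stability and reference records",
        )
    )
    me_ok = all(has(Role.SPIKE_POST, a) > 0 for a in analytes)
    report.blocks.append(
        BlockStatus("matrix_effects", me_ok, "needs post-extraction spike curves")
    )
    re_ok = all(has(Role.SPIKE_PRE, a) > 0 for a in analytes) and me_ok
    report.blocks.append(
        BlockStatus("extraction_recovery", re_ok, "needs pre/post spike pairs")
    )
    report.blocks.append(
        BlockStatus("trueness", has(Role.CRM) >= 2, "needs >=2 CRM replicates")
    )
    report.blocks.append(
        BlockStatus("quantification", has(Role.REAL) > 0, "needs real-sample records")
    )
    return report


__all__ = [
    "Analyte",
    "Role",
    "Medium",
    "MeasurementRecord",
    "SedimentProfile",
    "StudyConfig",
    "AnalyteSettings",
    "AcceptanceThresholds",
    "SchemaError",
    "ValidationError",
    "DesignReport",
    "default_config",
    "read_measurements",
    "write_measurements",
    "read_sediment_profiles",
    "write_sediment_profiles",
    "measurements_to_frame",
    "profiles_to_frame",
    "validate_study_design",
]
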