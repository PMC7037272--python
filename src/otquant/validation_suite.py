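"""Accuracy/precision, selectivity, carry-over and stability with EMA-style acceptance.

Every operation here is a pure function of measurement records (or of already
computed cells) plus the configured thresholds, so the acceptance verdict is
reproducible from the stored tables alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import CalibrationFit, back_calculate, response_of
from .io_model import MeasurementRecord, Role, StudyConfig, ValidationError


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicates where a CV is required."""


class DegenerateRatioError(ValueError):
    """A ratio denominator (LLOQ area, reference mean) is zero."""


@dataclass(frozen=True)
class AccuracyPrecisionCell:
    """One accuracy/precision result at one level, within or between runs."""

    analyte: str
    level: float  # ng/g
    scope: str  # within_run | between_run
    accuracy: float  # % of nominal
    precision: float  # CV %
    n: int
    passed: bool
    run_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.precision < 0:
            raise ValidationError("precision must be >= 0")


@dataclass(frozen=True)
class SelectivityResult:
    """Blank interference relative to the LLOQ signal, per analyte."""

    analyte: str
    ratio: float  # % of mean LLOQ area
    sd: float  # % over the blank set
    n: int
    passed: bool


@dataclass(frozen=True)
class CarryOverResult:
    """Residual signal in a blank injected after a high standard."""

    analyte: str
    carry_over: float  # % of the LLOQ area
    passed: bool


@dataclass(frozen=True)
class StabilityCell:
    """Stored/stressed concentration as % of the fresh reference."""

    analyte: str
    level: float
    condition: str
    stability: float  # % of reference
    passed: bool


@dataclass
class ValidationVerdict:
    """Per-block pass/fail and the overall conjunction."""

    blocks: dict[str, bool] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(self.blocks.values()) if self.blocks else False

    def failing_blocks(self) -> list[str]:
        return sorted(name for name, ok in self.blocks.items() if not ok)


def _is_lloq_level(level: float, config: StudyConfig, analyte: str) -> bool:
    return any(
        math.isclose(level, c) for c in config.analytes[analyte].lloq_candidates
    )


def accuracy_precision(
    records: Sequence[MeasurementRecord],
    fit: CalibrationFit,
    level: float,
    scope: str,
    config: StudyConfig,
    run_id: Optional[str] = None,
) -> AccuracyPrecisionCell:
    """Accuracy (% of nominal) and precision (CV %) of back-calculated QCs.

    ``within_run`` restricts to a single run (pass ``run_id`` or supply
    records from one run only); ``between_run`` pools replicates across all
    runs. Acceptance windows are 85-115% / <=15% at QC levels and 80-120% /
    <=20% at the LLOQ.
    """
    if scope not in ("within_run", "between_run"):
        raise ValueError(f"unknown scope {scope!r}")
    recs = [
        r
        for r in records
        if r.analyte == fit.analyte
        and r.nominal_conc is not None
        and math.isclose(r.nominal_conc, level)
    ]
    if scope == "within_run":
        runs = sorted({r.run_id for r in recs})
        if run_id is None:
            if len(runs) > 1:
                raise ValueError(
                    "within_run scope needs a run_id when records span several runs"
                )
            run_id = runs[0] if runs else None
        recs = [r for r in recs if r.run_id == run_id]
    if len(recs) < 2:
        raise InsufficientReplicatesError(
            f"need >=2 replicates at {level} ng/g, got {len(recs)}"
        )
    conc = np.array([back_calculate(fit, response_of(r, fit.response_kind)) for r in recs])
    accuracy = 100.0 * float(np.mean(conc)) / level
    precision = 100.0 * float(np.std(conc, ddof=1) / np.mean(conc))
    thr = config.thresholds
    if _is_lloq_level(level, config, fit.analyte):
        lo, hi = thr.accuracy_window_lloq
        cv_max = thr.precision_max_lloq
    else:
        lo, hi = thr.accuracy_window
        cv_max = thr.precision_max
    passed = (lo <= accuracy <= hi) and (precision <= cv_max)
    return AccuracyPrecisionCell(
        analyte=fit.analyte,
        level=level,
        scope=scope,
        accuracy=accuracy,
        precision=precision,
        n=len(recs),
        passed=passed,
        run_id=run_id if scope == "within_run" else None,
    )


def accuracy_precision_table(
    records: Sequence[MeasurementRecord],
    fit: CalibrationFit,
    config: StudyConfig,
) -> list[AccuracyPrecisionCell]:
    """All within-run (one cell per run) and between-run cells for an analyte.

    Mirrors the usual presentation of a validation table: within-run results
    reported per run (so a min-max range can be printed across runs) plus one
    pooled between-run row per level.
    """
    recs = [
        r
        for r in records
        if r.analyte == fit.analyte
        and r.role in (Role.QC.value, Role.CALIBRANT.value)
        and r.nominal_conc is not None
    ]
    settings = config.analytes[fit.analyte]
    levels = sorted(set(settings.lloq_candidates) | set(settings.qc_levels))
    qc_recs = [r for r in recs if r.role == Role.QC.value]
    cells: list[AccuracyPrecisionCell] = []
    for level in levels:
        at_level = [r for r in qc_recs if math.isclose(r.nominal_conc, level)]
        if len(at_level) < 2:
            continue
        for run in sorted({r.run_id for r in at_level}):
            cells.append(
                accuracy_precision(at_level, fit, level, "within_run", config, run_id=run)
            )
        cells.append(accuracy_precision(at_level, fit, level, "between_run", config))
    return cells


def selectivity(
    blank_records: Sequence[MeasurementRecord],
    lloq_records: Sequence[MeasurementRecord],
    config: StudyConfig,
    analyte: str,
    is_internal_standard: bool = False,
) -> SelectivityResult:
    """Blank interference at the analyte's retention time, % of LLOQ signal.

    Pass if below 20% for analytes and 5% for the internal standard.
    """
    blanks = [r.peak_area for r in blank_records if r.analyte == analyte]
    lloqs = [r.peak_area for r in lloq_records if r.analyte == analyte]
    if not blanks or not lloqs:
        raise ValidationError(f"need paired blank and LLOQ records for {analyte}")
    mean_lloq = float(np.mean(lloqs))
    if mean_lloq == 0:
        raise DegenerateRatioError("mean LLOQ peak area is zero")
    ratios = 100.0 * np.asarray(blanks, dtype=float) / mean_lloq
    ratio = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    thr = config.thresholds
    limit = thr.selectivity_max_is if is_internal_standard else thr.selectivity_max_analyte
    return SelectivityResult(
        analyte=analyte, ratio=ratio, sd=sd, n=len(blanks), passed=ratio < limit
    )


def carry_over(
    blank_after_high: MeasurementRecord,
    lloq_record: MeasurementRecord,
    config: StudyConfig,
    is_internal_standard: bool = False,
) -> CarryOverResult:
    """Carry-over = 100 * A_blank / A_LLOQ for one blank/LLOQ injection pair."""
    if lloq_record.peak_area == 0:
        raise DegenerateRatioError("LLOQ peak area is zero")
    pct = 100.0 * blank_after_high.peak_area / lloq_record.peak_area
    thr = config.thresholds
    limit = thr.carryover_max_is if is_internal_standard else thr.carryover_max_analyte
    return CarryOverResult(
        analyte=blank_after_high.analyte, carry_over=pct, passed=pct < limit
    )


def carry_over_summary(
    blank_records: Sequence[MeasurementRecord],
    lloq_records: Sequence[MeasurementRecord],
    config: StudyConfig,
    analyte: str,
    is_internal_standard: bool = False,
) -> CarryOverResult:
    """Carry-over of the mean blank area against the mean LLOQ area."""
    blanks = [r.peak_area for r in blank_records if r.analyte == analyte]
    lloqs = [r.peak_area for r in lloq_records if r.analyte == analyte]
    if not blanks or not lloqs:
        raise ValidationError(f"need carry-over blanks and LLOQ records for {analyte}")
    mean_lloq = float(np.mean(lloqs))
    if mean_lloq == 0:
        raise DegenerateRatioError("mean LLOQ peak area is zero")
    pct = 100.0 * float(np.mean(blanks)) / mean_lloq
    thr = config.thresholds
    limit = thr.carryover_max_is if is_internal_standard else thr.carryover_max_analyte
    return CarryOverResult(analyte=analyte, carry_over=pct, passed=pct < limit)


def stability(
    test_records: Sequence[MeasurementRecord],
    reference_records: Sequence[MeasurementRecord],
    condition: str,
    fit: CalibrationFit,
    config: StudyConfig,
    level: Optional[float] = None,
) -> StabilityCell:
    """Stability = 100 * mean(test conc) / mean(reference conc) for a condition.

    Referenced to freshly prepared and measured samples, not to nominal; pass
    within the configured window (default 85-115%).
    """
    test = [r for r in test_records if r.analyte == fit.analyte]
    ref = [r for r in reference_records if r.analyte == fit.analyte]
    if not test or not ref:
        raise ValidationError("both test and reference sets must be non-empty")
    if level is None:
        levels = {r.nominal_conc for r in test if r.nominal_conc is not None}
        if len(levels) != 1:
            raise ValidationError("stability records must share one nominal level")
        level = levels.pop()
    t_conc = np.array([back_calculate(fit, response_of(r, fit.response_kind)) for r in test])
    r_conc = np.array([back_calculate(fit, response_of(r, fit.response_kind)) for r in ref])
    ref_mean = float(np.mean(r_conc))
    if ref_mean == 0:
        raise DegenerateRatioError("reference mean concentration is zero")
    pct = 100.0 * float(np.mean(t_conc)) / ref_mean
    lo, hi = config.thresholds.stability_window
    return StabilityCell(
        analyte=fit.analyte,
        level=level,
        condition=condition,
        stability=pct,
        passed=lo <= pct <= hi,
    )


def evaluate_acceptance(
    config: StudyConfig,
    calibration_fits: Sequence[CalibrationFit] = (),
    accuracy_cells: Sequence[AccuracyPrecisionCell] = (),
    selectivity_results: Sequence[SelectivityResult] = (),
    carryover_results: Sequence[CarryOverResult] = (),
    stability_cells: Sequence[StabilityCell] = (),
    me_r_passed: Optional[bool] = None,
) -> ValidationVerdict:
    """Combine all validation cells into a per-block and overall verdict.

    Pure function: the same cells and config always give the same verdict.
    Blocks with no cells are omitted (reported as not run, not as failures).
    """
    verdict = ValidationVerdict()
    if calibration_fits:
        verdict.blocks["calibration"] = all(
            f.p_slope < 0.05 and f.n_points >= 3 for f in calibration_fits
        )
    if accuracy_cells:
        verdict.blocks["accuracy_precision"] = all(c.passed for c in accuracy_cells)
    if selectivity_results:
        verdict.blocks["selectivity"] = all(s.passed for s in selectivity_results)
    if carryover_results:
        verdict.blocks["carry_over"] = all(c.passed for c in carryover_results)
    if stability_cells:
        verdict.blocks["stability"] = all(s.passed for s in stability_cells)
    if me_r_passed is not None:
        verdict.blocks["relative_matrix_effect"] = me_r_passed
    return verdict


__all__ = [
    "AccuracyPrecisionCell",
    "SelectivityResult",
    "CarryOverResult",
    "StabilityCell",
    "ValidationVerdict",
    "accuracy_precision",
    "accuracy_precision_table",
    "selectivity",
    "carry_over",
    "carry_over_summary",
    "stability",
    "evaluate_acceptance",
    "InsufficientReplicatesError",
    "DegenerateRatioError",
]
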