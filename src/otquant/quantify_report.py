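"""Real-sample quantification with LOD/LLOQ censoring, monitoring summaries, reports."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationFit, LimitDecision, back_calculate, response_of
from .io_model import MeasurementRecord, Role, ValidationError

BELOW_LOD = "below_lod"
BELOW_LLOQ = "below_lloq"


@dataclass(frozen=True)
class QuantResult:
    """Reported concentration of one analyte in one sample, or a censor flag.

    Exactly one of ``concentration`` / ``censored`` is set: values below the
    detection limit are flagged ``below_lod``, values between the detection
    and quantification limits ``below_lloq``.
    """

    sample_id: str
    analyte: str
    concentration: Optional[float] = None  # ng/g
    censored: Optional[str] = None
    localization: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.concentration is None) == (self.censored is None):
            raise ValidationError(
                "exactly one of concentration / censored must be present"
            )
        if self.censored is not None and self.censored not in (BELOW_LOD, BELOW_LLOQ):
            raise ValidationError(f"unknown censor flag {self.censored!r}")


def censor(value: float, limits: LimitDecision) -> tuple[Optional[float], Optional[str]]:
    """Apply LOD/LLOQ censoring to one averaged concentration value."""
    if value < limits.lod:
        return None, BELOW_LOD
    if value < limits.lloq:
        return None, BELOW_LLOQ
    return value, None


def quantify(
    records: Sequence[MeasurementRecord],
    fit: CalibrationFit,
    limits: LimitDecision,
) -> list[QuantResult]:
    """Back-calculate real-sample concentrations and censor against the limits.

    Replicates of a sample are averaged before censoring. Quantification uses
    the calibration fit's response kind (analyte/IS area ratio by default); a
    missing IS area under an IS-ratio fit is a contract error.
    """
    recs = [
        r
        for r in records
        if r.analyte == fit.analyte and r.role == Role.REAL.value
    ]
    results: list[QuantResult] = []
    for sample_id in sorted({r.sample_id for r in recs}):
        group = [r for r in recs if r.sample_id == sample_id]
        conc = float(
            np.mean([back_calculate(fit, response_of(r, fit.response_kind)) for r in group])
        )
        value, flag = censor(conc, limits)
        results.append(
            QuantResult(
                sample_id=sample_id,
                analyte=fit.analyte,
                concentration=value,
                censored=flag,
                localization=group[0].matrix_id,
            )
        )
    return results


@dataclass(frozen=True)
class AnalyteSummary:
    """Monitoring summary for one analyte over a set of quantified samples."""

    analyte: str
    n_samples: int
    n_quantified: int  # uncensored (>= LLOQ)
    n_censored: int
    maximum: Optional[float]  # ng/g, over uncensored values
    minimum: Optional[float]
    n_above_thresholds: dict[float, int]


def summarize(
    results: Sequence[QuantResult],
    thresholds: Sequence[float] = (),
) -> dict[str, AnalyteSummary]:
    """Per-analyte max/min/count summaries; censored entries counted separately.

    ``thresholds`` are optional user-supplied cutoffs (e.g. sediment-quality
    action levels) counted over the uncensored values.
    """
    if not results:
        raise ValidationError("results must be non-empty")
    out: dict[str, AnalyteSummary] = {}
    for analyte in sorted({r.analyte for r in results}):
        sub = [r for r in results if r.analyte == analyte]
        vals = [r.concentration for r in sub if r.concentration is not None]
        out[analyte] = AnalyteSummary(
            analyte=analyte,
            n_samples=len(sub),
            n_quantified=len(vals),
            n_censored=len(sub) - len(vals),
            maximum=max(vals) if vals else None,
            minimum=min(vals) if vals else None,
            n_above_thresholds={t: sum(v > t for v in vals) for t in thresholds},
        )
    return out


def results_to_frame(results: Sequence[QuantResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "analyte": r.analyte,
                "concentration": r.concentration,
                "censored": r.censored,
                "localization": r.localization,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "analyte", "concentration", "censored", "localization"])


def _fmt(value: Optional[float], digits: int = 4) -> str:
    if value is None:
        return "-"
    return f"{value:.{digits}g}"


def render_report(
    summaries: Mapping[str, AnalyteSummary] | None = None,
    verdict: object | None = None,
    matrix_results: Sequence[object] = (),
    quant_results: Sequence[QuantResult] = (),
    limits: Mapping[str, object] | None = None,
    title: str = "Study report",
) -> str:
    """Deterministic markdown report: verdict, limits, matrix effects, samples.

    The same inputs always render byte-identical output (stable ordering
    everywhere); sections without inputs are marked "not run".
    """
    lines: list[str] = [f"# {title}", ""]

    lines.append("## Validation verdict")
    if verdict is None or not getattr(verdict, "blocks", None):
        lines.append("")
        lines.append("not run")
    else:
        lines.append("")
        for name in sorted(verdict.blocks):
            lines.append(f"- {name}: {'pass' if verdict.blocks[name] else 'FAIL'}")
        lines.append(f"- overall: {'pass' if verdict.overall else 'FAIL'}")
    lines.append("")

    lines.append("## Quantification limits")
    lines.append("")
    if not limits:
        lines.append("not run")
    else:
        lines.append("| analyte | LLOQ (ng/g) | LOD (ng/g) | S/N at LLOQ |")
        lines.append("|---|---|---|---|")
        for analyte in sorted(limits):
            lim = limits[analyte]
            lines.append(
                f"| {analyte} | {_fmt(lim.lloq)} | {_fmt(lim.lod)} | {_fmt(lim.sn_at_lloq)} |"
            )
    lines.append("")

    lines.append("## Matrix effects")
    lines.append("")
    if not matrix_results:
        lines.append("not run")
    else:
        lines.append("| matrix | analyte | ME_A (%) | RE (%) |")
        lines.append("|---|---|---|---|")
        for r in sorted(matrix_results, key=lambda m: (m.analyte, m.matrix_id)):
            lines.append(
                f"| {r.matrix_id} | {r.analyte} | {_fmt(r.me_a)} | {_fmt(r.re)} |"
            )
    lines.append("")

    lines.append("## Real samples")
    lines.append("")
    if not quant_results:
        lines.append("not run")
    else:
        lines.append("| sample | analyte | concentration (ng/g) |")
        lines.append("|---|---|---|")
        for r in sorted(quant_results, key=lambda q: (q.analyte, q.sample_id)):
            shown = f"<{BELOW_LLOQ}>" if r.censored == BELOW_LLOQ else (
                f"<{BELOW_LOD}>" if r.censored == BELOW_LOD else _fmt(r.concentration)
            )
            lines.append(f"| {r.sample_id} | {r.analyte} | {shown} |")
    lines.append("")

    lines.append("## Monitoring summary")
    lines.append("")
    if not summaries:
        lines.append("not run")
    else:
        for analyte in sorted(summaries):
            s = summaries[analyte]
            lines.append(
                f"- {analyte}: {s.n_quantified}/{s.n_samples} samples quantified, "
                f"max {_fmt(s.maximum)} ng/g, min {_fmt(s.minimum)} ng/g, "
                f"{s.n_censored} censored"
            )
    lines.append("")
    return "\n".join(lines)


__all__ = [
    "QuantResult",
    "AnalyteSummary",
    "BELOW_LOD",
    "BELOW_LLOQ",
    "censor",
    "quantify",
    "summarize",
    "results_to_frame",
    "render_report",
]
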