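"""Extraction recovery, absolute/relative matrix effects, CRM trueness, sieving.

The absolute matrix effect ME_A is the ratio of matrix-matched to aqueous
calibration slopes (x100): below 100% means ionization suppression by
co-extracted matrix components, above 100% enhancement. The relative matrix
effect ME_R is the between-matrix CV of the analyte/IS ME ratio — it measures
whether the isotope-labelled internal standard corrects suppression
reproducibly, which is what actually matters for quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .calibration import CalibrationFit, DegenerateFitError
from .io_model import MeasurementRecord, ValidationError


class PairingError(ValueError):
    """Before/after collections cannot be matched by matrix id."""


@dataclass(frozen=True)
class MatrixEffectResult:
    """Per-matrix absolute matrix effect and extraction recovery."""

    matrix_id: str
    analyte: str
    me_a: float  # %
    re: float | None = None  # %, optional

    def __post_init__(self) -> None:
        if self.me_a <= 0:
            raise ValidationError("me_a must be > 0 for a nondegenerate fit")
        if self.re is not None and self.re < 0:
            raise ValidationError("re must be >= 0")


@dataclass(frozen=True)
class RelativeMatrixEffect:
    """Between-matrix CV of the analyte/IS matrix-effect ratio."""

    analyte: str
    me_r: float  # CV %
    n_matrices: int
    passed: bool

    def __post_init__(self) -> None:
        if self.me_r < 0:
            raise ValidationError("me_r must be >= 0")


@dataclass(frozen=True)
class TruenessResult:
    """Bias against a certified reference material with expanded uncertainty.

    The method is compatible with the certificate when the absolute bias
    delta = |certified - measured mean| does not exceed
    U_delta = k * sqrt(u_ref^2 + s_m^2 / n).
    """

    analyte: str
    certified: float  # ng/g
    u_ref: float  # ng/g, standard uncertainty of the certified value
    measured_mean: float  # ng/g
    s_m: float  # ng/g, sample sd of the replicate measurements
    n: int
    k: float  # coverage factor
    delta: float  # ng/g
    u_delta: float  # ng/g
    compatible: bool


@dataclass(frozen=True)
class SievingComparison:
    """Matrix effects on matched sediments before vs after fine sieving."""

    analyte: str
    mean_before: float
    sd_before: float
    mean_after: float
    sd_after: float
    n_pairs: int
    t_statistic: float
    p_value: float  # two-sided, paired


def extraction_recovery(
    pre_spike: Sequence[MeasurementRecord],
    reference: Sequence[MeasurementRecord],
) -> float:
    """Recovery % = 100 * mean(pre-extraction-spike areas) / mean(reference areas).

    The reference is the post-extraction spike at the same level (isolating
    extraction losses from ionization suppression) or an aqueous solution,
    depending on which records the caller selects.
    """
    if not pre_spike or not reference:
        raise ValidationError("both record sets must be non-empty")
    analytes = {r.analyte for r in pre_spike} | {r.analyte for r in reference}
    if len(analytes) > 1:
        raise ValidationError(f"records mix analytes: {sorted(analytes)}")
    ref_mean = float(np.mean([r.peak_area for r in reference]))
    if ref_mean == 0:
        raise DegenerateFitError("reference mean peak area is zero")
    return 100.0 * float(np.mean([r.peak_area for r in pre_spike])) / ref_mean


def absolute_matrix_effect(
    matrix_curve: CalibrationFit, water_curve: CalibrationFit
) -> float:
    """ME_A % = 100 * slope(matrix-matched curve) / slope(aqueous curve).

    Both curves must be fitted on raw peak areas: normalizing by the IS first
    would make the relative matrix effect (which divides analyte ME by IS ME)
    vacuous.
    """
    if matrix_curve.response_kind != "raw_area" or water_curve.response_kind != "raw_area":
        raise ValidationError("matrix-effect curves must use raw_area responses")
    if water_curve.slope == 0:
        raise DegenerateFitError("aqueous calibration slope is zero")
    return 100.0 * matrix_curve.slope / water_curve.slope


def relative_matrix_effect(
    analyte_me: Mapping[str, float],
    is_me: Mapping[str, float],
    analyte: str = "TBT",
    me_r_max: float = 15.0,
) -> RelativeMatrixEffect:
    """ME_R = CV% across matrices of r_i = ME_A(analyte, i) / ME_A(IS, i).

    Exactly zero when the internal standard tracks the analyte's suppression
    in every matrix. Pass below ``me_r_max`` (guideline default 15%).
    """
    keys = sorted(analyte_me)
    if set(keys) != set(is_me):
        raise PairingError("analyte and IS matrix-effect collections must share matrices")
    if len(keys) < 2:
        raise ValidationError("need >= 2 matrices for a CV")
    if any(is_me[k] == 0 for k in keys):
        raise DegenerateFitError("internal-standard matrix effect of zero")
    ratios = np.array([analyte_me[k] / is_me[k] for k in keys])
    me_r = 100.0 * float(np.std(ratios, ddof=1) / np.mean(ratios))
    return RelativeMatrixEffect(
        analyte=analyte, me_r=me_r, n_matrices=len(keys), passed=me_r < me_r_max
    )


def trueness_vs_crm(
    measured: Sequence[float],
    certified: float,
    u_ref: float,
    k: float = 2.0,
    analyte: str = "TBT",
) -> TruenessResult:
    """Expanded-uncertainty compatibility test against a certified value.

    delta = |certified - mean(measured)|; U_delta = k*sqrt(u_ref^2 + s_m^2/n)
    with s_m the sample standard deviation (n-1). Compatible when
    delta <= U_delta (the boundary counts as compatible).
    """
    vals = np.asarray(measured, dtype=float)
    if len(vals) < 2:
        raise ValidationError("need >= 2 replicate measurements")
    if u_ref < 0:
        raise ValidationError("u_ref must be >= 0")
    mean = float(np.mean(vals))
    s_m = float(np.std(vals, ddof=1))
    n = len(vals)
    delta = abs(certified - mean)
    u_delta = k * math.sqrt(u_ref**2 + s_m**2 / n)
    return TruenessResult(
        analyte=analyte,
        certified=certified,
        u_ref=u_ref,
        measured_mean=mean,
        s_m=s_m,
        n=n,
        k=k,
        delta=delta,
        u_delta=u_delta,
        compatible=delta <= u_delta,
    )


def compare_sieving(
    me_before: Mapping[str, float],
    me_after: Mapping[str, float],
    analyte: str = "TBT",
) -> SievingComparison:
    """Paired two-sided t-test of per-matrix ME_A before vs after sieving.

    Matrices are matched by id; with all differences zero the statistic is 0
    and the p-value is reported as 1.
    """
    keys = sorted(me_before)
    if set(keys) != set(me_after):
        raise PairingError("before/after collections must share matrix ids")
    if len(keys) < 2:
        raise PairingError("need >= 2 matched pairs")
    before = np.array([me_before[k] for k in keys])
    after = np.array([me_after[k] for k in keys])
    diffs = before - after
    if np.allclose(diffs, 0.0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(before, after)
    return SievingComparison(
        analyte=analyte,
        mean_before=float(np.mean(before)),
        sd_before=float(np.std(before, ddof=1)),
        mean_after=float(np.mean(after)),
        sd_after=float(np.std(after, ddof=1)),
        n_pairs=len(keys),
        t_statistic=float(t_stat),
        p_value=float(p),
    )


__all__ = [
    "MatrixEffectResult",
    "RelativeMatrixEffect",
    "TruenessResult",
    "SievingComparison",
    "extraction_recovery",
    "absolute_matrix_effect",
    "relative_matrix_effect",
    "trueness_vs_crm",
    "compare_sieving",
    "PairingError",
]
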