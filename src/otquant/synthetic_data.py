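"""Synthetic validation studies with known latent truth.

Generates every experiment block the pipeline consumes — aqueous calibration
curves, QC replicates across runs, blanks, carry-over blanks, stability sets,
matrix-matched pre/post-extraction spikes, CRM replicates and real samples —
from an explicit measurement model, so every stage is testable end to end and
parameter recovery can be checked against the truth.

Measurement model
-----------------
The expected raw peak area of analyte ``a`` at concentration ``x`` in matrix
``i`` is ``m_ai * (r_i if spiked before extraction else 1) * (slope_a * x +
intercept_a)`` where ``m_ai`` in (0, 1.3] is the ionization
suppression/enhancement factor and ``r_i`` in (0, 1.1] the extraction
recovery of matrix ``i``. Observed areas are drawn as ``expected * (1 +
N(0, cv_prop)) + N(0, sd_floor)`` truncated at zero — a multiplicative noise
component that motivates 1/x calibration weights plus an additive baseline
floor that doubles as the noise estimate behind S/N ratios. The internal
standard is added at a fixed amount before extraction, so it carries the
matrix's recovery and its own (co-)suppression factor; the analyte/IS ratio
is unbiased exactly to the extent the IS tracks the analyte's suppression.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .io_model import (
    Analyte,
    MeasurementRecord,
    Medium,
    Role,
    SedimentProfile,
    StudyConfig,
    default_config,
)

IS_NAME = Analyte.TBT_D27.value

# substream indices: each block draws from rng([seed, BLOCK]) so blocks are
# individually reproducible and insensitive to generation order
_BLOCKS = {
    "truth": 0,
    "calibration": 1,
    "qc": 2,
    "blanks": 3,
    "carryover": 4,
    "stability": 5,
    "matrix": 6,
    "crm": 7,
    "real": 8,
    "profiles": 9,
    "sieving": 10,
}


class ScenarioError(ValueError):
    """The scenario specification is internally inconsistent."""


@dataclass
class ScenarioSpec:
    """Study design of a simulated validation campaign.

    Defaults mirror the validated organotin method: seven calibration levels
    spanning 1-4000 ng/g (TBT) and 5-4000 ng/g (TPhT) in six replicate
    curves, QCs at 3/2500/4000 and 15/2500/4000 ng/g measured five times in
    each of three runs, five-level matrix-spike curves at
    {2500, 1000, 500, 100, 50} ng/g over ten sediment matrices, six CRM
    replicates and ten real samples.
    """

    calibration_levels: dict[str, list[float]] = field(
        default_factory=lambda: {
            "TBT": [1.0, 5.0, 25.0, 100.0, 500.0, 2000.0, 4000.0],
            "TPhT": [5.0, 10.0, 50.0, 150.0, 500.0, 2000.0, 4000.0],
        }
    )
    qc_levels: dict[str, list[float]] = field(
        default_factory=lambda: {
            "TBT": [1.0, 3.0, 2500.0, 4000.0],
            "TPhT": [5.0, 15.0, 2500.0, 4000.0],
        }
    )
    n_calibration_replicates: int = 6
    n_qc_replicates: int = 5
    n_runs: int = 3
    me_levels: list[float] = field(default_factory=lambda: [50.0, 100.0, 500.0, 1000.0, 2500.0])
    n_me_replicates: int = 3
    re_level: float = 1000.0
    n_matrices: int = 10
    n_blanks: int = 6
    n_carryover_blanks: int = 6
    n_stability_replicates: int = 5
    stability_levels: dict[str, list[float]] = field(
        default_factory=lambda: {"TBT": [3.0, 4000.0], "TPhT": [15.0, 4000.0]}
    )
    stability_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "long_term_30d": 0.08,
            "short_term_4h": -0.04,
            "freeze_thaw": 0.05,
            "autosampler_24h": 0.01,
            "autosampler_48h": 0.02,
        }
    )
    crm_true_conc: dict[str, float] = field(
        default_factory=lambda: {"TBT": 450.0, "TPhT": 30.0}
    )
    n_crm_replicates: int = 6
    real_sample_truth: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            # ten estuary-like samples; TBT spans ~140-5300 ng/g, TPhT is
            # mostly below the 5 ng/g LLOQ with two quantifiable samples
            "S1": {"TBT": 3296.0, "TPhT": 2.0},
            "S2": {"TBT": 3884.0, "TPhT": 3.0},
            "S3": {"TBT": 142.0, "TPhT": 90.0},
            "S4": {"TBT": 1016.0, "TPhT": 1.0},
            "S5": {"TBT": 345.0, "TPhT": 2.0},
            "S6": {"TBT": 213.0, "TPhT": 1.0},
            "S7": {"TBT": 220.0, "TPhT": 3.0},
            "S8": {"TBT": 750.0, "TPhT": 2.0},
            "S9": {"TBT": 193.0, "TPhT": 2.0},
            "S10": {"TBT": 5263.0, "TPhT": 9.0},
        }
    )
    n_real_replicates: int = 3
    n_sieving_pairs: int = 5
    sieving_me_drop: float = 0.10
    property_noise: float = 0.10

    def validate(self) -> None:
        for analyte, levels in self.calibration_levels.items():
            if any(l <= 0 for l in levels) or sorted(levels) != levels:
                raise ScenarioError(
                    f"calibration levels of {analyte} must be positive and increasing"
                )
            if len(levels) < 3:
                raise ScenarioError(f"{analyte} needs >= 3 calibration levels")
        for n in (
            self.n_calibration_replicates,
            self.n_qc_replicates,
            self.n_me_replicates,
            self.n_crm_replicates,
            self.n_real_replicates,
        ):
            if n < 2:
                raise ScenarioError("replicate counts must be >= 2")
        if self.n_matrices < 2:
            raise ScenarioError("need >= 2 matrices")
        if self.n_sieving_pairs > self.n_matrices:
            raise ScenarioError("sieving pairs cannot exceed the matrix count")


@dataclass
class SimulationTruth:
    """Latent parameters behind one simulated study."""

    seed: int
    slopes: dict[str, float]  # raw-area response per ng/g, aqueous
    intercepts: dict[str, float]
    is_amount_area: float  # expected IS area in water at the added amount
    suppression: dict[str, dict[str, float]]  # analyte -> matrix -> m in (0, 1.3]
    is_cosuppression: dict[str, float]  # matrix -> IS suppression factor
    recovery: dict[str, float]  # matrix -> r in (0, 1.1]
    cv_prop: float = 0.05
    #: share of the proportional noise variance common to the analyte and IS
    #: areas of one injection (volume, spray, source state); the IS ratio
    #: cancels this part, which is what makes ratio CVs much tighter than
    #: raw-area CVs
    injection_noise_share: float = 0.85
    sd_floor: float = 30.0  # detector units; also the baseline noise for S/N
    carryover_fraction: float = 2.25e-5  # of the preceding high-standard area
    blank_interference: float = 0.05  # of the expected LLOQ-level area
    qc_matrix_suppression: float = 0.85  # blank validation sediment
    crm_suppression: float = 0.80
    truncated_at_zero: bool = True

    def validate(self) -> None:
        for analyte, per_matrix in self.suppression.items():
            for mid, m in per_matrix.items():
                if not (0 < m <= 1.3):
                    raise ScenarioError(f"suppression {m} of {analyte}/{mid} outside (0, 1.3]")
        for mid, r in self.recovery.items():
            if not (0 < r <= 1.1):
                raise ScenarioError(f"recovery {r} of {mid} outside (0, 1.1]")
        if self.cv_prop < 0:
            raise ScenarioError("cv_prop must be >= 0")
        if self.sd_floor <= 0:
            raise ScenarioError("sd_floor must be > 0")
        if not (0 <= self.carryover_fraction <= 0.05):
            raise ScenarioError("carryover fraction outside [0, 0.05]")

    def expected_area(
        self,
        analyte: str,
        conc: float,
        matrix_id: Optional[str] = None,
        pre_extraction: bool = False,
        suppression_override: Optional[float] = None,
    ) -> float:
        """Noise-free expected raw area under the measurement model."""
        base = self.slopes[analyte] * conc + self.intercepts[analyte]
        m = 1.0
        if suppression_override is not None:
            m = suppression_override
        elif matrix_id is not None:
            if analyte == IS_NAME:
                m = self.is_cosuppression.get(matrix_id, 1.0)
            else:
                m = self.suppression[analyte][matrix_id]
        r = self.recovery.get(matrix_id, 1.0) if (matrix_id and pre_extraction) else 1.0
        return m * r * base

    def expected_is_area(
        self, matrix_id: Optional[str] = None, pre_extraction: bool = True
    ) -> float:
        m = self.is_cosuppression.get(matrix_id, 1.0) if matrix_id else 1.0
        r = self.recovery.get(matrix_id, 1.0) if (matrix_id and pre_extraction) else 1.0
        return m * r * self.is_amount_area


def matrix_ids(n: int) -> list[str]:
    return [f"M{i + 1:02d}" for i in range(n)]


def default_truth(seed: int, spec: Optional[ScenarioSpec] = None) -> SimulationTruth:
    """Draw a study truth at the default realism level.

    One matrix (M01) carries a fixed strong TBT suppression of 0.58 — the
    worst case the method design must tolerate — while the remaining matrices
    draw suppression from U(0.60, 0.95) and recovery from U(0.85, 1.05). The
    IS co-suppression tracks the TBT suppression up to a lognormal
    mismatch with sigma 0.04, which puts the relative matrix effect near the
    few-percent level a well-chosen isotope-labelled IS achieves.
    """
    spec = spec or ScenarioSpec()
    rng = np.random.default_rng([seed, _BLOCKS["truth"]])
    mids = matrix_ids(spec.n_matrices)
    # suppression is matrix-driven: both analytes and the IS share a
    # per-matrix base factor (co-extracted interference load) up to small
    # analyte-specific lognormal mismatches — that shared structure is what
    # lets a single labelled IS keep the relative matrix effect at the
    # few-percent level for both analytes
    base = {mid: float(rng.uniform(0.60, 0.95)) for mid in mids}
    base[mids[0]] = 0.58
    supp: dict[str, dict[str, float]] = {"TBT": dict(base)}
    for analyte in spec.calibration_levels:
        if analyte == "TBT":
            continue
        supp[analyte] = {
            mid: float(min(base[mid] * math.exp(rng.normal(0.0, 0.05)), 1.3))
            for mid in mids
        }
    cosupp = {
        mid: float(min(base[mid] * math.exp(rng.normal(0.0, 0.04)), 1.3)) for mid in mids
    }
    recovery = {mid: float(rng.uniform(0.85, 1.05)) for mid in mids}
    return SimulationTruth(
        seed=seed,
        slopes={"TBT": 1000.0, "TPhT": 600.0, IS_NAME: 0.0},
        intercepts={"TBT": 50.0, "TPhT": 30.0, IS_NAME: 0.0},
        is_amount_area=50000.0,
        suppression=supp,
        is_cosuppression=cosupp,
        recovery=recovery,
    )


def _noise_split(truth: SimulationTruth) -> tuple[float, float]:
    share = min(max(truth.injection_noise_share, 0.0), 1.0)
    cv_common = truth.cv_prop * math.sqrt(share)
    cv_resid = truth.cv_prop * math.sqrt(1.0 - share)
    return cv_common, cv_resid


def _draw_area(
    rng: np.random.Generator,
    expected: float,
    truth: SimulationTruth,
    injection_factor: float | None = None,
) -> float:
    cv_common, cv_resid = _noise_split(truth)
    g = (
        injection_factor
        if injection_factor is not None
        else 1.0 + rng.normal(0.0, cv_common)
    )
    a = expected * g * (1.0 + rng.normal(0.0, cv_resid)) + rng.normal(0.0, truth.sd_floor)
    return max(a, 0.0) if truth.truncated_at_zero else a


def expected_truncated_area(expected: float, truth: SimulationTruth) -> float:
    """Analytic mean of the observed (zero-truncated) area at a given expectation.

    E[max(0, X)] for X ~ N(mu, sigma^2) with mu = expected and
    sigma^2 = (cv_prop * expected)^2 + sd_floor^2; the truth-recovery oracle
    for blank-like signals where truncation bias is not negligible.
    """
    mu = expected
    sigma = math.sqrt((truth.cv_prop * expected) ** 2 + truth.sd_floor**2)
    if sigma == 0:
        return max(mu, 0.0)
    z = mu / sigma
    phi = math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
    Phi = 0.5 * (1 + math.erf(z / math.sqrt(2)))
    return mu * Phi + sigma * phi


def _record(
    truth: SimulationTruth,
    rng: np.random.Generator,
    *,
    sample_id: str,
    analyte: str,
    role: str,
    run_id: str,
    replicate: int,
    expected: float,
    nominal: Optional[float] = None,
    matrix_id: Optional[str] = None,
    condition: Optional[str] = None,
    medium: str = Medium.MATRIX.value,
    with_is: bool = True,
    is_expected: Optional[float] = None,
) -> MeasurementRecord:
    cv_common, _ = _noise_split(truth)
    g = 1.0 + rng.normal(0.0, cv_common)  # shared per-injection factor
    is_area = None
    if with_is:
        is_exp = is_expected if is_expected is not None else truth.is_amount_area
        is_area = _draw_area(rng, is_exp, truth, injection_factor=g)
    return MeasurementRecord(
        sample_id=sample_id,
        analyte=analyte,
        role=role,
        run_id=run_id,
        replicate=replicate,
        peak_area=_draw_area(rng, expected, truth, injection_factor=g),
        nominal_conc=nominal,
        is_area=is_area,
        noise_sd=truth.sd_floor,
        matrix_id=matrix_id,
        condition=condition,
        medium=medium,
    )


def _analytes(spec: ScenarioSpec) -> list[str]:
    return list(spec.calibration_levels)


def simulate_calibration(truth: SimulationTruth, spec: ScenarioSpec) -> list[MeasurementRecord]:
    rng = np.random.default_rng([truth.seed, _BLOCKS["calibration"]])
    records = []
    for analyte in _analytes(spec):
        for rep in range(1, spec.n_calibration_replicates + 1):
            for level in spec.calibration_levels[analyte]:
                records.append(
                    _record(
                        truth,
                        rng,
                        sample_id=f"cal-{analyte}-{level:g}-{rep}",
                        analyte=analyte,
                        role=Role.CALIBRANT.value,
                        run_id=f"C{rep}",
                        replicate=rep,
                        expected=truth.expected_area(analyte, level),
                        nominal=level,
                        medium=Medium.WATER.value,
                    )
                )
    return records


def simulate_qc(truth: SimulationTruth, spec: ScenarioSpec) -> list[MeasurementRecord]:
    """QC replicates in blank validation sediment, across runs.

    The IS is spiked into the same matrix, so the suppression of the QC
    matrix cancels in the area ratio (the IS tracks it exactly here).
    """
    rng = np.random.default_rng([truth.seed, _BLOCKS["qc"]])
    m = truth.qc_matrix_suppression
    records = []
    for analyte in _analytes(spec):
        for run in range(1, spec.n_runs + 1):
            for level in spec.qc_levels[analyte]:
                for rep in range(1, spec.n_qc_replicates + 1):
                    expected = m * truth.expected_area(analyte, level)
                    records.append(
                        _record(
                            truth,
                            rng,
                            sample_id=f"qc-{analyte}-{level:g}-R{run}-{rep}",
                            analyte=analyte,
                            role=Role.QC.value,
                            run_id=f"R{run}",
                            replicate=rep,
                            expected=expected,
                            nominal=level,
                            matrix_id="QCM",
                            is_expected=m * truth.is_amount_area,
                        )
                    )
    return records


def simulate_blanks(truth: SimulationTruth, spec: ScenarioSpec) -> list[MeasurementRecord]:
    rng = np.random.default_rng([truth.seed, _BLOCKS["blanks"]])
    records = []
    for analyte in _analytes(spec) + [IS_NAME]:
        if analyte == IS_NAME:
            lloq_area = truth.is_amount_area
            interference = 0.01
        else:
            lloq = min(spec.qc_levels[analyte])
            lloq_area = truth.expected_area(analyte, lloq)
            interference = truth.blank_interference
        for rep in range(1, spec.n_blanks + 1):
            records.append(
                _record(
                    truth,
                    rng,
                    sample_id=f"blank-{analyte}-{rep}",
                    analyte=analyte,
                    role=Role.BLANK.value,
                    run_id="R1",
                    replicate=rep,
                    expected=interference * lloq_area,
                    matrix_id="QCM",
                    with_is=False,
                )
            )
    return records


def simulate_carryover(truth: SimulationTruth, spec: ScenarioSpec) -> list[MeasurementRecord]:
    """Blanks injected immediately after the top standard: area = kappa * A_high."""
    rng = np.random.default_rng([truth.seed, _BLOCKS["carryover"]])
    records = []
    for analyte in _analytes(spec) + [IS_NAME]:
        if analyte == IS_NAME:
            high_area = truth.is_amount_area
        else:
            high = max(spec.calibration_levels[analyte])
            high_area = truth.expected_area(analyte, high)
        for rep in range(1, spec.n_carryover_blanks + 1):
            records.append(
                _record(
                    truth,
                    rng,
                    sample_id=f"co-{analyte}-{rep}",
                    analyte=analyte,
                    role=Role.CARRYOVER_BLANK.value,
                    run_id="R1",
                    replicate=rep,
                    expected=truth.carryover_fraction * high_area,
                    medium=Medium.WATER.value,
                    with_is=False,
                )
            )
    return records


def simulate_stability(truth: SimulationTruth, spec: ScenarioSpec) -> list[MeasurementRecord]:
    """Stressed and freshly measured reference sets at low and high levels."""
    rng = np.random.default_rng([truth.seed, _BLOCKS["stability"]])
    m = truth.qc_matrix_suppression
    records = []
    for analyte in _analytes(spec):
        for level in spec.stability_levels[analyte]:
            base = m * truth.expected_area(analyte, level)
            for rep in range(1, spec.n_stability_replicates + 1):
                records.append(
                    _record(
                        truth,
                        rng,
                        sample_id=f"ref-{analyte}-{level:g}-{rep}",
                        analyte=analyte,
                        role=Role.REFERENCE.value,
                        run_id="R1",
                        replicate=rep,
                        expected=base,
                        nominal=level,
                        matrix_id="QCM",
                        condition="fresh",
                        is_expected=m * truth.is_amount_area,
                    )
                )
            for condition, fraction in spec.stability_fractions.items():
                for rep in range(1, spec.n_stability_replicates + 1):
                    records.append(
                        _record(
                            truth,
                            rng,
                            sample_id=f"stab-{analyte}-{level:g}-{condition}-{rep}",
                            analyte=analyte,
                            role=Role.STABILITY.value,
                            run_id="R1",
                            replicate=rep,
                            expected=base * (1.0 + fraction),
                            nominal=level,
                            matrix_id="QCM",
                            condition=condition,
                            is_expected=m * truth.is_amount_area,
                        )
                    )
    return records


def simulate_matrix_block(truth: SimulationTruth, spec: ScenarioSpec) -> list[MeasurementRecord]:
    """Pre/post-extraction spikes per matrix plus the aqueous reference curve.

    Post-extraction spikes see only suppression (area ~ m * base); spikes
    added before extraction see suppression and recovery (area ~ m * r *
    base), so the pre/post ratio at the shared level isolates r. The aqueous
    reference curve at the same five levels uses role ``reference``.
    """
    rng = np.random.default_rng([truth.seed, _BLOCKS["matrix"]])
    mids = matrix_ids(spec.n_matrices)
    records = []
    for analyte in _analytes(spec) + [IS_NAME]:
        # aqueous reference curve for the slope-ratio denominators
        for level in spec.me_levels:
            for rep in range(1, spec.n_me_replicates + 1):
                expected = (
                    truth.is_amount_area
                    if analyte == IS_NAME
                    else truth.expected_area(analyte, level)
                )
                records.append(
                    _record(
                        truth,
                        rng,
                        sample_id=f"mew-{analyte}-{level:g}-{rep}",
                        analyte=analyte,
                        role=Role.REFERENCE.value,
                        run_id="ME",
                        replicate=rep,
                        expected=expected,
                        nominal=level,
                        medium=Medium.WATER.value,
                        condition="me_water",
                        with_is=False,
                    )
                )
        for mid in mids:
            if analyte == IS_NAME:
                m = truth.is_cosuppression[mid]
            else:
                m = truth.suppression[analyte][mid]
            for level in spec.me_levels:
                for rep in range(1, spec.n_me_replicates + 1):
                    base = (
                        truth.is_amount_area
                        if analyte == IS_NAME
                        else truth.expected_area(analyte, level, suppression_override=1.0)
                    )
                    records.append(
                        _record(
                            truth,
                            rng,
                            sample_id=f"post-{analyte}-{mid}-{level:g}-{rep}",
                            analyte=analyte,
                            role=Role.SPIKE_POST.value,
                            run_id="ME",
                            replicate=rep,
                            expected=m * base,
                            nominal=level,
                            matrix_id=mid,
                            with_is=False,
                        )
                    )
            level = spec.re_level
            base = (
                truth.is_amount_area
                if analyte == IS_NAME
                else truth.expected_area(analyte, level, suppression_override=1.0)
            )
            for rep in range(1, spec.n_me_replicates + 1):
                records.append(
                    _record(
                        truth,
                        rng,
                        sample_id=f"pre-{analyte}-{mid}-{level:g}-{rep}",
                        analyte=analyte,
                        role=Role.SPIKE_PRE.value,
                        run_id="ME",
                        replicate=rep,
                        expected=m * truth.recovery[mid] * base,
                        nominal=level,
                        matrix_id=mid,
                        with_is=False,
                    )
                )
    return records


def simulate_sieving(truth: SimulationTruth, spec: ScenarioSpec) -> list[MeasurementRecord]:
    """Post-extraction spike curves on matched matrices before/after fine sieving.

    Sieving removes the coarse fraction and with it part of the co-extracted
    interference load; the generator lowers the suppression factor (stronger
    suppression, lower ME_A) by ``sieving_me_drop`` after sieving.
    """
    rng = np.random.default_rng([truth.seed, _BLOCKS["sieving"]])
    mids = matrix_ids(spec.n_matrices)[: spec.n_sieving_pairs]
    records = []
    for analyte in _analytes(spec):
        for mid in mids:
            m_before = truth.suppression[analyte][mid]
            m_after = max(m_before - spec.sieving_me_drop, 0.05)
            for tag, m in (("unsieved", m_before), ("sieved", m_after)):
                for level in spec.me_levels:
                    for rep in range(1, spec.n_me_replicates + 1):
                        base = truth.expected_area(analyte, level, suppression_override=1.0)
                        records.append(
                            _record(
                                truth,
                                rng,
                                sample_id=f"sieve-{analyte}-{mid}-{tag}-{level:g}-{rep}",
                                analyte=analyte,
                                role=Role.SPIKE_POST.value,
                                run_id="SV",
                                replicate=rep,
                                expected=m * base,
                                nominal=level,
                                matrix_id=mid,
                                condition=tag,
                                with_is=False,
                            )
                        )
    return records


def simulate_crm(truth: SimulationTruth, spec: ScenarioSpec) -> list[MeasurementRecord]:
    rng = np.random.default_rng([truth.seed, _BLOCKS["crm"]])
    m = truth.crm_suppression
    records = []
    for analyte in _analytes(spec):
        conc = spec.crm_true_conc[analyte]
        for rep in range(1, spec.n_crm_replicates + 1):
            records.append(
                _record(
                    truth,
                    rng,
                    sample_id=f"crm-{analyte}-{rep}",
                    analyte=analyte,
                    role=Role.CRM.value,
                    run_id="R1",
                    replicate=rep,
                    expected=m * truth.expected_area(analyte, conc),
                    matrix_id="CRM",
                    is_expected=m * truth.is_amount_area,
                )
            )
    return records


def simulate_real(truth: SimulationTruth, spec: ScenarioSpec) -> list[MeasurementRecord]:
    """Real samples quantified through the IS ratio; suppression cancels."""
    rng = np.random.default_rng([truth.seed, _BLOCKS["real"]])
    mids = matrix_ids(spec.n_matrices)
    records = []
    for idx, (sample_id, concs) in enumerate(spec.real_sample_truth.items()):
        mid = mids[idx % len(mids)]
        for analyte, conc in concs.items():
            m = truth.suppression[analyte][mid]
            is_m = truth.is_cosuppression[mid]
            r = truth.recovery[mid]
            for rep in range(1, spec.n_real_replicates + 1):
                records.append(
                    _record(
                        truth,
                        rng,
                        sample_id=sample_id,
                        analyte=analyte,
                        role=Role.REAL.value,
                        run_id="R1",
                        replicate=rep,
                        expected=m * r * truth.expected_area(analyte, conc, suppression_override=1.0),
                        matrix_id=mid,
                        is_expected=is_m * r * truth.is_amount_area,
                    )
                )
    return records


def simulate_sediment_profiles(
    spec: ScenarioSpec,
    truth: SimulationTruth,
    link: Optional[Callable[[float], float]] = None,
    property_noise: Optional[float] = None,
) -> list[SedimentProfile]:
    """Sediment property vectors tied to the matrices' suppression factors.

    The contamination-linked properties (PAH, TOC, heavy metals, AVS) are
    monotone increasing transforms of the suppression load ``s = 1 - m`` for
    TBT — anthropogenically impacted, organic-rich sediments suppress
    ionization more — while the sand fraction decreases with ``s``. With
    ``property_noise = 0`` the links are exact monotone functions, so
    Spearman(PAH, true ME_A) = -1 by construction. Property ranges bracket
    estuarine monitoring data (TOC up to ~15%, PAH up to ~74,000 ug/kg, sand
    14-51%).
    """
    noise = spec.property_noise if property_noise is None else property_noise
    link = link or (lambda s: s**2)
    rng = np.random.default_rng([truth.seed, _BLOCKS["profiles"]])
    profiles = []
    for mid in matrix_ids(spec.n_matrices):
        s = 1.0 - truth.suppression["TBT"][mid]

        def jitter(scale: float = 1.0) -> float:
            return float(1.0 + rng.normal(0.0, noise * scale))

        pah = 2000.0 + 70000.0 * link(s) * jitter()
        toc = min(0.5 + 30.0 * s * jitter(), 99.0)
        heavy = 1000.0 + 5000.0 * s * jitter()
        avs = min(max(0.05 + 1.5 * s * jitter(), 0.0), 5.0)
        sand = min(max(52.0 - 80.0 * s * jitter(), 5.0), 60.0)
        clay = float(rng.uniform(2.0, 4.0))
        silt = 100.0 - sand - clay
        profiles.append(
            SedimentProfile(
                matrix_id=mid,
                pH=float(rng.normal(6.8, 0.15)),
                conductivity=float(rng.lognormal(0.0, 0.4)),
                toc=toc,
                n=min(max(0.1 + 2.5 * s * jitter(), 0.0), 5.0),
                h=min(max(0.3 + 3.5 * s * jitter(), 0.0), 5.0),
                avs=avs,
                p=min(max(0.1 + 0.8 * s * jitter(), 0.0), 2.0),
                heavy_metals=max(heavy, 0.0),
                pah=max(pah, 0.0),
                sand=sand,
                silt=silt,
                clay=clay,
            )
        )
    return profiles


def degrade_for_stability(
    records: Sequence[MeasurementRecord],
    condition: str,
    fraction: float,
    truth: SimulationTruth,
    seed: Optional[int] = None,
) -> list[MeasurementRecord]:
    """Re-draw a record set with expected areas scaled by (1 + fraction).

    Emulates analyte loss (negative fraction) or apparent gain under a
    storage/stress condition; tags the records with the condition. The
    fraction must lie within +/-30%.
    """
    if not (-0.3 <= fraction <= 0.3):
        raise ScenarioError("degradation fraction must lie in [-0.3, 0.3]")
    rng = np.random.default_rng(
        [
            truth.seed if seed is None else seed,
            _BLOCKS["stability"],
            zlib.crc32(condition.encode()) % (2**31),
        ]
    )
    out = []
    for rec in records:
        expected = rec.peak_area * (1.0 + fraction)
        out.append(
            replace(
                rec,
                peak_area=_draw_area(rng, expected, truth),
                role=Role.STABILITY.value,
                condition=condition,
            )
        )
    return out


def simulate_study(
    truth: SimulationTruth, spec: Optional[ScenarioSpec] = None
) -> tuple[list[MeasurementRecord], list[SedimentProfile], SimulationTruth]:
    """Generate a complete synthetic validation study.

    Returns the long measurement table, the sediment profiles and the truth
    record. Fully reproducible: the same truth (seed) and spec always give
    identical records, and each experiment block draws from its own seed
    substream.
    """
    spec = spec or ScenarioSpec()
    spec.validate()
    truth.validate()
    records: list[MeasurementRecord] = []
    records += simulate_calibration(truth, spec)
    records += simulate_qc(truth, spec)
    records += simulate_blanks(truth, spec)
    records += simulate_carryover(truth, spec)
    records += simulate_stability(truth, spec)
    records += simulate_matrix_block(truth, spec)
    records += simulate_sieving(truth, spec)
    records += simulate_crm(truth, spec)
    records += simulate_real(truth, spec)
    profiles = simulate_sediment_profiles(spec, truth)
    return records, profiles, truth


def simulate_default_study(
    seed: int, spec: Optional[ScenarioSpec] = None
) -> tuple[list[MeasurementRecord], list[SedimentProfile], SimulationTruth, StudyConfig]:
    """Convenience wrapper: default truth, spec and matching study config."""
    spec = spec or ScenarioSpec()
    truth = default_truth(seed, spec)
    records, profiles, truth = simulate_study(truth, spec)
    return records, profiles, truth, default_config()


__all__ = [
    "ScenarioSpec",
    "SimulationTruth",
    "ScenarioError",
    "default_truth",
    "matrix_ids",
    "simulate_study",
    "simulate_default_study",
    "simulate_sediment_profiles",
    "degrade_for_stability",
    "expected_truncated_area",
    "IS_NAME",
]
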