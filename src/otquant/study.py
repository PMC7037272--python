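"""Model/Results facade over the whole validation and application pipeline.

:class:`ValidationStudy` is built from a long measurement table (plus
configuration and optional sediment profiles); :meth:`ValidationStudy.fit`
runs every runnable experiment block — weighted calibration, LLOQ/LOD,
accuracy/precision, selectivity, carry-over, stability, matrix effects,
extraction recovery, CRM trueness, correlation screening and real-sample
quantification — and returns a :class:`StudyResults` carrying the estimates,
their uncertainties and acceptance flags, with a printable ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import calibration as cal
from . import explore_stats as ex
from . import matrix_effects as me
from . import quantify_report as qr
from . import validation_suite as vs
from .io_model import (
    DesignReport,
    MeasurementRecord,
    Role,
    SedimentProfile,
    StudyConfig,
    default_config,
    measurements_to_frame,
    read_measurements,
    read_sediment_profiles,
    validate_study_design,
)
from .synthetic_data import IS_NAME


@dataclass
class StudyResults:
    """Fitted estimates, uncertainties and verdicts of one validation study."""

    config: StudyConfig
    design: DesignReport
    fits: dict[str, cal.CalibrationFit] = field(default_factory=dict)
    limits: dict[str, cal.LimitDecision] = field(default_factory=dict)
    accuracy_cells: list[vs.AccuracyPrecisionCell] = field(default_factory=list)
    selectivity: list[vs.SelectivityResult] = field(default_factory=list)
    carryover: list[vs.CarryOverResult] = field(default_factory=list)
    stability_cells: list[vs.StabilityCell] = field(default_factory=list)
    matrix_effects: list[me.MatrixEffectResult] = field(default_factory=list)
    relative_me: dict[str, me.RelativeMatrixEffect] = field(default_factory=dict)
    sieving: dict[str, me.SievingComparison] = field(default_factory=dict)
    trueness: dict[str, me.TruenessResult] = field(default_factory=dict)
    quant_results: list[qr.QuantResult] = field(default_factory=list)
    summaries: dict[str, qr.AnalyteSummary] = field(default_factory=dict)
    correlations: list[ex.CorrelationCell] = field(default_factory=list)
    pca_model: Optional[ex.PcaModel] = None
    verdict: vs.ValidationVerdict = field(default_factory=vs.ValidationVerdict)

    def me_a_frame(self) -> pd.DataFrame:
        """Per-matrix ME_A/RE values, one column per analyte, matrix index."""
        rows: dict[str, dict[str, float]] = {}
        for r in self.matrix_effects:
            rows.setdefault(r.matrix_id, {})[f"ME_A {r.analyte}"] = r.me_a
            if r.re is not None:
                rows[r.matrix_id][f"RE {r.analyte}"] = r.re
        return pd.DataFrame.from_dict(rows, orient="index").sort_index()

    def report(self) -> str:
        return qr.render_report(
            summaries=self.summaries,
            verdict=self.verdict,
            matrix_results=self.matrix_effects,
            quant_results=self.quant_results,
            limits=self.limits,
            title="Organotin method validation and monitoring report",
        )

    def summary(self) -> str:
        """Compact human-readable overview of every fitted block."""
        lines = ["Validation study results", "=" * 24, ""]
        for analyte, fit in sorted(self.fits.items()):
            lines.append(
                f"{analyte}: slope {fit.slope:.4g} +/- {fit.slope_sd:.2g} "
                f"(p={fit.p_slope:.2g}), intercept {fit.intercept:.4g}, "
                f"R2(w)={fit.r_squared:.4f}, {fit.weighting}, {fit.response_kind}, "
                f"n={fit.n_points}"
            )
            if analyte in self.limits:
                lim = self.limits[analyte]
                lines.append(
                    f"    LLOQ {lim.lloq:g} ng/g (S/N {lim.sn_at_lloq:.1f}, "
                    f"CV {lim.lloq_precision:.1f}%, accuracy {lim.lloq_accuracy:.0f}%), "
                    f"LOD {lim.lod:.2g} ng/g"
                )
        if self.matrix_effects:
            for analyte in sorted({r.analyte for r in self.matrix_effects}):
                vals = [r.me_a for r in self.matrix_effects if r.analyte == analyte]
                lines.append(
                    f"ME_A {analyte}: {min(vals):.0f}-{max(vals):.0f}% "
                    f"(mean {np.mean(vals):.1f}%, SD {np.std(vals, ddof=1):.1f}%)"
                )
                res = [r.re for r in self.matrix_effects if r.analyte == analyte and r.re is not None]
                if res:
                    lines.append(
                        f"RE {analyte}: {min(res):.0f}-{max(res):.0f}% "
                        f"(mean {np.mean(res):.1f}%, SD {np.std(res, ddof=1):.1f}%)"
                    )
        for analyte, rme in sorted(self.relative_me.items()):
            lines.append(
                f"ME_R {analyte}: {rme.me_r:.1f}% over {rme.n_matrices} matrices "
                f"({'pass' if rme.passed else 'FAIL'})"
            )
        for analyte, t in sorted(self.trueness.items()):
            lines.append(
                f"CRM {analyte}: measured {t.measured_mean:.0f} +/- {t.s_m:.0f} ng/g "
                f"(n={t.n}) vs certified {t.certified:g} ng/g; "
                f"delta {t.delta:.1f} <= U_delta {t.u_delta:.1f}: "
                f"{'compatible' if t.compatible else 'NOT compatible'}"
            )
        for analyte, s in sorted(self.summaries.items()):
            mx = f"{s.maximum:.0f}" if s.maximum is not None else "-"
            lines.append(
                f"Samples {analyte}: {s.n_quantified}/{s.n_samples} quantified, "
                f"max {mx} ng/g, {s.n_censored} censored"
            )
        if self.verdict.blocks:
            lines.append(
                "Verdict: "
                + ("PASS" if self.verdict.overall else "FAIL")
                + " ("
                + ", ".join(f"{k}={'ok' if v else 'fail'}" for k, v in sorted(self.verdict.blocks.items()))
                + ")"
            )
        return "\n".join(lines)


class ValidationStudy:
    """A targeted LC-MS/MS validation study ready to be fitted.

    Parameters
    ----------
    measurements:
        Long-format measurement records covering whichever experiment blocks
        were run (missing blocks are skipped, not failed).
    config:
        Study configuration (levels, thresholds, weighting, coverage factor).
    sediments:
        Optional sediment physicochemistry used for the matrix-effect
        correlation screen and PCA.
    """

    def __init__(
        self,
        measurements: Sequence[MeasurementRecord],
        config: Optional[StudyConfig] = None,
        sediments: Sequence[SedimentProfile] = (),
    ) -> None:
        if not measurements:
            raise ValueError("measurements must be non-empty")
        self.measurements = list(measurements)
        self.config = config or default_config()
        self.sediments = list(sediments)
        self._df = measurements_to_frame(self.measurements)

    @classmethod
    def from_csv(
        cls,
        measurements_path: str | Path,
        config: Optional[StudyConfig] = None,
        sediments_path: Optional[str | Path] = None,
    ) -> "ValidationStudy":
        config = config or default_config()
        records = read_measurements(measurements_path, config)
        sediments = read_sediment_profiles(sediments_path) if sediments_path else ()
        return cls(records, config, sediments)

    # -- helpers -----------------------------------------------------------

    def _records(self, **where: object) -> list[MeasurementRecord]:
        out = []
        for r in self.measurements:
            ok = True
            for key, val in where.items():
                got = getattr(r, key)
                if isinstance(val, float) and got is not None:
                    ok = ok and math.isclose(float(got), val)
                else:
                    ok = ok and got == val
                if not ok:
                    break
            if ok:
                out.append(r)
        return out

    def _lloq_level(self, analyte: str) -> float:
        return min(self.config.analytes[analyte].lloq_candidates)

    def _fit_me_curve(
        self, records: Sequence[MeasurementRecord], analyte: str
    ) -> cal.CalibrationFit:
        pts = [(r.nominal_conc, r.peak_area) for r in records if r.nominal_conc]
        return cal.fit_weighted_line(
            pts, weighting=self.config.weighting, analyte=analyte, response_kind="raw_area"
        )

    # -- fit ---------------------------------------------------------------

    def fit(self) -> StudyResults:
        config = self.config
        analytes = list(config.analytes)
        design = validate_study_design(self.measurements, config)
        results = StudyResults(config=config, design=design)

        # calibration and limits
        for analyte in analytes:
            calibrants = self._records(analyte=analyte, role=Role.CALIBRANT.value)
            if not calibrants:
                continue
            kind = "is_ratio" if all(r.is_area for r in calibrants) else "raw_area"
            fit = cal.fit_calibration(calibrants, analyte, config, response_kind=kind)
            results.fits[analyte] = fit
            try:
                results.limits[analyte] = cal.decide_limits(calibrants, fit, config)
            except (cal.NoLimitError, cal.InsufficientDataError):
                pass

        # accuracy / precision
        for analyte, fit in results.fits.items():
            try:
                results.accuracy_cells += vs.accuracy_precision_table(
                    self.measurements, fit, config
                )
            except vs.InsufficientReplicatesError:
                pass

        # selectivity and carry-over (analytes against the LLOQ-level QCs,
        # the IS against its own working-level area)
        blanks = self._records(role=Role.BLANK.value)
        co_blanks = self._records(role=Role.CARRYOVER_BLANK.value)
        for analyte in analytes:
            lloq_qcs = self._records(
                analyte=analyte, role=Role.QC.value, nominal_conc=self._lloq_level(analyte)
            )
            if blanks and lloq_qcs:
                results.selectivity.append(
                    vs.selectivity(blanks, lloq_qcs, config, analyte)
                )
            if co_blanks and lloq_qcs:
                results.carryover.append(
                    vs.carry_over_summary(co_blanks, lloq_qcs, config, analyte)
                )
        is_working = [
            r.is_area
            for r in self._records(role=Role.QC.value)
            if r.is_area is not None
        ]
        if is_working:
            mean_is = float(np.mean(is_working))
            for role_records, out, kind in (
                (blanks, results.selectivity, "sel"),
                (co_blanks, results.carryover, "co"),
            ):
                is_blanks = [r.peak_area for r in role_records if r.analyte == IS_NAME]
                if not is_blanks or mean_is == 0:
                    continue
                pct = 100.0 * float(np.mean(is_blanks)) / mean_is
                if kind == "sel":
                    sd = (
                        float(np.std(100.0 * np.array(is_blanks) / mean_is, ddof=1))
                        if len(is_blanks) > 1
                        else 0.0
                    )
                    out.append(
                        vs.SelectivityResult(
                            analyte=IS_NAME,
                            ratio=pct,
                            sd=sd,
                            n=len(is_blanks),
                            passed=pct < config.thresholds.selectivity_max_is,
                        )
                    )
                else:
                    out.append(
                        vs.CarryOverResult(
                            analyte=IS_NAME,
                            carry_over=pct,
                            passed=pct < config.thresholds.carryover_max_is,
                        )
                    )

        # stability
        for analyte, fit in results.fits.items():
            stab = self._records(analyte=analyte, role=Role.STABILITY.value)
            refs = self._records(
                analyte=analyte, role=Role.REFERENCE.value, condition="fresh"
            )
            levels = sorted({r.nominal_conc for r in stab if r.nominal_conc})
            conditions = sorted({r.condition for r in stab if r.condition})
            for level in levels:
                ref_at = [r for r in refs if math.isclose(r.nominal_conc or -1, level)]
                if not ref_at:
                    continue
                for condition in conditions:
                    test = [
                        r
                        for r in stab
                        if r.condition == condition
                        and math.isclose(r.nominal_conc or -1, level)
                    ]
                    if test:
                        results.stability_cells.append(
                            vs.stability(test, ref_at, condition, fit, config, level=level)
                        )

        # matrix effects, recovery, relative ME, sieving
        me_by_analyte: dict[str, dict[str, float]] = {}
        for analyte in analytes + [IS_NAME]:
            water = [
                r
                for r in self._records(analyte=analyte, role=Role.REFERENCE.value)
                if r.medium == "water" and r.condition == "me_water"
            ]
            posts = [
                r
                for r in self._records(analyte=analyte, role=Role.SPIKE_POST.value)
                if r.condition is None
            ]
            if not water or not posts:
                continue
            per_matrix: dict[str, float] = {}
            if analyte == IS_NAME:
                # the IS is added at one fixed amount: its matrix effect is
                # the area ratio at that amount, not a slope ratio
                water_mean = float(np.mean([r.peak_area for r in water]))
                for mid in sorted({r.matrix_id for r in posts}):
                    mposts = [r for r in posts if r.matrix_id == mid]
                    per_matrix[mid] = (
                        100.0 * float(np.mean([r.peak_area for r in mposts])) / water_mean
                    )
                me_by_analyte[analyte] = per_matrix
                continue
            water_fit = self._fit_me_curve(water, analyte)
            for mid in sorted({r.matrix_id for r in posts}):
                mposts = [r for r in posts if r.matrix_id == mid]
                try:
                    matrix_fit = self._fit_me_curve(mposts, analyte)
                except cal.InsufficientDataError:
                    continue
                per_matrix[mid] = me.absolute_matrix_effect(matrix_fit, water_fit)
            me_by_analyte[analyte] = per_matrix
            pres = [
                r
                for r in self._records(analyte=analyte, role=Role.SPIKE_PRE.value)
                if r.condition is None
            ]
            for mid, me_a in per_matrix.items():
                mpres = [r for r in pres if r.matrix_id == mid]
                mposts_at = [
                    r
                    for r in posts
                    if r.matrix_id == mid
                    and mpres
                    and math.isclose(r.nominal_conc or -1, mpres[0].nominal_conc or -2)
                ]
                re_pct = (
                    me.extraction_recovery(mpres, mposts_at) if mpres and mposts_at else None
                )
                results.matrix_effects.append(
                    me.MatrixEffectResult(matrix_id=mid, analyte=analyte, me_a=me_a, re=re_pct)
                )
        for analyte in analytes:
            if analyte in me_by_analyte and IS_NAME in me_by_analyte:
                shared = set(me_by_analyte[analyte]) & set(me_by_analyte[IS_NAME])
                if len(shared) >= 2:
                    results.relative_me[analyte] = me.relative_matrix_effect(
                        {k: me_by_analyte[analyte][k] for k in shared},
                        {k: me_by_analyte[IS_NAME][k] for k in shared},
                        analyte=analyte,
                        me_r_max=config.thresholds.me_r_max,
                    )

        # sieving comparison (post-extraction spikes tagged sieved/unsieved)
        for analyte in analytes:
            water = [
                r
                for r in self._records(analyte=analyte, role=Role.REFERENCE.value)
                if r.medium == "water" and r.condition == "me_water"
            ]
            if not water:
                continue
            water_fit = self._fit_me_curve(water, analyte)
            pairs: dict[str, dict[str, float]] = {"unsieved": {}, "sieved": {}}
            for tag in pairs:
                tagged = self._records(
                    analyte=analyte, role=Role.SPIKE_POST.value, condition=tag
                )
                for mid in sorted({r.matrix_id for r in tagged}):
                    sub = [r for r in tagged if r.matrix_id == mid]
                    try:
                        fit_t = self._fit_me_curve(sub, analyte)
                    except cal.InsufficientDataError:
                        continue
                    pairs[tag][mid] = me.absolute_matrix_effect(fit_t, water_fit)
            shared = set(pairs["unsieved"]) & set(pairs["sieved"])
            if len(shared) >= 2:
                results.sieving[analyte] = me.compare_sieving(
                    {k: pairs["unsieved"][k] for k in shared},
                    {k: pairs["sieved"][k] for k in shared},
                    analyte=analyte,
                )

        # CRM trueness
        for analyte, fit in results.fits.items():
            settings = config.analytes[analyte]
            crm = self._records(analyte=analyte, role=Role.CRM.value)
            if len(crm) >= 2 and settings.crm_certified is not None:
                measured = [
                    cal.back_calculate(fit, cal.response_of(r, fit.response_kind))
                    for r in crm
                ]
                results.trueness[analyte] = me.trueness_vs_crm(
                    measured,
                    certified=settings.crm_certified,
                    u_ref=settings.crm_u_ref or 0.0,
                    k=config.coverage_k,
                    analyte=analyte,
                )

        # real samples
        for analyte, fit in results.fits.items():
            if analyte in results.limits and self._records(
                analyte=analyte, role=Role.REAL.value
            ):
                results.quant_results += qr.quantify(
                    self.measurements, fit, results.limits[analyte]
                )
        if results.quant_results:
            results.summaries = qr.summarize(results.quant_results)

        # exploratory statistics against sediment properties
        if self.sediments and results.matrix_effects:
            responses = results.me_a_frame()
            results.correlations = ex.correlation_screen(responses, self.sediments)
            try:
                results.pca_model = ex.pca(self.sediments)
            except (ex.InsufficientDataError, ex.DegenerateVariableError):
                results.pca_model = None

        results.verdict = vs.evaluate_acceptance(
            config,
            calibration_fits=list(results.fits.values()),
            accuracy_cells=results.accuracy_cells,
            selectivity_results=results.selectivity,
            carryover_results=results.carryover,
            stability_cells=results.stability_cells,
            me_r_passed=(
                all(r.passed for r in results.relative_me.values())
                if results.relative_me
                else None
            ),
        )
        return results


__all__ = ["ValidationStudy", "StudyResults"]
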