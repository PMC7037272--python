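"""Accuracy/precision, selectivity, carry-over, stability and acceptance logic."""

import numpy as np
import pytest

from otquant.calibration import fit_weighted_line
from otquant.io_model import MeasurementRecord, default_config
from otquant.validation_suite import (
    DegenerateRatioError,
    InsufficientReplicatesError,
    accuracy_precision,
    carry_over,
    carry_over_summary,
    evaluate_acceptance,
    selectivity,
    stability,
)

IDENTITY_FIT = fit_weighted_line(
    [(1.0, 1.0), (10.0, 10.0), (100.0, 100.0), (1000.0, 1000.0)],
    weighting="one_over_x",
    response_kind="raw_area",
)


def qc(level, values, run="R1", analyte="TBT", role="qc"):
    """QC records whose raw-area response equals the back-calculated conc."""
    return [
        MeasurementRecord(
            sample_id=f"qc-{run}-{i}", analyte=analyte, role=role, run_id=run,
            replicate=i + 1, peak_area=float(v), nominal_conc=level, matrix_id="QCM",
        )
        for i, v in enumerate(values)
    ]


class TestAccuracyPrecision:
    def test_identical_replicates_give_perfect_cell(self, config):
        cell = accuracy_precision(qc(100.0, [100, 100, 100]), IDENTITY_FIT, 100.0, "within_run", config)
        assert cell.accuracy == pytest.approx(100.0)
        assert cell.precision == pytest.approx(0.0)
        assert cell.passed

    def test_hand_arithmetic_spread(self, config):
        cell = accuracy_precision(qc(100.0, [90, 100, 110]), IDENTITY_FIT, 100.0, "within_run", config)
        assert cell.accuracy == pytest.approx(100.0)
        assert cell.precision == pytest.approx(10.0)  # sd = 10 on mean 100
        assert cell.passed

    def test_accuracy_outside_window_fails_qc_level(self, config):
        cell = accuracy_precision(qc(100.0, [117, 117, 117]), IDENTITY_FIT, 100.0, "within_run", config)
        assert cell.accuracy == pytest.approx(117.0)
        assert not cell.passed  # window 85-115% at QC levels

    def test_lloq_level_uses_wider_window(self, config):
        cell = accuracy_precision(qc(1.0, [1.17, 1.17, 1.17]), IDENTITY_FIT, 1.0, "within_run", config)
        assert cell.passed  # 80-120% at the LLOQ

    def test_single_replicate_rejected(self, config):
        with pytest.raises(InsufficientReplicatesError):
            accuracy_precision(qc(100.0, [100]), IDENTITY_FIT, 100.0, "within_run", config)

    def test_between_run_pooling_of_identical_runs_matches_within_run(self, config):
        """Pooling k runs with identical data per run equals the within-run cell."""
        one_run = qc(100.0, [95, 100, 105], run="R1")
        pooled = one_run + qc(100.0, [95, 100, 105], run="R2") + qc(100.0, [95, 100, 105], run="R3")
        within = accuracy_precision(one_run, IDENTITY_FIT, 100.0, "within_run", config)
        between = accuracy_precision(pooled, IDENTITY_FIT, 100.0, "between_run", config)
        assert between.accuracy == pytest.approx(within.accuracy)
        # pooled sd over 9 values equals the within-run sd up to the n-1 factor
        vals = np.array([95, 100, 105] * 3, dtype=float)
        assert between.precision == pytest.approx(100 * vals.std(ddof=1) / vals.mean())


class TestSelectivityCarryOver:
    def test_all_zero_blanks_pass(self, config):
        res = selectivity(qc(1.0, [0, 0, 0], role="blank"), qc(1.0, [1000] * 3), config, "TBT")
        assert res.ratio == 0.0 and res.passed

    def test_blank_fraction_of_lloq_signal(self, config):
        blanks = qc(1.0, [61, 61, 61], role="blank")
        lloqs = qc(1.0, [1000, 1000, 1000])
        res = selectivity(blanks, lloqs, config, "TBT")
        assert res.ratio == pytest.approx(6.1)
        assert res.passed

    def test_is_threshold_is_tighter(self, config):
        blanks = qc(1.0, [60, 60], role="blank", analyte="TBT_d27")
        lloqs = qc(1.0, [1000, 1000], analyte="TBT_d27")
        res = selectivity(blanks, lloqs, config, "TBT_d27", is_internal_standard=True)
        assert res.ratio == pytest.approx(6.0)
        assert not res.passed  # 6% > 5% IS limit

    def test_carry_over_printed_ratio(self, config):
        blank = qc(1.0, [12.1], role="carryover_blank")[0]
        lloq = qc(1.0, [1000])[0]
        res = carry_over(blank, lloq, config)
        assert res.carry_over == pytest.approx(1.21)
        assert res.passed

    def test_carry_over_above_analyte_limit_fails(self, config):
        res = carry_over(qc(1.0, [250], role="carryover_blank")[0], qc(1.0, [1000])[0], config)
        assert res.carry_over == pytest.approx(25.0)
        assert not res.passed

    def test_zero_lloq_area_degenerate(self, config):
        with pytest.raises(DegenerateRatioError):
            carry_over(qc(1.0, [1], role="carryover_blank")[0], qc(1.0, [0])[0], config)

    def test_scale_invariance(self, config):
        """Multiplying every area by c > 0 leaves both statistics unchanged."""
        for c in (0.5, 3.0, 1e4):
            blanks = qc(1.0, [np.float64(12.1) * c], role="carryover_blank")
            lloqs = qc(1.0, [1000.0 * c, 980.0 * c])
            res = carry_over_summary(blanks, lloqs, config, "TBT")
            assert res.carry_over == pytest.approx(100 * 12.1 / 990)
            sel = selectivity(qc(1.0, [61 * c, 59 * c], role="blank"), lloqs, config, "TBT")
            assert sel.ratio == pytest.approx(100 * 60 / 990)


class TestStability:
    def test_test_equals_reference_gives_100(self, config):
        cell = stability(
            qc(100.0, [100, 100], role="stability"), qc(100.0, [100, 100], role="reference"),
            "freeze_thaw", IDENTITY_FIT, config,
        )
        assert cell.stability == pytest.approx(100.0)
        assert cell.passed

    @pytest.mark.parametrize("ratio,passed", [(1.06, True), (1.14, True), (0.80, False), (1.16, False)])
    def test_window_85_115(self, config, ratio, passed):
        cell = stability(
            qc(100.0, [100 * ratio] * 3, role="stability"),
            qc(100.0, [100.0] * 3, role="reference"),
            "long_term_30d", IDENTITY_FIT, config,
        )
        assert cell.stability == pytest.approx(100 * ratio)
        assert cell.passed is passed


class TestEvaluateAcceptance:
    def test_all_passing_cells_pass_overall(self, config):
        cells = [accuracy_precision(qc(100.0, [100, 101]), IDENTITY_FIT, 100.0, "within_run", config)]
        stab = [
            stability(qc(100.0, [106.0] * 2, role="stability"), qc(100.0, [100.0] * 2, role="reference"),
                      "x", IDENTITY_FIT, config)
        ]
        verdict = evaluate_acceptance(config, accuracy_cells=cells, stability_cells=stab)
        assert verdict.overall

    def test_one_failing_stability_cell_fails_the_block(self, config):
        stab = [
            stability(qc(100.0, [80.0] * 2, role="stability"), qc(100.0, [100.0] * 2, role="reference"),
                      "x", IDENTITY_FIT, config)
        ]
        verdict = evaluate_acceptance(config, stability_cells=stab)
        assert not verdict.overall
        assert verdict.failing_blocks() == ["stability"]

    def test_verdict_is_deterministic_in_its_inputs(self, config):
        cells = [accuracy_precision(qc(100.0, [100, 101]), IDENTITY_FIT, 100.0, "within_run", config)]
        v1 = evaluate_acceptance(config, accuracy_cells=cells)
        v2 = evaluate_acceptance(config, accuracy_cells=cells)
        assert v1.blocks == v2.blocks and v1.overall == v2.overall
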