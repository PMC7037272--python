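"""Slope-ratio matrix effects, recovery, CRM trueness and the sieving t-test."""

import math

import numpy as np
import pytest

from otquant.calibration import fit_weighted_line
from otquant.io_model import MeasurementRecord
from otquant.matrix_effects import (
    PairingError,
    absolute_matrix_effect,
    compare_sieving,
    extraction_recovery,
    relative_matrix_effect,
    trueness_vs_crm,
)


def spikes(areas, role="spike_pre", analyte="TBT"):
    return [
        MeasurementRecord(
            sample_id=f"{role}-{i}", analyte=analyte, role=role, run_id="ME",
            replicate=i + 1, peak_area=float(a), nominal_conc=1000.0, matrix_id="M01",
        )
        for i, a in enumerate(areas)
    ]


def raw_fit(slope, intercept=0.0):
    pts = [(x, slope * x + intercept) for x in (50.0, 100.0, 500.0, 1000.0, 2500.0)]
    return fit_weighted_line(pts, weighting="one_over_x", response_kind="raw_area")


class TestExtractionRecovery:
    def test_identical_sets_give_100(self):
        assert extraction_recovery(spikes([100, 100]), spikes([100, 100], "spike_post")) == pytest.approx(100.0)

    def test_printed_mean_ratio(self):
        pre = spikes([932, 932, 932])
        post = spikes([1000, 1000, 1000], "spike_post")
        assert extraction_recovery(pre, post) == pytest.approx(93.2)

    def test_hand_arithmetic(self):
        assert extraction_recovery(spikes([50, 60]), spikes([100, 100], "spike_post")) == pytest.approx(55.0)

    def test_scale_invariance(self):
        base = extraction_recovery(spikes([50, 60]), spikes([100, 100], "spike_post"))
        scaled = extraction_recovery(spikes([500, 600]), spikes([1000, 1000], "spike_post"))
        assert base == pytest.approx(scaled)


class TestAbsoluteMatrixEffect:
    def test_identical_slopes_mean_no_matrix_effect(self):
        assert absolute_matrix_effect(raw_fit(2.0), raw_fit(2.0)) == pytest.approx(100.0)

    def test_suppressed_slope_ratio(self):
        assert absolute_matrix_effect(raw_fit(0.58 * 2.0), raw_fit(2.0)) == pytest.approx(58.0)

    def test_enhancement_above_100(self):
        assert absolute_matrix_effect(raw_fit(1.2 * 2.0), raw_fit(2.0)) == pytest.approx(120.0)

    def test_is_ratio_curves_rejected(self):
        pts = [(x, 2.0 * x) for x in (50.0, 100.0, 500.0)]
        ratio_fit = fit_weighted_line(pts, response_kind="is_ratio")
        with pytest.raises(Exception, match="raw_area"):
            absolute_matrix_effect(ratio_fit, raw_fit(2.0))


class TestRelativeMatrixEffect:
    def test_is_tracking_analyte_everywhere_gives_zero(self):
        me_a = {"M1": 58.0, "M2": 75.0, "M3": 92.0}
        me_is = {k: v * 0.7 for k, v in me_a.items()}  # same suppression pattern
        res = relative_matrix_effect(me_a, me_is)
        assert res.me_r == pytest.approx(0.0, abs=1e-12)
        assert res.passed

    def test_hand_cv_of_ratios(self):
        res = relative_matrix_effect({"a": 0.9, "b": 1.0, "c": 1.1}, {"a": 1.0, "b": 1.0, "c": 1.0})
        assert res.me_r == pytest.approx(10.0)  # mean 1.0, sd 0.1
        assert res.passed

    def test_large_spread_fails(self):
        res = relative_matrix_effect({"a": 0.5, "b": 1.0, "c": 1.5}, {"a": 1.0, "b": 1.0, "c": 1.0})
        assert res.me_r == pytest.approx(50.0)
        assert not res.passed

    def test_mismatched_matrices_rejected(self):
        with pytest.raises(PairingError):
            relative_matrix_effect({"a": 1.0, "b": 1.0}, {"a": 1.0, "c": 1.0})


class TestTruenessVsCrm:
    def test_zero_bias_always_compatible(self):
        res = trueness_vs_crm([480.0, 480.0, 480.0], certified=480.0, u_ref=0.0, k=2.0)
        assert res.delta == pytest.approx(0.0)
        assert res.compatible

    def test_tbt_certificate_case(self):
        # certified 480 +/- 40 ng/g, k = 2, n = 6, measured around 450
        measured = [450 + d for d in (-30, -18, -6, 6, 18, 30)]
        res = trueness_vs_crm(measured, certified=480.0, u_ref=40.0, k=2.0)
        assert res.delta == pytest.approx(30.0)
        s_m = np.std(measured, ddof=1)
        assert res.u_delta == pytest.approx(2 * math.sqrt(40**2 + s_m**2 / 6))
        assert res.compatible  # k*u_ref = 80 >= 30 regardless of s_m

    def test_tpht_certificate_case(self):
        measured = [30 + d for d in (-2, -1, 0, 0, 1, 2)]
        res = trueness_vs_crm(measured, certified=29.0, u_ref=5.5, k=2.0)
        assert res.delta == pytest.approx(1.0)
        assert res.compatible

    def test_compatibility_monotone_in_u_ref_and_k(self):
        measured = [450.0, 452.0, 448.0, 451.0]
        verdicts_u = [trueness_vs_crm(measured, 480.0, u, 2.0).compatible for u in (0.0, 5.0, 15.0, 40.0)]
        assert verdicts_u == sorted(verdicts_u)  # False before True
        verdicts_k = [trueness_vs_crm(measured, 480.0, 10.0, k).compatible for k in (0.5, 1.0, 2.0, 4.0)]
        assert verdicts_k == sorted(verdicts_k)

    def test_u_delta_never_below_k_u_ref(self, rng):
        for _ in range(20):
            measured = rng.normal(100, 10, size=int(rng.integers(2, 8)))
            res = trueness_vs_crm(list(measured), 100.0, u_ref=7.0, k=2.0)
            assert res.u_delta >= 2.0 * 7.0


def paired_t_oracle(diffs):
    """Closed-form paired t on the differences, via the t distribution."""
    from scipy.stats import t as tdist

    d = np.asarray(diffs, dtype=float)
    n = len(d)
    t_stat = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2 * tdist.sf(abs(t_stat), df=n - 1)
    return t_stat, p


class TestCompareSieving:
    def test_no_change_gives_t0_p1(self):
        same = {"a": 70.0, "b": 80.0, "c": 90.0}
        res = compare_sieving(same, dict(same))
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_hand_paired_t(self):
        before = {m: b for m, b in zip("abcde", [80.0, 75.0, 77.0, 70.0, 84.0])}
        after = {m: a for m, a in zip("abcde", [70.0, 65.0, 66.0, 62.0, 65.0])}
        res = compare_sieving(before, after)
        t_stat, p = paired_t_oracle([80 - 70, 75 - 65, 77 - 66, 70 - 62, 84 - 65])
        assert res.t_statistic == pytest.approx(t_stat)
        assert res.p_value == pytest.approx(p)
        assert res.mean_before == pytest.approx(77.2)

    def test_single_pair_rejected(self):
        with pytest.raises(PairingError):
            compare_sieving({"a": 80.0}, {"a": 70.0})
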