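"""Weighted calibration fits, back-calculation and LLOQ/LOD decisions."""

import numpy as np
import pytest

from otquant.calibration import (
    DegenerateFitError,
    InsufficientDataError,
    NoLimitError,
    back_calculate,
    decide_limits,
    fit_weighted_line,
)
from otquant.io_model import AcceptanceThresholds, MeasurementRecord, default_config

from .test_io_model import make_calibrant


def wls_normal_equations(x, y, w):
    """Independent closed-form solution of the weighted normal equations."""
    sw = np.sum(w)
    sx = np.sum(w * x)
    sy = np.sum(w * y)
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    denom = sw * sxx - sx**2
    a = (sw * sxy - sx * sy) / denom
    b = (sxx * sy - sx * sxy) / denom
    return a, b


class TestFitWeightedLine:
    def test_noiseless_line_recovered_exactly(self):
        pts = [(1.0, 3.0), (10.0, 21.0), (100.0, 201.0)]
        fit = fit_weighted_line(pts, weighting="one_over_x")
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_unweighted_fit_matches_ols_closed_form(self, rng):
        x = rng.uniform(1, 100, size=12)
        y = 3.0 * x + 5.0 + rng.normal(0, 2, size=12)
        fit = fit_weighted_line(list(zip(x, y)), weighting="none")
        a, b = wls_normal_equations(x, y, np.ones_like(x))
        assert fit.slope == pytest.approx(a)
        assert fit.intercept == pytest.approx(b)

    @pytest.mark.parametrize("weighting", ["none", "one_over_x", "one_over_x2"])
    def test_weighted_fit_matches_normal_equations_on_random_instances(self, rng, weighting):
        for _ in range(25):
            n = int(rng.integers(4, 20))
            x = rng.uniform(0.5, 4000, size=n)
            y = rng.uniform(0.1, 2.0) * x + rng.normal(0, 5, size=n)
            fit = fit_weighted_line(list(zip(x, y)), weighting=weighting)
            w = {"none": np.ones_like(x), "one_over_x": 1 / x, "one_over_x2": 1 / x**2}[weighting]
            a, b = wls_normal_equations(x, y, w)
            assert fit.slope == pytest.approx(a, rel=1e-9)
            assert fit.intercept == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_fewer_than_three_distinct_levels_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_weighted_line([(1.0, 1.0), (1.0, 1.1), (2.0, 2.0)])

    def test_zero_concentration_incompatible_with_one_over_x(self):
        with pytest.raises(DegenerateFitError):
            fit_weighted_line([(0.0, 0.1), (1.0, 1.0), (2.0, 2.0)], weighting="one_over_x")

    def test_slope_significant_across_replicate_heteroscedastic_curves(self, rng):
        """At study noise levels every replicate curve has p(slope) < 0.05."""
        levels = np.array([1.0, 5.0, 25.0, 100.0, 500.0, 2000.0, 4000.0])
        for _ in range(6):
            y = (0.02 * levels) * (1 + rng.normal(0, 0.05, size=7)) + rng.normal(0, 0.001, 7)
            fit = fit_weighted_line(list(zip(levels, y)), weighting="one_over_x")
            assert fit.p_slope < 0.05

    def test_one_over_x_weights_tighten_low_end_accuracy(self, rng):
        """Back-calculated accuracy at the lowest level has smaller spread
        under 1/x weights than unweighted, over 200 heteroscedastic curves."""
        levels = np.array([1.0, 5.0, 25.0, 100.0, 500.0, 2000.0, 4000.0])
        err_w, err_u = [], []
        for _ in range(200):
            y = (2.0 * levels + 1.0) * (1 + rng.normal(0, 0.08, size=7))
            pts = list(zip(levels, y))
            fw = fit_weighted_line(pts, weighting="one_over_x")
            fu = fit_weighted_line(pts, weighting="none")
            err_w.append(back_calculate(fw, 2.0 * 1.0 + 1.0) - 1.0)
            err_u.append(back_calculate(fu, 2.0 * 1.0 + 1.0) - 1.0)
        assert np.std(err_w) < np.std(err_u)


class TestBackCalculate:
    def test_exact_inverse(self):
        fit = fit_weighted_line([(1.0, 3.0), (10.0, 21.0), (100.0, 201.0)])
        assert back_calculate(fit, 21.0) == pytest.approx(10.0)
        assert back_calculate(fit, fit.intercept) == pytest.approx(0.0)

    @pytest.mark.parametrize("x", [1.0, 50.0, 4000.0])
    def test_round_trip_identity(self, x):
        fit = fit_weighted_line([(1.0, 3.0), (10.0, 21.0), (100.0, 201.0)])
        assert back_calculate(fit, fit.slope * x + fit.intercept) == pytest.approx(x)


def lloq_records(level=1.0, areas=(1000, 1020, 980, 1010, 995), noise=190.0):
    return [
        MeasurementRecord(
            sample_id=f"L{i}", analyte="TBT", role="calibrant", run_id="C1",
            replicate=i + 1, peak_area=float(a), nominal_conc=level,
            noise_sd=noise, medium="water",
        )
        for i, a in enumerate(areas)
    ]


def upper_records():
    recs = []
    for i, lvl in enumerate([10.0, 100.0, 1000.0]):
        for rep in range(2):
            recs.append(
                MeasurementRecord(
                    sample_id=f"U{i}{rep}", analyte="TBT", role="calibrant",
                    run_id="C1", replicate=rep + 1, peak_area=1000.0 * lvl,
                    nominal_conc=lvl, noise_sd=190.0, medium="water",
                )
            )
    return recs


class TestDecideLimits:
    def setup_method(self):
        self.config = default_config()
        pts = [(lvl, 1000.0 * lvl) for lvl in [1.0, 10.0, 100.0, 1000.0]]
        self.fit = fit_weighted_line(pts, weighting="one_over_x", response_kind="raw_area")

    def test_level_meeting_all_three_criteria_is_lloq(self):
        recs = lloq_records()  # S/N ~ 5.3, CV ~ 1.5%, accuracy ~ 100%
        limits = decide_limits(recs + upper_records(), self.fit, self.config)
        assert limits.lloq == 1.0
        assert limits.sn_at_lloq == pytest.approx(5.27, abs=0.05)
        assert limits.lloq_precision < 20
        assert 80 <= limits.lloq_accuracy <= 120

    def test_lod_scales_sn_linearly_from_lloq(self):
        recs = lloq_records(noise=200.2)  # S/N = 5.0 within rounding
        limits = decide_limits(recs + upper_records(), self.fit, self.config)
        assert limits.lod == pytest.approx(limits.lloq * 3.0 / limits.sn_at_lloq)
        assert limits.lod == pytest.approx(0.6, abs=0.01)

    def test_high_cv_rejected_regardless_of_sn(self):
        recs = lloq_records(areas=(600, 1400, 700, 1300, 1000), noise=100.0)
        with pytest.raises(NoLimitError, match="CV"):
            decide_limits(recs + upper_records(), self.fit, self.config)

    def test_low_sn_rejected(self):
        recs = lloq_records(noise=500.0)  # S/N ~ 2
        with pytest.raises(NoLimitError, match="S/N"):
            decide_limits(recs + upper_records(), self.fit, self.config)

    def test_raising_sn_threshold_never_lowers_the_lloq(self):
        cfg = default_config()
        cfg.analytes["TBT"].lloq_candidates = [1.0, 5.0]
        recs = lloq_records() + lloq_records(level=5.0, areas=(5000, 5100, 4900, 5050, 4950))
        recs += upper_records()
        lloqs = []
        for sn_min in (3.0, 5.0, 10.0):
            c = cfg.model_copy(deep=True)
            c.thresholds.sn_min_lloq = sn_min
            try:
                lloqs.append(decide_limits(recs, self.fit, c).lloq)
            except NoLimitError:
                lloqs.append(float("inf"))
        assert lloqs == sorted(lloqs)
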