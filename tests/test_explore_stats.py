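"""Spearman screening, PCA decomposition/biplot and Welch comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from otquant.explore_stats import (
    DegenerateVariableError,
    InsufficientDataError,
    UndefinedCorrelationError,
    biplot_data,
    correlation_screen,
    pca,
    spearman,
    welch_t_from_summary,
)


def rank_oracle(values):
    """Average ranks computed by explicit enumeration."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def spearman_oracle(x, y):
    rx, ry = np.array(rank_oracle(x)), np.array(rank_oracle(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearman:
    def test_strictly_monotone_sequences(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, [10, 20, 30, 40, 50]).rho == pytest.approx(1.0)
        assert spearman(x, [50, 40, 30, 20, 10]).rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # d^2 = (1,1,1,1,0): rho = 1 - 6*4/(5*24) = 0.8
        cell = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert cell.rho == pytest.approx(0.8)
        assert cell.rho == pytest.approx(spearman_oracle([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))

    def test_matches_rank_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 15))
            x = rng.integers(0, 5, size=n).astype(float)  # force ties
            y = rng.integers(0, 5, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman(x, y).rho == pytest.approx(spearman_oracle(x, y))

    def test_missing_pairs_dropped_then_minimum_n_enforced(self):
        x = [1.0, 2.0, np.nan, 4.0]
        y = [1.0, np.nan, 3.0, 4.0]
        with pytest.raises(InsufficientDataError):
            spearman(x, y)

    def test_constant_input_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=12, unique=True))
    def test_invariant_under_strictly_monotone_transforms(self, xs):
        xs = [float(x) for x in xs]
        ys = list(np.linspace(0, 1, len(xs)) ** 2)
        base = spearman(xs, ys).rho
        assert spearman([math.exp(x / 1e3) for x in xs], ys).rho == pytest.approx(base)
        assert spearman(xs, [3 * y + 1 for y in ys]).rho == pytest.approx(base)
        assert spearman([-x for x in xs], ys).rho == pytest.approx(-base)


class TestCorrelationScreen:
    def test_response_identical_to_property_gives_rho_1(self):
        prof = pd.DataFrame({"pah": [1.0, 2.0, 3.0, 4.0, 5.0], "toc": [5.0, 3.0, 4.0, 1.0, 2.0]},
                            index=[f"M{i}" for i in range(5)])
        resp = pd.DataFrame({"ME_A TBT": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=prof.index)
        cells = {(c.response, c.property): c for c in correlation_screen(resp, prof)}
        assert cells[("ME_A TBT", "pah")].rho == pytest.approx(1.0)

    def test_all_missing_property_absent_from_output(self):
        prof = pd.DataFrame({"pah": [np.nan] * 5, "toc": [1.0, 2.0, 3.0, 4.0, 5.0]},
                            index=[f"M{i}" for i in range(5)])
        resp = pd.DataFrame({"ME_A TBT": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=prof.index)
        props = {c.property for c in correlation_screen(resp, prof)}
        assert props == {"toc"}

    def test_shuffled_labels_destroy_significance_at_nominal_rate(self, rng):
        """With labels permuted, ~5% of screens are significant at p < 0.05."""
        n = 12
        hits = 0
        trials = 200
        for _ in range(trials):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if spearman(x, y).p_value < 0.05:
                hits += 1
        assert hits / trials < 0.12  # binomial(200, 0.05) stays under 12% w.h.p.


class TestPca:
    def test_perfectly_correlated_pair_loads_on_one_component(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]},
                          index=list("wxyz"))
        model = pca(df)
        assert model.variance_explained[0] == pytest.approx(100.0)

    def test_variance_explained_sums_to_100(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        model = pca(df)
        assert model.variance_explained.sum() == pytest.approx(100.0)

    def test_reconstruction_from_all_components(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        model = pca(df)
        z = (df - df.mean()) / df.std(ddof=1)
        recon = model.scores @ model.loadings.T
        assert np.allclose(recon, z.to_numpy())

    def test_loadings_orthonormal(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 5)), columns=list("abcde"))
        model = pca(df)
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(model.loadings.shape[1]), atol=1e-10)

    def test_rotation_invariance_of_variance_profile(self, rng):
        x = rng.normal(size=(10, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        a = pca(pd.DataFrame(x, columns=list("abcd")))
        b = pca(pd.DataFrame(x @ q, columns=list("abcd")))
        # standardization changes per-variable scale, so compare covariance
        # PCA behaviour via the unstandardized singular values of centred data
        xc = x - x.mean(0)
        xr = (x @ q) - (x @ q).mean(0)
        sa = np.linalg.svd(xc, compute_uv=False) ** 2
        sb = np.linalg.svd(xr, compute_uv=False) ** 2
        assert np.allclose(100 * sa / sa.sum(), 100 * sb / sb.sum())
        assert a.variance_explained.sum() == pytest.approx(b.variance_explained.sum())

    def test_zero_variance_variable_named(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateVariableError, match="a"):
            pca(df)

    def test_listwise_missing_exclusion(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, np.nan], "b": [2.0, 1.0, 4.0, 5.0],
                           "c": [1.0, 3.0, 2.0, 4.0]})
        model = pca(df)
        assert model.scores.shape[0] == 3


class TestBiplot:
    def test_out_of_range_component_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("abc"))
        model = pca(df)
        with pytest.raises(IndexError):
            biplot_data(model, (2, 4))

    def test_arrow_lengths_bounded_by_singular_scale(self, rng):
        df = pd.DataFrame(rng.normal(size=(7, 4)), columns=list("abcd"))
        model = pca(df)
        data = biplot_data(model, (1, 2))
        n = model.scores.shape[0]
        bounds = model.singular_values[:2] / np.sqrt(n - 1)
        arrows = data["arrows"].to_numpy()
        assert np.all(np.abs(arrows[:, 0]) <= bounds[0] + 1e-12)
        assert np.all(np.abs(arrows[:, 1]) <= bounds[1] + 1e-12)

    def test_uncorrelated_variables_give_orthogonal_arrows(self):
        df = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0], "b": [1.0, 1.0, -1.0, -1.0]})
        model = pca(df)
        arrows = biplot_data(model, (1, 2))["arrows"].to_numpy()
        assert np.dot(arrows[0], arrows[1]) == pytest.approx(0.0, abs=1e-10)


class TestWelch:
    def test_identical_groups_p_1(self):
        t, p = welch_t_from_summary(10.0, 0.0, 5, 10.0, 0.0, 5)
        assert t == 0.0 and p == 1.0

    def test_clearly_different_optimization_outcomes(self):
        t, p = welch_t_from_summary(69.3, 2.7, 5, 89.0, 1.5, 5)
        assert p < 0.001

    def test_matches_closed_form_oracle(self):
        m1, s1, n1, m2, s2, n2 = 10.0, 1.0, 5, 12.0, 1.0, 5
        t, p = welch_t_from_summary(m1, s1, n1, m2, s2, n2)
        se2 = s1**2 / n1 + s2**2 / n2
        t_hand = (m1 - m2) / math.sqrt(se2)
        df_hand = se2**2 / ((s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1))
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), df=df_hand)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)
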