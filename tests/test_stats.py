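"""Contingency chi-square and ANOVA layer against closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cutisol.stats import (
    AssociationResult,
    ContingencyTable,
    P_SENTINEL,
    anova_oneway,
    anova_twoway,
    chi_square,
    expected_count,
)


def make_table(counts, rows=None, cols=None):
    arr = np.asarray(counts)
    return ContingencyTable(
        rows=tuple(rows or [f"r{i}" for i in range(arr.shape[0])]),
        cols=tuple(cols or [f"c{j}" for j in range(arr.shape[1])]),
        counts=tuple(tuple(int(v) for v in row) for row in arr),
    )


class TestChiSquare:
    def test_identical_distributions(self):
        result = chi_square(make_table([[5, 5], [5, 5]]))
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        # E = 2.5 everywhere, so X2 = 4 * (2.5)^2 / 2.5 = 10 with df 1
        result = chi_square(make_table([[5, 0], [0, 5]]))
        assert result.statistic == pytest.approx(10.0)
        assert result.df == (1,)

    def test_pearson_closed_form_oracle(self):
        counts = np.array([[10, 3, 0], [2, 4, 6], [7, 23, 18]], dtype=float)
        expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        stat = ((counts - expected) ** 2 / expected).sum()
        result = chi_square(make_table(counts.astype(int)))
        assert result.statistic == pytest.approx(stat)
        assert result.df == (4,)

    def test_low_expected_cell_warning(self):
        result = chi_square(make_table([[1, 0], [0, 1]]))
        assert result.warning is not None

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            chi_square(make_table([[0, 0], [0, 0]]))

    def test_needs_two_by_two(self):
        with pytest.raises(ValueError):
            chi_square(make_table([[1, 2]]))

    def test_permutation_invariance(self):
        counts = np.array([[10, 3, 0], [2, 4, 6], [7, 23, 18]])
        reference = chi_square(make_table(counts))
        for rperm in itertools.permutations(range(3)):
            shuffled = counts[list(rperm)][:, [2, 0, 1]]
            result = chi_square(make_table(shuffled))
            assert result.statistic == pytest.approx(reference.statistic)
            assert result.p_value == pytest.approx(reference.p_value)


class TestExpectedCounts:
    def test_table2_cell(self):
        table = make_table([[10, 3, 0], [2, 4, 6], [7, 23, 18]])
        # 13 soluble x 19 RR-1 / 73 total
        assert expected_count(table, 0, 0) == pytest.approx(13 * 19 / 73)
        assert round(expected_count(table, 0, 0)) == 3

    def test_uniform_two_by_two(self):
        table = make_table([[1, 1], [1, 1]])
        for i, j in itertools.product(range(2), range(2)):
            assert expected_count(table, i, j) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts",
        [[[10, 3, 0], [2, 4, 6], [7, 23, 18]], [[1, 2], [3, 4]],
         [[0, 5], [5, 0]]],
    )
    def test_expected_sums_to_grand_total(self, counts):
        table = make_table(counts)
        assert table.expected.sum() == pytest.approx(table.grand_total)


class TestOneWayAnova:
    def test_equal_means_f_zero(self):
        result = anova_oneway({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_degenerate_zero_within_variance(self):
        result = anova_oneway({"a": [0, 0], "b": [1, 1]})
        assert result.statistic == float("inf")
        assert result.p_value == P_SENTINEL

    def test_f_equals_t_squared_two_groups(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 1, rng.integers(3, 12))
            ours = anova_oneway({"a": a, "b": b})
            t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
            assert ours.statistic == pytest.approx(t ** 2, rel=1e-9)
            assert ours.p_value == pytest.approx(p, rel=1e-9)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(9)
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abc")}
        ours = anova_oneway(groups)
        stat, p = scipy.stats.f_oneway(*groups.values())
        assert ours.statistic == pytest.approx(stat)
        assert ours.p_value == pytest.approx(p)

    def test_residual_df_zero_error(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": [1], "b": [2]})


def type3_f_by_model_comparison(data, term):
    """Oracle: Type III F from full-vs-reduced residual SS with sum coding."""
    def design(include):
        a_levels = sorted(data["a"].unique())
        b_levels = sorted(data["b"].unique())
        cols = [np.ones(len(data))]
        a_cols, b_cols = [], []
        for lev in a_levels[:-1]:
            col = (data["a"] == lev).astype(float) - (
                data["a"] == a_levels[-1]
            ).astype(float)
            a_cols.append(col.to_numpy())
        for lev in b_levels[:-1]:
            col = (data["b"] == lev).astype(float) - (
                data["b"] == b_levels[-1]
            ).astype(float)
            b_cols.append(col.to_numpy())
        ab_cols = [ac * bc for ac in a_cols for bc in b_cols]
        parts = {"a": a_cols, "b": b_cols, "a:b": ab_cols}
        for name, cs in parts.items():
            if name in include:
                cols.extend(cs)
        return np.column_stack(cols), {k: len(v) for k, v in parts.items()}

    y = data["y"].to_numpy(dtype=float)
    full, sizes = design({"a", "b", "a:b"})
    reduced, _ = design({"a", "b", "a:b"} - {term})
    rss = lambda X: ((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum()
    rss_full, rss_red = rss(full), rss(reduced)
    df_term = sizes[term]
    df_resid = len(y) - full.shape[1]
    return ((rss_red - rss_full) / df_term) / (rss_full / df_resid)


class TestTwoWayAnova:
    def _toy(self):
        rng = np.random.default_rng(3)
        rows = []
        # unbalanced 2x2 crossed design
        for a, b, n, mu in [("a1", "b1", 4, 0.0), ("a1", "b2", 6, 1.0),
                            ("a2", "b1", 3, 0.5), ("a2", "b2", 5, 2.0)]:
            for _ in range(n):
                rows.append({"y": rng.normal(mu, 1.0), "a": a, "b": b})
        return pd.DataFrame(rows)

    def test_type3_matches_model_comparison_oracle(self):
        data = self._toy()
        results = anova_twoway(data, "y", "a", "b")
        for term, key in [("a", "a"), ("b", "b"), ("a:b", "a:b")]:
            expected = type3_f_by_model_comparison(data, key)
            assert results[term].statistic == pytest.approx(
                expected, rel=1e-6
            ), term

    def test_balanced_design_matches_classical_decomposition(self):
        rng = np.random.default_rng(11)
        rows = []
        for a in ("a1", "a2"):
            for b in ("b1", "b2", "b3"):
                for _ in range(4):
                    rows.append(
                        {"y": rng.normal((a == "a2") + (b == "b3"), 1.0),
                         "a": a, "b": b}
                    )
        data = pd.DataFrame(rows)
        results = anova_twoway(data, "y", "a", "b")
        # classical textbook decomposition on balanced data
        grand = data["y"].mean()
        n_per_cell = 4
        cell = data.groupby(["a", "b"])["y"].mean()
        am = data.groupby("a")["y"].mean()
        bm = data.groupby("b")["y"].mean()
        ss_a = 12 * ((am - grand) ** 2).sum()
        ss_b = 8 * ((bm - grand) ** 2).sum()
        ss_cells = n_per_cell * ((cell - grand) ** 2).sum()
        ss_ab = ss_cells - ss_a - ss_b
        ss_within = sum(
            ((sub["y"] - sub["y"].mean()) ** 2).sum()
            for _, sub in data.groupby(["a", "b"])
        )
        df_resid = len(data) - 6
        assert results["a"].statistic == pytest.approx(
            (ss_a / 1) / (ss_within / df_resid), rel=1e-6
        )
        assert results["b"].statistic == pytest.approx(
            (ss_b / 2) / (ss_within / df_resid), rel=1e-6
        )
        assert results["a:b"].statistic == pytest.approx(
            (ss_ab / 2) / (ss_within / df_resid), rel=1e-6
        )

    def test_residual_df_zero_error(self):
        data = pd.DataFrame(
            {"y": [1.0, 2.0, 3.0, 4.0], "a": ["a1", "a1", "a2", "a2"],
             "b": ["b1", "b2", "b1", "b2"]}
        )
        with pytest.raises(ValueError):
            anova_twoway(data, "y", "a", "b")


def test_result_invariants_enforced():
    with pytest.raises(AssertionError):
        AssociationResult(kind="chi_square", statistic=-1.0, df=(1,),
                          p_value=0.5)
    with pytest.raises(AssertionError):
        AssociationResult(kind="chi_square", statistic=1.0, df=(1,),
                          p_value=0.0)
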