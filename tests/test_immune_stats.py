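import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rsikit.errors import ValidationError
from rsikit.immune import (
    anova_across_groups,
    filter_differential,
    group_compare,
    m1_m2_log_ratio,
    spearman_matrix,
    spearman_with_p,
    validate_immune_fractions,
)


def _fractions(rows):
    return pd.DataFrame(rows, columns=["Macrophages M1", "Macrophages M2"],
                        index=[f"S{i}" for i in range(len(rows))])


class TestM1M2Ratio:
    def test_known_ratios(self):
        t = _fractions([[0.2, 0.1], [0.05, 0.05]])
        res = m1_m2_log_ratio(t)
        assert res.values.tolist() == pytest.approx([1.0, 0.0])
        assert res.n_excluded == 0

    def test_structural_zero_excluded_and_counted(self):
        t = _fractions([[0.2, 0.0], [0.0, 0.1], [0.1, 0.1]])
        res = m1_m2_log_ratio(t)
        assert res.n_excluded == 2
        assert res.values.index.tolist() == ["S2"]

    def test_missing_columns_error(self):
        with pytest.raises(ValidationError):
            m1_m2_log_ratio(pd.DataFrame({"other": [1.0]}))


def test_fraction_table_validation():
    bad = _fractions([[0.7, 0.6]])
    with pytest.raises(ValidationError, match="sum"):
        validate_immune_fractions(bad)
    with pytest.raises(ValidationError, match="non-negative"):
        validate_immune_fractions(_fractions([[-0.1, 0.2]]))


class TestSpearman:
    def test_self_and_negation(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        assert spearman_with_p(x, x)[0] == pytest.approx(1.0)
        assert spearman_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_rho_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=10), rng.normal(size=10)
        rho, _ = spearman_with_p(x, y)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_p_matches_direct_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        _, p = spearman_with_p(x, y)
        # independent enumeration of all 5! rank pairings
        ry = sps.rankdata(y)
        d2_obs = ((sps.rankdata(x) - ry) ** 2).sum()
        mid = 5 * 24 / 6
        hits = sum(
            abs(((np.array(perm) - ry) ** 2).sum() - mid) >= abs(d2_obs - mid)
            for perm in itertools.permutations(range(1, 6))
        )
        assert p == pytest.approx(hits / 120)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = spearman_with_p(x, y)
        assert spearman_with_p(np.exp(x), y) == pytest.approx(base)
        assert spearman_with_p(x, y**3) == pytest.approx(base)

    def test_matrix_pairwise_complete_and_min_pairs(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        X.loc[3:19, "b"] = np.nan  # only 3 complete pairs for b
        rho, p, n = spearman_matrix(X)
        assert rho.loc["a", "a"] == pytest.approx(1.0)
        assert n.loc["a", "b"] == 3
        assert np.isnan(rho.loc["a", "b"]) and np.isnan(p.loc["a", "b"])


class TestGroupCompare:
    def test_exact_separated_groups(self):
        vals = np.array([1.0, 2, 3, 4, 5, 6])
        labels = np.array(["x", "x", "x", "y", "y", "y"])
        u, p = group_compare(vals, labels)
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        vals = np.array([1.0, 2, 3, 1, 2, 3])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert group_compare(vals, labels)[1] == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(size=14)
        labels = np.array([0] * 7 + [1] * 7)
        assert group_compare(vals, labels)[1] == pytest.approx(
            group_compare(vals, 1 - labels)[1])

    def test_exact_and_asymptotic_agree_at_n8(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a, b = rng.normal(size=8), rng.normal(size=8) + 0.5
            vals = np.r_[a, b]
            labels = np.array([0] * 8 + [1] * 8)
            _, p_exact = group_compare(vals, labels)
            p_approx = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                              method="asymptotic").pvalue)
            assert abs(p_exact - p_approx) < 0.02

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            group_compare(np.array([1.0, 2.0]), np.array([0, 0]))


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(31)
        vals = rng.normal(size=40)
        labels = np.array([0] * 20 + [1] * 20)
        f, p_f = anova_across_groups(vals, labels)
        t, p_t = sps.ttest_ind(vals[:20], vals[20:])
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_null_f_near_one_in_expectation(self):
        rng = np.random.default_rng(37)
        fs = [anova_across_groups(rng.normal(size=30),
                                  np.repeat([0, 1, 2], 10))[0]
              for _ in range(1000)]
        assert 0.8 < np.mean(fs) < 1.2

    def test_zero_within_variance_separated_means(self):
        vals = np.array([1.0, 1.0, 2.0, 2.0])
        labels = np.array([0, 0, 1, 1])
        _, p = anova_across_groups(vals, labels)
        assert p < 1e-10

    def test_degenerate_groups_error(self):
        with pytest.raises(ValidationError):
            anova_across_groups(np.array([1.0, 2, 3]), np.array([0, 0, 1]))


class TestDifferentialFilter:
    def test_paper_style_rows(self):
        rows = pd.DataFrame({
            "feature": ["TAP2", "weak", "boundary_fc", "boundary_p", "strong"],
            "logFC": [-1.33, 0.5, 1.0, 2.0, 2.2],
            "adj_p": [0.01, 0.001, 0.01, 0.05, 0.002],
        })
        kept = filter_differential(rows)
        assert kept["feature"].tolist() == ["TAP2", "strong"]

    def test_subset_and_threshold_monotonicity(self):
        rng = np.random.default_rng(41)
        rows = pd.DataFrame({"logFC": rng.normal(scale=2, size=200),
                             "adj_p": rng.uniform(size=200)})
        kept = filter_differential(rows)
        assert kept.index.isin(rows.index).all()
        assert len(filter_differential(rows, alpha=0.2)) >= len(kept)
        assert len(filter_differential(rows, fc_thresh=2.0)) <= len(kept)

    def test_bad_p_values_rejected(self):
        with pytest.raises(ValidationError):
            filter_differential(pd.DataFrame({"logFC": [2.0], "adj_p": [1.5]}))
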