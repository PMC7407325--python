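"""Collinearity screening, merging, and quartile binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fmribucket import (
    flag_collinear_pairs,
    merge_collinear,
    pearson_matrix,
    quartile_bin,
    screen_features,
)


def _two_pass_corr(x, y):
    """Textbook sample-correlation formula, computed independently."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx**0.5 * syy**0.5)


class TestPearsonMatrix:
    def test_hand_example(self):
        X = pd.DataFrame({"x": [1, 2, 3], "y": [1, 2, 4]})
        r = pearson_matrix(X).loc["x", "y"]
        assert r == pytest.approx(0.982, abs=5e-4)
        assert r == pytest.approx(_two_pass_corr([1, 2, 3], [1, 2, 4]))

    def test_duplicated_column_correlates_exactly(self):
        X = pd.DataFrame({"a": [1.0, 5.0, 2.0, 8.0], "b": [1.0, 5.0, 2.0, 8.0]})
        assert pearson_matrix(X).loc["a", "b"] == pytest.approx(1.0)

    def test_full_feature_count_shape(self, default_cohort):
        _, cohort = default_cohort
        mat = pearson_matrix(cohort.table.counts)
        assert mat.shape == (117, 117)
        assert np.allclose(np.diag(mat), 1.0)

    def test_constant_column_yields_missing_not_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        mat = pearson_matrix(X)
        assert np.isnan(mat.loc["a", "c"])
        assert mat.loc["c", "c"] == 1.0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="3 rows"):
            pearson_matrix(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_two_pass_formula(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 5))
        mat = pearson_matrix(pd.DataFrame(X)).to_numpy()
        for i in range(5):
            for j in range(i + 1, 5):
                assert mat[i, j] == pytest.approx(
                    _two_pass_corr(X[:, i], X[:, j]), abs=1e-12
                )
        assert np.allclose(mat, mat.T, equal_nan=True)


class TestFlagCollinearPairs:
    def test_negated_feature_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        X = pd.DataFrame({"f": x, "neg": -x, "other": rng.normal(size=10)})
        report = flag_collinear_pairs(X.iloc[:5], X.iloc[5:])
        assert ("f", "neg") in report.flagged_feature_pairs

    def test_uncorrelated_features_pass(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        report = flag_collinear_pairs(X.iloc[:20], X.iloc[20:])
        assert report.flagged_pairs == []

    def test_flag_in_any_dataset_suffices(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        train = pd.DataFrame({"a": x, "b": x + rng.normal(0, 1e-6, 10)})
        test = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        report = flag_collinear_pairs(train, test)
        datasets = {d for _, _, d, _ in report.flagged_pairs}
        assert "train" in datasets

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_pairwise_check(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(14, 10))
        base[:, 1] = base[:, 0] * 2 + rng.normal(0, 0.05, 14)  # near-duplicate pair
        train, test = pd.DataFrame(base[:7]), pd.DataFrame(base[7:])
        report = flag_collinear_pairs(train, test, threshold=0.9)
        expected = set()
        for name, X in (("train", train), ("test", test),
                        ("combined", pd.concat([train, test]))):
            arr = X.to_numpy()
            for i in range(10):
                for j in range(i + 1, 10):
                    r = _two_pass_corr(arr[:, i], arr[:, j])
                    if abs(r) >= 0.9:
                        expected.add((X.columns[i], X.columns[j]))
        assert report.flagged_feature_pairs == expected


class TestMergeCollinear:
    def test_no_flags_is_identity(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        report = flag_collinear_pairs(X.iloc[:15], X.iloc[15:])
        merged, _ = merge_collinear(X, report)
        pd.testing.assert_frame_equal(merged, X)

    def test_duplicated_columns_are_summed(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        X = pd.DataFrame({"a": x, "b": x, "z": [1, 7, 2, 9, 3, 8.0]})
        report = flag_collinear_pairs(X.iloc[:3], X.iloc[3:])
        merged, out = merge_collinear(X, report)
        assert "a+b" in merged.columns
        assert np.array_equal(merged["a+b"].to_numpy(), 2 * x)
        assert (("a", "b"), "a+b") in out.merges

    def test_fixed_point_and_mass_conservation(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(30, size=(20, 3)).astype(float)
        X = pd.DataFrame(
            {"a": base[:, 0], "b": base[:, 0] + 1, "c": base[:, 1], "d": base[:, 2]}
        )
        report = flag_collinear_pairs(X.iloc[:10], X.iloc[10:])
        merged, _ = merge_collinear(X, report)
        assert merged.to_numpy().sum() == pytest.approx(X.to_numpy().sum())
        re_report = flag_collinear_pairs(merged.iloc[:10], merged.iloc[10:])
        # fixed point holds on the matrix merge_collinear itself re-screens
        assert not any(
            abs(r) >= 0.9
            for r in pearson_matrix(merged).to_numpy()[
                np.triu_indices(merged.shape[1], 1)
            ]
            if not np.isnan(r)
        )
        merged2, _ = merge_collinear(merged, re_report)
        assert list(merged2.columns) == list(merged.columns)

    def test_screen_features_applies_same_merge_to_both_halves(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(40, 30).astype(float)
        X = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.1, 30),
                          "c": rng.poisson(40, 30).astype(float)})
        tr, te, report = screen_features(X.iloc[:15], X.iloc[15:])
        assert list(tr.columns) == list(te.columns)
        assert any(name == "a+b" for _, name in report.merges)


class TestQuartileBin:
    def test_one_value_per_quartile(self):
        X = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]})
        codes, _ = quartile_bin(X)
        assert codes["v"].tolist() == [1, 2, 3, 4]

    def test_constant_column_degenerates_to_one(self):
        X = pd.DataFrame({"v": [5.0] * 6})
        with pytest.warns(UserWarning, match="degenerate"):
            codes, _ = quartile_bin(X)
        assert (codes["v"] == 1).all()

    def test_boundaries_persist_to_new_data(self):
        train = pd.DataFrame({"v": np.arange(1.0, 9.0)})
        _, binner = quartile_bin(train)
        codes = binner.transform(pd.DataFrame({"v": [0.0, 100.0]}))
        assert codes["v"].tolist() == [1, 4]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_sort_and_split_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=17)
        codes, _ = quartile_bin(pd.DataFrame({"v": v}))
        q = np.quantile(v, [0.25, 0.5, 0.75])
        brute = [1 + sum(b < x for b in q) for x in v]
        assert codes["v"].tolist() == brute
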