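"""Descriptor ingestion, cleaning cascade, and recursive feature elimination."""

import numpy as np
import pandas as pd
import pytest

from pfas_semiquant.descriptors import (
    DescriptorError,
    clean_cascade,
    drop_correlated,
    drop_missing,
    drop_near_zero_variance,
    read_descriptor_table,
    rfe_select,
)


@pytest.fixture()
def small_table(tmp_path):
    p = tmp_path / "padel.csv"
    p.write_text(
        "Name,ALogP,MW,nF,TopoPSA\n"
        "PFOA,1.2,414.07,15,37.3\n"
        "PFOS,0.9,500.13,17,62.7\n"
        "PFBS,0.4,300.10,9,62.7\n"
    )
    return p


class TestReadDescriptorTable:
    def test_reads_padel_layout(self, small_table):
        m = read_descriptor_table(small_table)
        assert m.shape == (3, 4)
        assert list(m.index) == ["PFOA", "PFOS", "PFBS"]
        assert m.loc["PFOS", "MW"] == pytest.approx(500.13)

    def test_empty_cell_is_missing_not_zero(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("Name,A,B\nX,1.0,\nY,2.0,3.0\n")
        m = read_descriptor_table(p)
        assert np.isnan(m.loc["X", "B"])
        assert m.loc["Y", "B"] == 3.0

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("Name,A\nX,1\nX,2\n")
        with pytest.raises(DescriptorError, match="duplicate"):
            read_descriptor_table(p)

    def test_no_descriptor_columns_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("Name\nX\n")
        with pytest.raises(DescriptorError):
            read_descriptor_table(p)


class TestDropMissing:
    def test_nan_and_inf_columns_dropped_clean_kept(self):
        m = pd.DataFrame(
            {
                "ok": [1.0, 2.0, 3.0],
                "has_nan": [1.0, np.nan, 3.0],
                "has_inf": [1.0, np.inf, 3.0],
            }
        )
        kept, dropped = drop_missing(m)
        assert list(kept.columns) == ["ok"]
        assert sorted(dropped) == ["has_inf", "has_nan"]

    def test_identity_when_all_finite(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        kept, dropped = drop_missing(m)
        assert dropped == [] and kept.equals(m)

    def test_all_columns_missing_is_error(self):
        m = pd.DataFrame({"a": [np.nan, 1.0]})
        with pytest.raises(DescriptorError):
            drop_missing(m)


class TestNearZeroVariance:
    def test_constant_dropped_diverse_kept(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame({"const": np.ones(50), "diverse": rng.normal(size=50)})
        kept, dropped = drop_near_zero_variance(m)
        assert dropped == ["const"]
        assert list(kept.columns) == ["diverse"]

    def test_both_criteria_required(self):
        # 48 zeros / 2 ones: freq ratio 24 > 19 and 4 % unique < 10 % -> dropped
        spiky = np.zeros(50)
        spiky[:2] = 1.0
        # 25/25 split: freq ratio 1 -> kept despite 4 % uniqueness
        balanced = np.repeat([0.0, 1.0], 25)
        m = pd.DataFrame({"spiky": spiky, "balanced": balanced})
        kept, dropped = drop_near_zero_variance(m)
        assert dropped == ["spiky"]
        assert list(kept.columns) == ["balanced"]

    def test_requires_no_missing(self):
        m = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(DescriptorError):
            drop_near_zero_variance(m)


class TestDropCorrelated:
    def test_identical_columns_one_dropped(self):
        x = np.arange(10.0)
        m = pd.DataFrame({"a": x, "b": x.copy(), "c": np.random.default_rng(1).normal(size=10)})
        kept, dropped = drop_correlated(m)
        assert len(dropped) == 1 and dropped[0] in {"a", "b"}
        assert "c" in kept.columns

    def test_independent_columns_untouched(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(60, 6)), columns=list("abcdef"))
        # oracle: verify independence numerically before asserting identity
        corr = np.abs(np.corrcoef(m.to_numpy(), rowvar=False))
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.8
        kept, dropped = drop_correlated(m)
        assert dropped == [] and list(kept.columns) == list("abcdef")

    def test_planted_block_is_broken_up(self):
        rng = np.random.default_rng(3)
        n = 80
        shared = rng.normal(size=n)
        m = pd.DataFrame(
            {
                "b1": shared + 0.2 * rng.normal(size=n),
                "b2": shared + 0.2 * rng.normal(size=n),
                "b3": shared + 0.2 * rng.normal(size=n),
                "i1": rng.normal(size=n),
                "i2": rng.normal(size=n),
            }
        )
        kept, dropped = drop_correlated(m, threshold=0.8)
        assert len([c for c in dropped if c.startswith("b")]) >= 2
        # brute-force audit of the survivors
        corr = np.abs(np.corrcoef(kept.to_numpy(), rowvar=False))
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.8

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(40, 8))
        base[:, 1] = base[:, 0] + 0.1 * rng.normal(size=40)
        m = pd.DataFrame(base, columns=[f"c{i}" for i in range(8)])
        _, d1 = drop_correlated(m)
        _, d2 = drop_correlated(m.copy())
        assert d1 == d2


class TestCascade:
    def test_monotone_column_counts(self, default_dataset):
        m = default_dataset.descriptors
        m1, miss = drop_missing(m)
        m2, nzv = drop_near_zero_variance(m1)
        m3, corr = drop_correlated(m2)
        assert m.shape[1] >= m1.shape[1] >= m2.shape[1] >= m3.shape[1]
        assert set(miss).isdisjoint(nzv) and set(nzv).isdisjoint(corr)

    def test_cascade_equals_staged_calls(self, default_dataset):
        m = default_dataset.descriptors
        cleaned, dropped = clean_cascade(m)
        total = sum(len(v) for v in dropped.values())
        assert cleaned.shape[1] == m.shape[1] - total


class TestRFE:
    def test_all_columns_when_single_size(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(30, 6)), columns=[f"f{i}" for i in range(6)])
        y = m["f0"] + 0.1 * rng.normal(size=30)
        report = rfe_select(m, y, subset_sizes=[6], folds=3, repeats=1, seed=0, n_estimators=50)
        assert sorted(report.selected) == sorted(m.columns)

    def test_planted_linear_signal_recovered(self):
        rng = np.random.default_rng(6)
        n, p, k = 60, 50, 5
        X = rng.normal(size=(n, p))
        planted = [f"f{i}" for i in range(k)]
        y = X[:, :k].sum(axis=1) + 0.05 * rng.normal(size=n)
        m = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
        report = rfe_select(
            m, y, subset_sizes=[5, 10, 20], folds=5, repeats=2, seed=0, n_estimators=200
        )
        assert len(set(report.selected) & set(planted)) >= 4

    def test_pure_noise_profile_flat_and_1se_picks_smallest(self):
        rng = np.random.default_rng(7)
        n, p = 40, 30
        m = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
        y = rng.normal(size=n)
        report = rfe_select(
            m, y, subset_sizes=[5, 10, 20], folds=4, repeats=2, seed=0,
            n_estimators=100, pick="1se",
        )
        means = [v[0] for v in report.cv_profile.values()]
        # no size does materially better than guessing sd(y)
        assert max(means) / min(means) < 1.35
        assert np.min(means) > 0.7 * np.std(y)
        # 1se rule: the smallest size whose mean sits within one SE of the best
        best_size = min(report.cv_profile, key=lambda s: report.cv_profile[s][0])
        cutoff = sum(report.cv_profile[best_size])
        expected = min(s for s, (m_, _) in report.cv_profile.items() if m_ <= cutoff)
        assert len(report.selected) == expected <= best_size

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(30, 10)), columns=[f"f{i}" for i in range(10)])
        y = m["f0"] - m["f1"] + 0.1 * rng.normal(size=30)
        r1 = rfe_select(m, y, [3, 6], folds=3, repeats=2, seed=11, n_estimators=50)
        r2 = rfe_select(m, y, [3, 6], folds=3, repeats=2, seed=11, n_estimators=50)
        assert r1.selected == r2.selected and r1.cv_profile == r2.cv_profile

    def test_too_many_folds_rejected(self):
        m = pd.DataFrame(np.eye(4), columns=list("abcd"))
        with pytest.raises(DescriptorError, match="folds"):
            rfe_select(m, [1, 2, 3, 4], [2], folds=10, repeats=1, seed=0)
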