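"""Cleaning chain: strict missingness exclusion, TSR imputation,
group classification, sex adjustment, standardization, idempotence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import remodelscore as rs
from remodelscore.cohort import CohortTable
from remodelscore.config import PreprocessParams


def _table(X, sbp=None, med=None, sex=None):
    n, p = X.shape
    names = [f"f{j}" for j in range(p)]
    data = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "visit": "baseline",
            "sex": sex if sex is not None else np.arange(n) % 2,
            "sbp": sbp if sbp is not None else np.full(n, 130.0),
            "on_medication": med if med is not None else np.zeros(n, dtype=int),
            "group": "unassigned",
        }
    )
    data[names] = X
    return CohortTable(data, names)


class TestFilterMissing:
    def test_strict_30_percent_rule(self):
        """Exactly 30% missing is retained; strictly more is excluded."""
        X = np.random.default_rng(0).normal(size=(20, 100))
        X[0, :31] = np.nan   # 31% -> excluded
        X[1, :30] = np.nan   # 30% -> retained
        kept, report = rs.filter_missing(_table(X))
        ids = set(kept.data["subject_id"])
        assert "S000" not in ids and "S001" in ids
        assert list(report.loc[report.kind == "subject", "id"]) == ["S000"]

    def test_fully_observed_identity(self):
        X = np.random.default_rng(1).normal(size=(10, 5))
        cohort = _table(X)
        kept, report = rs.filter_missing(cohort)
        assert report.empty
        pd.testing.assert_frame_equal(kept.data, cohort.data)

    def test_all_missing_column_removed_not_subjects(self):
        X = np.random.default_rng(2).normal(size=(10, 10))
        X[:, 3] = np.nan
        kept, report = rs.filter_missing(_table(X))
        assert len(kept) == 10
        assert kept.feature_names == [f"f{j}" for j in range(10) if j != 3]
        assert list(report["kind"]) == ["feature"]


class TestImputeTSR:
    def test_no_missing_is_identity(self):
        X = np.random.default_rng(3).normal(size=(15, 6))
        cohort = _table(X)
        out = rs.impute_tsr(cohort)
        pd.testing.assert_frame_equal(out.data, cohort.data)

    def test_rank1_completion_matches_closed_form(self):
        """A deleted cell of an exact rank-1 matrix is recovered."""
        rng = np.random.default_rng(4)
        u, v = rng.uniform(1, 2, 20), rng.uniform(1, 2, 5)
        X = np.outer(u, v)
        X[7, 2] = np.nan
        params = PreprocessParams(tsr_components=1, tsr_tol=1e-10, tsr_max_iter=2000)
        out = rs.impute_tsr(_table(X), params)
        assert out.features.iloc[7, 2] == pytest.approx(u[7] * v[2], abs=1e-6)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_observed_cells_never_altered(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 6))
        mask = rng.uniform(size=X.shape) < 0.15
        mask[:, 0] = False  # keep at least one fully observed column
        Xm = np.where(mask, np.nan, X)
        out = rs.impute_tsr(_table(Xm))
        filled = out.features.to_numpy()
        np.testing.assert_array_equal(filled[~mask], Xm[~mask])
        assert not np.isnan(filled).any()

    def test_imputed_fraction_logged(self, caplog):
        import logging

        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 10))
        X[rng.uniform(size=X.shape) < 0.03] = np.nan
        with caplog.at_level(logging.INFO, logger="remodelscore.preprocess"):
            rs.impute_tsr(_table(X))
        assert any("imputed" in rec.message for rec in caplog.records)


class TestClassifyGroups:
    @pytest.mark.parametrize(
        "sbp,med,expected",
        [
            (118.0, 0, "normotensive"),
            (118.0, 1, "intermediate"),
            (160.0, 0, "hypertensive"),
            (130.0, 0, "intermediate"),
            (119.99, 0, "normotensive"),
            (120.0, 0, "intermediate"),
        ],
    )
    def test_thresholds(self, sbp, med, expected):
        X = np.zeros((3, 2))
        cohort = _table(X, sbp=[sbp, 100.0, 170.0], med=[med, 0, 0])
        out = rs.classify_groups(cohort)
        assert out.groups.iloc[0] == expected

    def test_missing_sbp_unassigned(self):
        cohort = _table(np.zeros((2, 2)), sbp=[np.nan, 130.0])
        out = rs.classify_groups(cohort)
        assert out.groups.iloc[0] == "unassigned"


class TestAdjustSex:
    def test_residual_orthogonality_and_mean_preserved(self):
        rng = np.random.default_rng(6)
        n = 200
        sex = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 4)) + np.outer(sex, [1.0, -0.5, 0.0, 2.0])
        cohort = _table(X, sex=sex)
        adjusted, model = rs.adjust_sex(cohort)
        A = adjusted.features.to_numpy()
        sex_c = sex - sex.mean()
        slopes = (sex_c @ A) / (sex_c @ sex_c)
        np.testing.assert_allclose(slopes, 0.0, atol=1e-10)
        np.testing.assert_allclose(A.mean(axis=0), X.mean(axis=0), atol=1e-10)

    def test_zero_sex_effect_feature_nearly_unchanged(self):
        rng = np.random.default_rng(7)
        n = 2000
        X = rng.normal(size=(n, 1))
        cohort = _table(X, sex=rng.integers(0, 2, n))
        adjusted, _ = rs.adjust_sex(cohort)
        change = np.abs(adjusted.features.to_numpy() - X).mean()
        assert change < 0.05  # shrinks as O(1/sqrt(n))

    def test_single_sex_skipped_with_warning(self):
        cohort = _table(np.random.default_rng(8).normal(size=(10, 3)), sex=np.ones(10, int))
        with pytest.warns(RuntimeWarning, match="single-sex"):
            adjusted, _ = rs.adjust_sex(cohort)
        pd.testing.assert_frame_equal(adjusted.data, cohort.data)


class TestStandardize:
    def test_training_moments(self):
        cohort = _table(np.random.default_rng(9).normal(2, 3, size=(50, 4)))
        out, model = rs.standardize(cohort)
        Z = out.features.to_numpy()
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_constant_feature_dropped(self):
        X = np.random.default_rng(10).normal(size=(20, 3))
        X[:, 1] = 5.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out, model = rs.standardize(_table(X))
        assert out.feature_names == ["f0", "f2"]
        assert model.dropped_features == ["f1"]

    def test_heldout_uses_training_parameters(self):
        rng = np.random.default_rng(11)
        train = _table(rng.normal(0, 1, size=(60, 3)))
        other = _table(rng.normal(5, 2, size=(40, 3)))
        _, model = rs.standardize(train)
        out, _ = rs.standardize(other, model)
        Z = out.features.to_numpy()
        expected = (other.features.to_numpy() - model.means.to_numpy()) / model.sds.to_numpy()
        np.testing.assert_allclose(Z, expected)
        assert abs(Z.mean()) > 0.5  # not re-centred on its own moments


def test_chain_idempotent(demo_cohort):
    """Running the full cleaning chain on its own output is an identity."""
    cohort, _ = demo_cohort
    clean, model, _ = rs.preprocess_cohort(cohort)
    again, _, report = rs.preprocess_cohort(clean)
    assert report.empty
    np.testing.assert_allclose(
        again.features.to_numpy(), clean.features.to_numpy(), atol=1e-10
    )


def test_transform_matches_training_on_complete_data():
    cohort, _ = rs.simulate_cohort(rs.SimConfig(n_subjects=120, seed=13, missing_rate=0.0))
    clean, model, _ = rs.preprocess_cohort(cohort)
    Z = model.transform(cohort)
    np.testing.assert_allclose(Z, clean.features.to_numpy(), atol=1e-8)


def test_transform_imputes_under_training_pca_model():
    """Held-out missing cells are reconstructed from the training PCA
    basis, far better than a column-mean fill for factor-driven data."""
    cohort, truth = rs.simulate_cohort(rs.SimConfig(n_subjects=300, seed=14, missing_rate=0.0))
    clean, model, _ = rs.preprocess_cohort(cohort)
    holdout = cohort.subset(np.arange(len(cohort)) < 50)
    Z_full = model.transform(holdout)
    masked = holdout.copy()
    rng = np.random.default_rng(0)
    cells = [(i, 5 + i % 30) for i in range(50)]
    for i, j in cells:
        masked.data.loc[masked.data.index[i], masked.feature_names[j]] = np.nan
    Z_imp = model.transform(masked)
    err = np.array([abs(Z_imp[i, j] - Z_full[i, j]) for i, j in cells])
    naive = np.array([abs(Z_full[i, j]) for i, j in cells])  # mean-fill error (z-scale)
    assert err.mean() < 0.8 * naive.mean()
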