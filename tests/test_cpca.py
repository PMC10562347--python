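"""Contrastive PCA: eigendecomposition oracle, alpha selection,
component-count rule, Hopkins statistic, feature relevance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.covariance import LedoitWolf
from sklearn.decomposition import PCA

import remodelscore as rs
from remodelscore.cpca import DEFAULT_ALPHA_GRID, hopkins_statistic


def _align_signs(A, B):
    """Flip columns of B to match the sign convention of A."""
    signs = np.sign((A * B).sum(axis=0))
    signs[signs == 0] = 1.0
    return B * signs[None, :]


def _two_groups(seed=0, n=60, p=8):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, p)), rng.normal(size=(n, p))


class TestCpca:
    def test_alpha_zero_reduces_to_target_pca(self):
        """With alpha = 0 the contrast degenerates to PCA of the target
        covariance (sample covariance when shrinkage is off)."""
        target, background = _two_groups(seed=1, n=120, p=6)
        sub = rs.cpca(target, background, alpha=0.0, n_components=4, shrinkage=False)
        pca = PCA(n_components=4).fit(target)
        expected = _align_signs(sub.loadings.to_numpy(), pca.components_.T)
        np.testing.assert_allclose(sub.loadings.to_numpy(), expected, atol=1e-8)

    def test_shrinkage_preserves_pca_eigenvectors_on_structured_data(self):
        """Ledoit-Wolf shrinks toward a scaled identity, which leaves
        the eigenvectors of a structured covariance unchanged."""
        rng = np.random.default_rng(9)
        n, p = 150, 6
        F = rng.normal(size=(p, 2))
        target = rng.normal(size=(n, 2)) @ F.T + rng.normal(0, 0.3, (n, p))
        background = rng.normal(size=(n, p))
        sub = rs.cpca(target, background, alpha=0.0, n_components=2, shrinkage=True)
        pca = PCA(n_components=2).fit(target)
        expected = _align_signs(sub.loadings.to_numpy(), pca.components_.T)
        np.testing.assert_allclose(sub.loadings.to_numpy(), expected, atol=1e-6)

    def test_matches_dense_eigensolver_oracle(self):
        """Loadings equal those of a dense symmetric eigendecomposition
        of the explicitly formed contrast matrix."""
        target, background = _two_groups(seed=2, n=40, p=8)
        alpha = 1.7
        C = (
            LedoitWolf().fit(target).covariance_
            - alpha * LedoitWolf().fit(background).covariance_
        )
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        sub = rs.cpca(target, background, alpha, n_components=5)
        oracle = _align_signs(sub.loadings.to_numpy(), evecs[:, order[:5]])
        np.testing.assert_allclose(sub.loadings.to_numpy(), oracle, atol=1e-8)
        np.testing.assert_allclose(sub.contrast_eigenvalues, evals[order], atol=1e-8)

    def test_background_suppression_reveals_target_axis(self):
        """Background variance along e1, target variance along e1 and
        e2: at large alpha the top component aligns with e2."""
        rng = np.random.default_rng(3)
        n, p = 500, 6
        background = rng.normal(size=(n, p)) * 0.2
        background[:, 0] += rng.normal(0, 3.0, n)
        target = rng.normal(size=(n, p)) * 0.2
        target[:, 0] += rng.normal(0, 3.0, n)
        target[:, 1] += rng.normal(0, 1.5, n)
        sub = rs.cpca(target, background, alpha=5.0, n_components=1)
        cos = abs(sub.loadings.to_numpy()[1, 0])
        assert cos >= 0.95

    def test_negative_alpha_rejected(self):
        target, background = _two_groups()
        with pytest.raises(ValueError, match="alpha"):
            rs.cpca(target, background, alpha=-0.1, n_components=2)

    def test_loadings_orthonormal_across_grid(self):
        target, background = _two_groups(seed=4, n=80, p=7)
        for alpha in [0.0, 0.5, 2.0, 10.0, 100.0]:
            sub = rs.cpca(target, background, alpha, n_components=5)
            L = sub.loadings.to_numpy()
            np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-8)
            assert np.all(np.diff(sub.contrast_eigenvalues) <= 1e-10)


class TestChooseNComponents:
    @pytest.mark.parametrize(
        "eigenvalues,expected",
        [
            ([8.0, 1.0, 1.0], 1),          # 8/10 = 0.8 reaches the threshold
            ([5.0, 3.0, 1.0, 1.0], 2),     # (5+3)/10
            ([4.0, -1.0, 3.0, -2.0, 1.0], 2),  # negatives carry no mass
        ],
    )
    def test_positive_mass_rule(self, eigenvalues, expected):
        assert rs.choose_n_components(np.array(eigenvalues), 0.8) == expected

    def test_no_positive_eigenvalues_is_an_error(self):
        with pytest.raises(ValueError, match="positive"):
            rs.choose_n_components(np.array([-1.0, -2.0]), 0.8)

    def test_cap(self):
        assert rs.choose_n_components(np.ones(50), 0.99, cap=10) == 10


class TestHopkins:
    def test_uniform_cloud_near_half(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(500, 2))
        h = hopkins_statistic(X, 0.25, rng, n_resamples=20)
        assert abs(h - 0.5) < 0.1

    def test_two_clusters_above_half(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.05, (100, 2)), rng.normal(1, 0.05, (100, 2))])
        h = hopkins_statistic(X, 0.25, rng, n_resamples=20)
        assert h > 0.7


class TestSelectAlpha:
    def test_singleton_grid(self):
        rng = np.random.default_rng(7)
        background = rng.normal(size=(80, 6)) * 0.3
        target = rng.normal(size=(80, 6)) * 0.3
        target[:, 2] += rng.normal(0, 2.0, 80)  # genuine target-enriched axis
        alpha, diag = rs.select_alpha(target, background, grid=[5.0])
        assert alpha == 5.0
        assert len(diag) == 1

    def test_masked_bimodality_selects_positive_alpha(self):
        """Two-cluster target structure hidden behind a dominant shared
        background axis: the selected alpha is strictly positive."""
        positive = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p = 200, 8
            shared = rng.normal(0, 3.0, (2 * n, 1))
            base = rng.normal(0, 0.3, (2 * n, p))
            base[:, :1] += shared
            background = base[:n]
            target = base[n:]
            target[:, 1] += rng.choice([-1.5, 1.5], n)  # bimodal once e1 suppressed
            alpha, _ = rs.select_alpha(
                pd.DataFrame(target), pd.DataFrame(background), seed=seed
            )
            positive += alpha > 0
        assert positive >= 18

    def test_default_grid_brackets_typical_contrast_values(self):
        assert DEFAULT_ALPHA_GRID[0] == 0.0
        assert DEFAULT_ALPHA_GRID.min() == 0.0 and DEFAULT_ALPHA_GRID.max() == pytest.approx(1000.0)
        assert len(DEFAULT_ALPHA_GRID) == 41


class TestFeatureRelevance:
    def test_single_loaded_feature_takes_all_relevance(self):
        loadings = np.zeros((4, 1))
        loadings[2, 0] = 1.0
        sub = rs.ContrastiveSubspace(
            alpha=1.0,
            loadings=pd.DataFrame(loadings, index=list("abcd")),
            contrast_eigenvalues=np.array([3.0, -0.5]),
            n_components=1,
        )
        rel = rs.feature_relevance(sub)
        assert rel.relevance["c"] == pytest.approx(1.0)
        assert rel.top_set == ["c"]

    def test_relevance_sums_to_one(self):
        target, background = _two_groups(seed=8, n=90, p=10)
        sub = rs.cpca(target, background, 0.5, 4)
        rel = rs.feature_relevance(sub)
        assert rel.relevance.sum() == pytest.approx(1.0, abs=1e-10)
        assert (rel.relevance >= 0).all()

    def test_planted_disease_features_top_ranking(self):
        """Equal-magnitude three-factor design: planted features
        dominate the relevance ranking (mean precision >= 0.8)."""
        precisions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p = 500, 40
            t = rng.uniform(0, 1, n)
            g = (t**2 + t) / 2
            g = (g - g.mean()) / g.std()
            D = np.zeros((p, 3))
            for k in range(3):
                D[k * 7 : (k + 1) * 7, k] = rng.choice([-1, 1], 7) / np.sqrt(7)
            B = rng.normal(size=(p, 4))
            B /= np.linalg.norm(B, axis=0)
            X = (
                rng.normal(size=(n, 4)) @ B.T
                + 1.5 * np.outer(g, D.sum(axis=1))
                + rng.normal(0, 0.3, (n, p))
            )
            X = pd.DataFrame((X - X.mean(0)) / X.std(0), columns=[f"f{i}" for i in range(p)])
            target, background = X[t > 0.7], X[t < 0.2]
            alpha, _ = rs.select_alpha(target, background, seed=seed)
            probe = rs.cpca(target, background, alpha, 10)
            k = rs.choose_n_components(probe.contrast_eigenvalues, 0.8, 10)
            rel = rs.feature_relevance(rs.cpca(target, background, alpha, k))
            top = set(rel.ranking.index[:21])
            precisions.append(len(top & {f"f{i}" for i in range(21)}) / 21)
        assert np.mean(precisions) >= 0.8
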