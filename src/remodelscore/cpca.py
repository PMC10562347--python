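"""Contrastive PCA with automatic contrast-parameter selection.

Contrasted principal component analysis finds the directions along
which a target population (here: hypertensive subjects) carries excess
variance relative to a background population (normotensive subjects),
by eigendecomposing ``C_target − α · C_background``. The contrast
parameter α weighs how strongly shared background variance is
suppressed; it is selected automatically as the value whose subspace
maximizes the clustering tendency (Hopkins statistic) of the projected
target subjects.

Covariances are estimated with Ledoit–Wolf shrinkage toward a scaled
identity because the group sizes (~100) are comparable to the number of
features (68); the shrinkage target preserves eigenvectors, so with
α = 0 the loadings coincide with ordinary PCA of the target covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.covariance import LedoitWolf

DEFAULT_ALPHA_GRID = np.concatenate([[0.0], np.logspace(-2, 3, 40)])


@dataclass
class ContrastiveSubspace:
    """A fitted contrastive subspace.

    ``loadings`` has orthonormal columns (one per retained component),
    sign-fixed so the largest-magnitude entry of each column is
    positive. ``contrast_eigenvalues`` holds the full descending
    spectrum of the contrast matrix, not only the retained part.
    """

    alpha: float
    loadings: pd.DataFrame              # features × components, orthonormal
    contrast_eigenvalues: np.ndarray    # full spectrum, descending
    n_components: int
    variance_threshold: float = 0.80
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_names:
            self.feature_names = list(self.loadings.index)

    def project(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.loadings.to_numpy()


@dataclass
class FeatureRelevance:
    relevance: pd.Series      # nonnegative, sums to 1, original feature order
    ranking: pd.DataFrame     # sorted descending with cumulative column
    top_set: list[str]        # minimal set whose cumulative relevance exceeds threshold


def shrunk_covariance(X: np.ndarray, shrinkage: bool = True) -> np.ndarray:
    """Group covariance; Ledoit–Wolf analytic shrinkage by default."""
    X = np.asarray(X, dtype=float)
    if not shrinkage:
        return np.cov(X, rowvar=False, ddof=1)
    lw = LedoitWolf(assume_centered=False).fit(X)
    return lw.covariance_


def contrast_matrix(
    target: np.ndarray, background: np.ndarray, alpha: float, shrinkage: bool = True
) -> np.ndarray:
    """Explicitly formed symmetric contrast matrix C_t − α·C_b."""
    return shrunk_covariance(target, shrinkage) - alpha * shrunk_covariance(background, shrinkage)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs[None, :]


def cpca(
    target: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
    alpha: float,
    n_components: int,
    shrinkage: bool = True,
    variance_threshold: float = 0.80,
) -> ContrastiveSubspace:
    """Eigendecomposition of the contrast matrix.

    Returns the top ``n_components`` eigenvectors (descending
    eigenvalue order, deterministic sign convention). Deterministic
    given its inputs.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    names = list(target.columns) if isinstance(target, pd.DataFrame) else [
        f"feature_{i + 1:03d}" for i in range(np.asarray(target).shape[1])
    ]
    T = target.to_numpy(dtype=float) if isinstance(target, pd.DataFrame) else np.asarray(target, float)
    B = background.to_numpy(dtype=float) if isinstance(background, pd.DataFrame) else np.asarray(background, float)
    if T.shape[1] != B.shape[1]:
        raise ValueError("target and background must share the feature set")

    C = contrast_matrix(T, B, alpha, shrinkage)
    evals, evecs = eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = int(min(n_components, evecs.shape[1]))
    loadings = _fix_signs(evecs[:, :k])
    return ContrastiveSubspace(
        alpha=float(alpha),
        loadings=pd.DataFrame(loadings, index=names),
        contrast_eigenvalues=evals,
        n_components=k,
        variance_threshold=variance_threshold,
        feature_names=names,
    )


def choose_n_components(
    eigenvalues: np.ndarray, variance_threshold: float = 0.80, cap: int = 10
) -> int:
    """Smallest k whose cumulative positive-eigenvalue mass reaches the
    threshold; negative eigenvalues carry no enriched variance and are
    excluded from the mass. Capped."""
    ev = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    positive = ev[ev > 0]
    if positive.size == 0:
        raise ValueError("no positive contrast eigenvalues: no enriched structure")
    ratio = np.cumsum(positive) / positive.sum()
    k = int(np.searchsorted(ratio, variance_threshold - 1e-12) + 1)
    return int(min(k, cap, positive.size))


def hopkins_statistic(
    X: np.ndarray,
    sampling_fraction: float = 0.25,
    rng: np.random.Generator | None = None,
    n_resamples: int = 1,
) -> float:
    """Hopkins clustering-tendency statistic.

    Compares nearest-neighbour distances from uniform probes in the
    bounding box (u) with those from sampled data points to the rest of
    the data (w): H = Σu / (Σu + Σw). ≈0.5 for a uniform cloud, →1 for
    clustered data. Averaged over ``n_resamples`` seeded draws to tame
    sampling noise.
    """
    from sklearn.neighbors import NearestNeighbors

    rng = rng or np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    m = max(1, int(np.ceil(sampling_fraction * n)))
    lo, hi = X.min(axis=0), X.max(axis=0)
    nn_all = NearestNeighbors(n_neighbors=2).fit(X)

    values = []
    for _ in range(n_resamples):
        probes = rng.uniform(lo, hi, size=(m, d))
        u = nn_all.kneighbors(probes, n_neighbors=1)[0][:, 0]
        sample_idx = rng.choice(n, size=m, replace=False)
        w = nn_all.kneighbors(X[sample_idx], n_neighbors=2)[0][:, 1]
        total = u.sum() + w.sum()
        values.append(0.5 if total == 0 else float(u.sum() / total))
    return float(np.mean(values))


def select_alpha(
    target: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
    grid: np.ndarray | list[float] | None = None,
    n_components: int | str = "auto",
    variance_threshold: float = 0.80,
    max_components: int = 10,
    shrinkage: bool = True,
    sampling_fraction: float = 0.25,
    n_resamples: int = 20,
    n_null_reps: int = 25,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Pick the contrast parameter maximizing clustering tendency.

    For each α on the grid the target subjects are projected onto the
    contrastive subspace (component count chosen per α when
    ``n_components='auto'``) and the clustering tendency of the
    projection is measured as the Hopkins statistic's *excess* over its
    Monte-Carlo expectation under a variance-matched Gaussian null with
    the same sample size and dimension. The raw Hopkins value is not
    comparable across subspaces of different dimension (its no-structure
    level rises with d), so the excess is what is maximized. Tendencies
    within one null standard deviation of the maximum are treated as
    tied, and ties break toward the larger α — the conservative default
    of maximal background suppression while enriched structure remains.
    Returns (alpha, diagnostics table).
    """
    if grid is None:
        grid = DEFAULT_ALPHA_GRID
    grid = np.sort(np.asarray(list(grid), dtype=float))
    if grid.size == 0:
        raise ValueError("alpha grid must be non-empty")
    if (grid < 0).any():
        raise ValueError("alpha grid values must be nonnegative")

    rows = []
    for alpha in grid:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
        null_rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
        try:
            sub = cpca(target, background, alpha, max_components, shrinkage, variance_threshold)
            k = (
                choose_n_components(sub.contrast_eigenvalues, variance_threshold, max_components)
                if n_components == "auto"
                else int(n_components)
            )
            proj = sub.project(target)[:, :k]
        except ValueError as exc:
            warnings.warn(f"alpha {alpha:g} skipped: {exc}", RuntimeWarning)
            rows.append({"alpha": float(alpha), "hopkins": np.nan, "excess": np.nan,
                         "null_sd": np.nan, "n_components": np.nan})
            continue
        if not np.all(proj.std(axis=0) > 0):
            warnings.warn(f"alpha {alpha:g} skipped: degenerate projection", RuntimeWarning)
            rows.append({"alpha": float(alpha), "hopkins": np.nan, "excess": np.nan,
                         "null_sd": np.nan, "n_components": k})
            continue
        h = hopkins_statistic(proj, sampling_fraction, rng, n_resamples)
        sds = proj.std(axis=0, ddof=0)
        nulls = np.array(
            [
                hopkins_statistic(
                    null_rng.normal(size=proj.shape) * sds[None, :],
                    sampling_fraction,
                    null_rng,
                    1,
                )
                for _ in range(n_null_reps)
            ]
        )
        rows.append(
            {
                "alpha": float(alpha),
                "hopkins": h,
                "excess": h - float(nulls.mean()),
                "null_sd": float(nulls.std(ddof=1)) if n_null_reps > 1 else 0.0,
                "n_components": k,
            }
        )
    diagnostics = pd.DataFrame(rows)
    valid = diagnostics.dropna(subset=["excess"])
    if valid.empty:
        raise ValueError("no valid alpha on the grid")
    best_excess = valid["excess"].max()
    tied = valid[valid["excess"] >= best_excess - valid["null_sd"]]
    return float(tied["alpha"].max()), diagnostics


def feature_relevance(subspace: ContrastiveSubspace) -> FeatureRelevance:
    """Per-feature contribution to the retained subspace.

    relevance_f ∝ Σ_k |loading_{f,k}| · λ_k⁺ over retained components,
    normalized to sum to one. Also reports the minimal feature set whose
    cumulative relevance exceeds the subspace's variance threshold.
    """
    lam = np.clip(subspace.contrast_eigenvalues[: subspace.n_components], 0.0, None)
    weights = np.abs(subspace.loadings.to_numpy()) @ lam
    total = weights.sum()
    if total == 0:
        raise ValueError("subspace carries no positive contrast variance")
    rel = pd.Series(weights / total, index=subspace.loadings.index, name="relevance")
    ranked = rel.sort_values(ascending=False, kind="stable").to_frame()
    ranked["cumulative"] = ranked["relevance"].cumsum()
    n_top = int(np.searchsorted(ranked["cumulative"].to_numpy(), subspace.variance_threshold - 1e-12) + 1)
    n_top = min(n_top, len(ranked))
    return FeatureRelevance(relevance=rel, ranking=ranked, top_set=list(ranked.index[:n_top]))
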