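"""Unsupervised feature pre-screening.

Scores each feature by the ratio of its global variance to its mean
variance within local k-nearest-neighbour neighbourhoods of the point
cloud. A feature varying smoothly across the cloud has large global
spread but small local spread (high score); pure noise scores near 1.
By default all features are carried forward (``keep_fraction = 1``) and
the scores are report-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors


@dataclass
class FeatureSelectionResult:
    scores: pd.Series          # per-feature variance ratio, original order
    retained: list[str]        # names surviving the keep_fraction cut
    threshold: float           # score of the weakest retained feature

    def to_frame(self) -> pd.DataFrame:
        ranked = self.scores.sort_values(ascending=False)
        return pd.DataFrame(
            {"score": ranked, "retained": [n in set(self.retained) for n in ranked.index]}
        )


def select_features(
    features: pd.DataFrame,
    k_neighbours: int = 10,
    keep_fraction: float = 1.0,
) -> FeatureSelectionResult:
    """Rank features by global-to-neighbourhood variance ratio.

    Parameters
    ----------
    features
        Standardized subjects × features matrix.
    k_neighbours
        Neighbourhood size (excluding the point itself); must be < n.
    keep_fraction
        Fraction of top-ranked features to retain; 1.0 keeps all.
    """
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    if k_neighbours >= n:
        raise ValueError(f"k_neighbours ({k_neighbours}) must be < n subjects ({n})")
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")

    nn = NearestNeighbors(n_neighbors=k_neighbours + 1).fit(X)
    _, idx = nn.kneighbors(X)          # includes the point itself
    # neighbourhood variance per feature, averaged over all subjects
    local = X[idx]                     # n × (k+1) × p
    local_var = local.var(axis=1, ddof=1).mean(axis=0)
    global_var = X.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(local_var > 0, global_var / local_var, np.inf)

    scores = pd.Series(ratio, index=features.columns)
    n_keep = max(1, int(round(keep_fraction * p)))
    ranked = scores.sort_values(ascending=False, kind="stable")
    retained = list(ranked.index[:n_keep])
    threshold = float(ranked.iloc[n_keep - 1])
    # preserve original column order among the retained features
    retained = [f for f in features.columns if f in set(retained)]
    return FeatureSelectionResult(scores=scores, retained=retained, threshold=threshold)
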