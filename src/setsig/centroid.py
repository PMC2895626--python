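"""The centroid classifier: class-mean prototypes and an inner-product rule.

Fitting computes the feature-wise mean of each class, c⁺ and c⁻; the weight
vector w = c⁺ − c⁻ connects the two centroids and the decision value for a
sample z is ŷ = ⟨z − c, w⟩ with c = (c⁺ + c⁻)/2.  The sign of ŷ is the
predicted class; the raw ŷ is used for AUC because it yields a lower-variance
AUC estimate than the hard class labels.

Because each weight depends only on its own feature, recursive feature
elimination is a single ranking by |w| — truncating to the top-k features and
refitting reproduces the same weights.  The classifier is equivalent to
diagonal-covariance LDA with uniform priors and needs no tuning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats


@dataclass
class CentroidModel:
    feature_names: list[str]
    c_plus: np.ndarray
    c_minus: np.ndarray
    statistic: str = "raw"

    def __post_init__(self) -> None:
        self.c_plus = np.asarray(self.c_plus, dtype=float)
        self.c_minus = np.asarray(self.c_minus, dtype=float)
        if self.c_plus.shape != self.c_minus.shape or self.c_plus.ndim != 1:
            raise ValueError("centroid vectors must be 1-D and equal length")
        if len(self.feature_names) != self.c_plus.size:
            raise ValueError("feature_names length does not match centroid length")
        if not (np.isfinite(self.c_plus).all() and np.isfinite(self.c_minus).all()):
            raise ValueError("non-finite centroid entries")

    @property
    def w(self) -> np.ndarray:
        return self.c_plus - self.c_minus

    @property
    def midpoint(self) -> np.ndarray:
        return (self.c_plus + self.c_minus) / 2.0

    @property
    def n_features(self) -> int:
        return self.c_plus.size

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "c_plus": self.c_plus.tolist(),
            "c_minus": self.c_minus.tolist(),
            "statistic": self.statistic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CentroidModel":
        return cls(
            feature_names=list(d["feature_names"]),
            c_plus=np.array(d["c_plus"], dtype=float),
            c_minus=np.array(d["c_minus"], dtype=float),
            statistic=d.get("statistic", "raw"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "CentroidModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_centroid(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str] | None = None,
    statistic: str = "raw",
) -> CentroidModel:
    """Fit class centroids from a p×N feature matrix and ±1 labels."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[1] != y.size:
        raise ValueError("features must be p×N with one label per column")
    pos = y == 1
    neg = y == -1
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present to fit centroids")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[0])]
    return CentroidModel(
        feature_names=list(feature_names),
        c_plus=X[:, pos].mean(axis=1),
        c_minus=X[:, neg].mean(axis=1),
        statistic=statistic,
    )


def decision_values(model: CentroidModel, features: np.ndarray) -> np.ndarray:
    """ŷ_i = ⟨z_i − c, w⟩ for each column z_i of ``features``."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[0]} does not match model ({model.n_features})"
        )
    return model.w @ (X - model.midpoint[:, None])


def rank_features_by_weight(model: CentroidModel) -> np.ndarray:
    """Feature indices ordered by decreasing |w|; ties keep original order.

    ``order[0]`` is the rank-1 (largest-|w|) feature.
    """
    return np.argsort(-np.abs(model.w), kind="stable")


def feature_ranks(model: CentroidModel) -> np.ndarray:
    """Rank of each feature (1 = largest |w|), aligned with feature order."""
    order = rank_features_by_weight(model)
    ranks = np.empty(model.n_features, dtype=int)
    ranks[order] = np.arange(1, model.n_features + 1)
    return ranks


def truncate_model(model: CentroidModel, top_k: int) -> tuple[CentroidModel, np.ndarray]:
    """Keep the top-k features by |w|; returns the submodel and the kept indices.

    No refit is needed: centroid weights are feature-wise independent.
    """
    if top_k < 1:
        raise ValueError("top_k must be ≥ 1")
    idx = rank_features_by_weight(model)[: min(top_k, model.n_features)]
    sub = CentroidModel(
        feature_names=[model.feature_names[i] for i in idx],
        c_plus=model.c_plus[idx],
        c_minus=model.c_minus[idx],
        statistic=model.statistic,
    )
    return sub, idx


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score⁺ > score⁻) with ties credited ½."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = y == 1
    neg = y == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = stats.rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
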