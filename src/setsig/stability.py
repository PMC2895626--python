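"""Signature stability: bootstrap rank intervals, cross-dataset weight
concordance, and top-f list overlap.

Gene signatures derived from expression studies are notoriously unstable —
the top-ranked features change under resampling of the same dataset and
across cohorts.  This module quantifies that instability three ways:

* percentile-bootstrap distributions of each feature's |w|-rank within one
  dataset (stratified resampling of samples with replacement);
* Spearman rank-correlation of centroid weight vectors between datasets;
* for each cutoff f, how many features appear in the top f of at least k of
  the D datasets' ranked lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .centroid import CentroidModel, feature_ranks, fit_centroid

DEFAULT_BOOTSTRAP_REPS = 5000


@dataclass
class RankStability:
    """Bootstrap distribution of feature ranks (1 = largest |w|)."""

    feature_names: list[str]
    mean_rank: np.ndarray
    lo: np.ndarray  # 2.5% percentile by default
    hi: np.ndarray  # 97.5% percentile
    n_reps: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "mean_rank": self.mean_rank,
            "lo": self.lo,
            "hi": self.hi,
        }).sort_values("mean_rank").reset_index(drop=True)

    def top_interval_width(self, top: int = 15) -> float:
        """Mean hi−lo interval width over the ``top`` features by mean rank."""
        order = np.argsort(self.mean_rank, kind="stable")[:top]
        return float(np.mean(self.hi[order] - self.lo[order]))


def _empirical_quantile(sorted_cols: np.ndarray, q: float) -> np.ndarray:
    """Type-1 (inverse empirical CDF) quantile along axis 0 of a sorted array."""
    n = sorted_cols.shape[0]
    idx = max(int(np.ceil(q * n)) - 1, 0)
    return sorted_cols[idx]


def bootstrap_feature_ranks(
    features: np.ndarray,
    labels: np.ndarray,
    n_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
    feature_names: list[str] | None = None,
    q_lo: float = 0.025,
    q_hi: float = 0.975,
) -> RankStability:
    """Percentile bootstrap of centroid-weight ranks.

    Each replication resamples samples with replacement within each class
    (stratified, so no resample is single-class), refits the centroid model
    and ranks features by |w|.  Reported per feature: mean rank and the
    empirical ``q_lo``/``q_hi`` percentiles over replications.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be ≥ 1")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = np.where(y == 1)[0]
    neg = np.where(y == -1)[0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    p = X.shape[0]
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]
    rng = np.random.default_rng(seed)
    # vectorised: class centroids for all replications at once via count matrices
    cnt_pos = rng.multinomial(pos.size, np.full(pos.size, 1.0 / pos.size), size=n_reps)
    cnt_neg = rng.multinomial(neg.size, np.full(neg.size, 1.0 / neg.size), size=n_reps)
    c_plus = X[:, pos] @ cnt_pos.T / pos.size  # p×R
    c_minus = X[:, neg] @ cnt_neg.T / neg.size
    w = np.abs(c_plus - c_minus)
    order = np.argsort(-w, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(1, p + 1)[:, None]
    np.put_along_axis(ranks, order, np.broadcast_to(rows, order.shape), axis=0)
    ranks_sorted = np.sort(ranks, axis=1)  # per-feature sorted replication ranks
    return RankStability(
        feature_names=list(feature_names),
        mean_rank=ranks.mean(axis=1),
        lo=_empirical_quantile(ranks_sorted.T, q_lo).astype(float),
        hi=_empirical_quantile(ranks_sorted.T, q_hi).astype(float),
        n_reps=n_reps,
    )


def spearman_weight_concordance(
    models: list[CentroidModel] | list[np.ndarray],
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman ρ between every unordered pair of weight vectors.

    Models (or raw weight vectors) must share one feature list in one order.
    """
    if len(models) < 2:
        raise ValueError("need ≥ 2 models")
    weights = [m.w if isinstance(m, CentroidModel) else np.asarray(m, float)
               for m in models]
    n = weights[0].size
    for w in weights:
        if w.size != n:
            raise ValueError("weight vectors differ in length")
    if names is None:
        names = [f"m{i}" for i in range(len(weights))]
    rows = []
    for i, j in combinations(range(len(weights)), 2):
        rho = stats.spearmanr(weights[i], weights[j]).statistic
        rows.append({"a": names[i], "b": names[j], "rho": float(rho)})
    return pd.DataFrame(rows)


def list_overlap_counts(
    ranked_lists: list[list[str]],
    cutoffs: list[int] | np.ndarray,
    k: int,
) -> pd.DataFrame:
    """For each cutoff f: how many features sit in the top f of ≥ k lists."""
    d = len(ranked_lists)
    if k > d:
        raise ValueError(f"k={k} exceeds the number of lists ({d})")
    if k < 1:
        raise ValueError("k must be ≥ 1")
    universe = sorted(set().union(*ranked_lists))
    pos = np.full((d, len(universe)), np.inf)
    col = {f: i for i, f in enumerate(universe)}
    for li, lst in enumerate(ranked_lists):
        for r, f in enumerate(lst, start=1):
            pos[li, col[f]] = r
    rows = []
    for f in cutoffs:
        count = int((((pos <= f).sum(axis=0)) >= k).sum())
        rows.append({"f": int(f), "count": count})
    return pd.DataFrame(rows)


def first_common_cutoff(ranked_lists: list[list[str]], k: int | None = None,
                        max_f: int | None = None) -> int | None:
    """Smallest f at which some feature is in the top f of ≥ k lists.

    ``k`` defaults to all lists.  Returns None if no feature is common up to
    ``max_f`` (default: longest list).
    """
    d = len(ranked_lists)
    k = d if k is None else k
    max_f = max_f or max(len(l) for l in ranked_lists)
    table = list_overlap_counts(ranked_lists, np.arange(1, max_f + 1), k)
    hits = table[table["count"] >= 1]
    return int(hits["f"].iloc[0]) if len(hits) else None


def consensus_rank(ranked_lists: list[list[str]]) -> list[str]:
    """Features ordered by their mean rank across lists (ties by name).

    A feature absent from a list is assigned rank len(list)+1 there.
    """
    universe = sorted(set().union(*ranked_lists))
    means = {}
    for f in universe:
        rs = []
        for lst in ranked_lists:
            try:
                rs.append(lst.index(f) + 1)
            except ValueError:
                rs.append(len(lst) + 1)
        means[f] = float(np.mean(rs))
    return sorted(universe, key=lambda f: (means[f], f))


def select_reference_genes(
    reference_features: np.ndarray,
    reference_labels: np.ndarray,
    m: int,
    feature_names: list[str] | None = None,
) -> np.ndarray:
    """Indices of the top-m genes by |w| of a model fitted on a reference dataset.

    Used to compare genes against sets at equal feature counts: the gene list
    is pre-selected on a *different* dataset and held fixed, so the comparison
    is not biased in favour of the genes.
    """
    model = fit_centroid(reference_features, reference_labels,
                         feature_names=feature_names)
    order = np.argsort(-np.abs(model.w), kind="stable")
    return order[:m]


def ranked_feature_list(features: np.ndarray, labels: np.ndarray,
                        feature_names: list[str]) -> list[str]:
    """Feature names ordered by |w| of a single (non-bagged) centroid fit."""
    model = fit_centroid(features, labels, feature_names=feature_names)
    order = np.argsort(-np.abs(model.w), kind="stable")
    return [feature_names[i] for i in order]
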