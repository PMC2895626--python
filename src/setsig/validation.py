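"""Repeated random subsampling, bagging and internal/external AUC validation.

Internal validation splits one dataset B times into a 2/3 training and 1/3
testing part (repeated random subsampling, akin to the 0.632 bootstrap
without replacement), fits one centroid model per split, and pools each
sample's held-out decision values into one bagged prediction before
computing AUC.  External validation fits a bagged classifier (B subsample
models) on one whole dataset and scores every sample of another dataset, for
all D(D−1) ordered pairs.  Both are evaluated along a grid of feature counts
using |w|-ranked feature truncation, which for the centroid classifier needs
no refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .centroid import auc, decision_values, fit_centroid, rank_features_by_weight

DEFAULT_B = 25
DEFAULT_TRAIN_FRAC = 2.0 / 3.0


@dataclass
class SplitPlan:
    """Parameters of the repeated random subsampling scheme."""

    B: int = DEFAULT_B
    train_frac: float = DEFAULT_TRAIN_FRAC
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be ≥ 1")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")


@dataclass
class ValidationReport:
    """Per-(pair, feature-count) AUC table plus bagged predictions."""

    mode: str  # "internal" or "external"
    table: pd.DataFrame  # columns: train, test, n_features, auc
    feature_grid: list[int]
    bagged_scores: dict = field(default_factory=dict)  # (train, test, k) → N-vector

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Mean AUC with a normal-approximation CI, per feature count."""
        z = stats.norm.ppf(1 - alpha / 2)
        rows = []
        for k, grp in self.table.groupby("n_features"):
            vals = grp["auc"].to_numpy()
            m = vals.mean()
            se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            rows.append({"n_features": k, "mean_auc": m, "n": len(vals),
                         "ci_lo": m - z * se, "ci_hi": m + z * se})
        return pd.DataFrame(rows)

    def variance_summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """AUC variance with a chi-squared CI, per feature count."""
        rows = []
        for k, grp in self.table.groupby("n_features"):
            vals = grp["auc"].to_numpy()
            if len(vals) < 2:
                continue
            var, lo, hi = auc_variance_ci(vals, alpha=alpha)
            rows.append({"n_features": k, "variance": var, "ci_lo": lo, "ci_hi": hi,
                         "n": len(vals)})
        return pd.DataFrame(rows)


def split_subsample(labels: np.ndarray, plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """B random (train, test) index partitions, stratified by class by default.

    Stratified: per class, floor(train_frac·n_class) samples go to training,
    the remainder to testing.  Deterministic under ``plan.seed``.
    """
    y = np.asarray(labels, dtype=int)
    n = y.size
    if not ((y == 1).any() and (y == -1).any()):
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(plan.seed)
    splits = []
    for _ in range(plan.B):
        if plan.stratified:
            train_parts, test_parts = [], []
            for cls in (1, -1):
                idx = np.where(y == cls)[0]
                if idx.size < 2:
                    raise ValueError(
                        f"class {cls:+d} has {idx.size} sample(s); stratified "
                        "subsampling needs ≥ 2 per class"
                    )
                perm = rng.permutation(idx)
                n_train = int(np.floor(plan.train_frac * idx.size))
                n_train = min(max(n_train, 1), idx.size - 1)
                train_parts.append(perm[:n_train])
                test_parts.append(perm[n_train:])
            train = np.sort(np.concatenate(train_parts))
            test = np.sort(np.concatenate(test_parts))
        else:
            perm = rng.permutation(n)
            n_train = int(np.floor(plan.train_frac * n))
            n_train = min(max(n_train, 1), n - 1)
            train = np.sort(perm[:n_train])
            test = np.sort(perm[n_train:])
        splits.append((train, test))
    return splits


def default_feature_grid(p: int) -> list[int]:
    """Powers of two up to and including p."""
    grid = []
    k = 1
    while k < p:
        grid.append(k)
        k *= 2
    grid.append(p)
    return grid


def bagged_fit_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    plan: SplitPlan,
    top_k: int | None = None,
) -> np.ndarray:
    """Average decision values of B subsample-trained, |w|-truncated models."""
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be ≥ 1")
    X = np.asarray(train_features, dtype=float)
    Xt = np.asarray(test_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    total = np.zeros(Xt.shape[1])
    for train_idx, _ in split_subsample(y, plan):
        model = fit_centroid(X[:, train_idx], y[train_idx])
        if top_k is not None and top_k < model.n_features:
            keep = rank_features_by_weight(model)[:top_k]
            sub = fit_centroid(X[keep][:, train_idx], y[train_idx])
            total += decision_values(sub, Xt[keep])
        else:
            total += decision_values(model, Xt)
    return total / plan.B


def _scores_along_grid(
    model_X: np.ndarray, model_y: np.ndarray, test_X: np.ndarray, grid: list[int]
) -> dict[int, np.ndarray]:
    """Decision values on ``test_X`` for one fitted model truncated at each k."""
    model = fit_centroid(model_X, model_y)
    order = rank_features_by_weight(model)
    out = {}
    for k in grid:
        keep = order[: min(k, model.n_features)]
        sub = fit_centroid(model_X[keep], model_y)
        out[k] = decision_values(sub, test_X[keep])
    return out


def internal_validation(
    features: np.ndarray,
    labels: np.ndarray,
    plan: SplitPlan,
    feature_grid: list[int] | None = None,
    name: str = "dataset",
) -> ValidationReport:
    """Within-dataset AUC by repeated random subsampling with bagging.

    For every split a model is fitted on the training 2/3 and scored on the
    held-out third; a sample's bagged prediction is the mean of its held-out
    scores over splits, and one pooled AUC per feature count is computed from
    those.  Per-split held-out AUCs are also recorded (rows with
    ``test = name:split<i>``) so the spread across splits is available.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    grid = feature_grid or default_feature_grid(X.shape[0])
    grid = sorted({min(k, X.shape[0]) for k in grid})
    n = y.size
    sums = {k: np.zeros(n) for k in grid}
    counts = np.zeros(n)
    rows = []
    for i, (train, test) in enumerate(split_subsample(y, plan)):
        per_k = _scores_along_grid(X[:, train], y[train], X[:, test], grid)
        counts[test] += 1
        for k in grid:
            sums[k][test] += per_k[k]
            if (y[test] == 1).any() and (y[test] == -1).any():
                rows.append({"train": name, "test": f"{name}:split{i}",
                             "n_features": k, "auc": auc(per_k[k], y[test])})
    seen = counts > 0
    bagged = {}
    for k in grid:
        scores = np.full(n, np.nan)
        scores[seen] = sums[k][seen] / counts[seen]
        bagged[(name, name, k)] = scores
        rows.append({"train": name, "test": f"{name}:bagged", "n_features": k,
                     "auc": auc(scores[seen], y[seen])})
    return ValidationReport(mode="internal", table=pd.DataFrame(rows),
                            feature_grid=grid, bagged_scores=bagged)


def internal_bagged_auc(report: ValidationReport) -> pd.DataFrame:
    """The pooled bagged AUC per feature count from an internal report."""
    t = report.table
    return t[t["test"].str.endswith(":bagged")][["n_features", "auc"]].reset_index(drop=True)


def external_validation(
    datasets: list[tuple[str, np.ndarray, np.ndarray]],
    plan: SplitPlan,
    feature_grid: list[int] | None = None,
) -> ValidationReport:
    """Cross-dataset AUC for every ordered (train, test) pair.

    ``datasets`` is a list of (name, p×N feature matrix, ±1 labels) sharing
    one feature space (same rows in the same order).  For each ordered pair a
    bagged classifier (B subsamples of the training dataset) scores all test
    samples; one AUC per feature count.  Pair count is D(D−1).
    """
    if len(datasets) < 2:
        raise ValueError("external validation needs ≥ 2 datasets")
    p = datasets[0][1].shape[0]
    for name, X, y in datasets:
        if X.shape[0] != p:
            raise ValueError("datasets must share one feature space")
    grid = feature_grid or default_feature_grid(p)
    grid = sorted({min(k, p) for k in grid})
    # one deterministic child seed per ordered pair
    ss = np.random.SeedSequence(plan.seed)
    children = ss.spawn(len(datasets) * len(datasets))
    rows = []
    bagged = {}
    for a, (name_a, Xa, ya) in enumerate(datasets):
        for b, (name_b, Xb, yb) in enumerate(datasets):
            if a == b:
                continue
            child_seed = int(children[a * len(datasets) + b].generate_state(1)[0] % (2**31))
            pair_plan = SplitPlan(B=plan.B, train_frac=plan.train_frac,
                                  stratified=plan.stratified, seed=child_seed)
            for k in grid:
                scores = bagged_fit_predict(Xa, ya, Xb, pair_plan, top_k=k)
                bagged[(name_a, name_b, k)] = scores
                rows.append({"train": name_a, "test": name_b, "n_features": k,
                             "auc": auc(scores, yb)})
    return ValidationReport(mode="external", table=pd.DataFrame(rows),
                            feature_grid=grid, bagged_scores=bagged)


def auc_variance_ci(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Sample variance of AUC values with a two-sided chi-squared CI.

    CI = ((n−1)s²/χ²_{1−α/2,n−1}, (n−1)s²/χ²_{α/2,n−1}).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need ≥ 2 values for a variance CI")
    s2 = float(np.var(v, ddof=1))
    lo = (n - 1) * s2 / stats.chi2.ppf(1 - alpha / 2, n - 1)
    hi = (n - 1) * s2 / stats.chi2.ppf(alpha / 2, n - 1)
    return s2, float(lo), float(hi)


def align_datasets(datasets: list) -> list:
    """Restrict a list of ExpressionDatasets to their common features, in the
    first dataset's order."""
    common = set(datasets[0].feature_ids)
    for ds in datasets[1:]:
        common &= set(ds.feature_ids)
    if not common:
        raise ValueError("feature intersection is empty")
    ordered = [f for f in datasets[0].feature_ids if f in common]
    out = []
    for ds in datasets:
        pos = {f: i for i, f in enumerate(ds.feature_ids)}
        out.append(ds.subset_features([pos[f] for f in ordered]))
    return out
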