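"""Unsupervised set statistics: reduce a gene set's expression submatrix to one
value per sample.

Six statistics are provided — set centroid (per-sample mean over member
genes), set median, set medoid (the member gene whose full profile lies
closest to the centroid profile), set t-statistic (centroid divided by its
standard error within the sample, on gene-standardized data), a rank-sum
(Mann–Whitney U) signed log p-value comparing in-set against out-of-set
ranks within each sample, and the first principal component of the set's
submatrix.  ``raw`` passes the gene-level matrix through unchanged and is the
individual-genes baseline.

None of these use the outcome labels; any classifier can be trained on the
resulting set×sample feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data_io import ExpressionDataset, GeneSetCollection, normalize

STATISTICS = ("centroid", "median", "medoid", "tstat", "ustat", "pc1", "raw")

#: Sets smaller than this are excluded from the t-statistic (the standard
#: error estimate is too unstable for small sets).
DEFAULT_MIN_TSTAT_SIZE = 30

#: Lower guard on the within-sample standard deviation in the t-statistic.
SD_EPS = 1e-8


@dataclass
class SetFeatureMatrix:
    """A set×sample feature matrix produced by one set statistic."""

    statistic: str
    set_names: list[str]
    sample_ids: np.ndarray
    values: np.ndarray  # M'×N, finite
    excluded_sets: list[tuple[str, str]] = field(default_factory=list)
    set_sizes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)  # per-set extras (medoid index, ν1, ...)

    @property
    def n_sets(self) -> int:
        return len(self.set_names)


# ---------------------------------------------------------------------------
# per-set statistics (operate on an s×N submatrix)
# ---------------------------------------------------------------------------

def set_centroid(sub: np.ndarray) -> np.ndarray:
    """Mean expression over the set's genes, per sample."""
    sub = np.atleast_2d(np.asarray(sub, dtype=float))
    if sub.shape[0] == 0:
        raise ValueError("empty set")
    return sub.mean(axis=0)


def set_median(sub: np.ndarray) -> np.ndarray:
    """Median expression over the set's genes, per sample."""
    sub = np.atleast_2d(np.asarray(sub, dtype=float))
    if sub.shape[0] == 0:
        raise ValueError("empty set")
    return np.median(sub, axis=0)


def set_medoid(
    sub: np.ndarray, distance_columns: Sequence[int] | None = None
) -> tuple[np.ndarray, int]:
    """The member gene whose profile is closest (Euclidean) to the centroid.

    Returns the chosen gene's full row and its row index within the
    submatrix.  Ties break to the lowest row index.  ``distance_columns``
    restricts the distance computation to a subset of samples (training
    columns inside a validation split) while the returned profile still spans
    all samples.
    """
    sub = np.atleast_2d(np.asarray(sub, dtype=float))
    if sub.shape[0] == 0:
        raise ValueError("empty set")
    ref = sub if distance_columns is None else sub[:, np.asarray(distance_columns, int)]
    centroid = ref.mean(axis=0)
    d2 = ((ref - centroid) ** 2).sum(axis=1)
    idx = int(np.argmin(d2))  # argmin returns first minimum → lowest index
    return sub[idx].copy(), idx


def set_tstat(sub: np.ndarray, s: int | None = None, sd_eps: float = SD_EPS) -> np.ndarray:
    """One-sample t of the set's genes within each sample.

    ``sub`` must already be gene-standardized (each gene mean 0, unit sample
    variance across samples).  The statistic is centroid / (sd/√s), with the
    within-sample standard deviation guarded below by ``sd_eps``.
    """
    sub = np.atleast_2d(np.asarray(sub, dtype=float))
    if sub.shape[0] < 2:
        raise ValueError("t-statistic needs ≥ 2 genes in the set")
    if s is None:
        s = sub.shape[0]
    mean = sub.mean(axis=0)
    sd = np.maximum(sub.std(axis=0, ddof=1), sd_eps)
    return mean / (sd / np.sqrt(s))


def ustat_moments(s: int, s_not: int) -> tuple[float, float]:
    """Null mean and variance of the Mann–Whitney U for set size s vs complement."""
    mu = s * s_not / 2.0
    var = s * s_not * (s + s_not + 1) / 12.0
    return mu, var


def set_ustat_logp(full: np.ndarray, member_indices: Sequence[int]) -> np.ndarray:
    """Signed log p of the rank-sum statistic for the set, per sample.

    Within each sample all p genes are ranked (ascending, average ranks for
    ties); R = sum of member ranks; U = R − s(s+1)/2.  Under the null U is
    approximately Normal(μ = s·s¬/2, σ² = s·s¬(s+s¬+1)/12).  The feature is
    sign(z)·(−ln p_two-sided), with p floored at the smallest positive double
    so the feature stays finite.
    """
    full = np.asarray(full, dtype=float)
    members = np.asarray(member_indices, dtype=int)
    p_genes = full.shape[0]
    s = members.size
    if s < 1:
        raise ValueError("empty set")
    if s >= p_genes:
        raise ValueError("set covers the whole matrix; complement is empty")
    ranks = stats.rankdata(full, axis=0, method="average")
    r = ranks[members].sum(axis=0)
    u = r - s * (s + 1) / 2.0
    mu, var = ustat_moments(s, p_genes - s)
    z = (u - mu) / np.sqrt(var)
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    return np.sign(z) * (-np.log(pval))


def set_pc1(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """First principal component of the set's submatrix.

    The N×s transposed matrix is column-centred and scaled to unit variance
    before the SVD; zero-variance genes are dropped from the decomposition
    (their indices are returned).  The returned score vector is the projection
    onto the first right-singular direction, with its sign fixed so that the
    correlation with the set centroid is ≥ 0; the unit-norm loading vector ν1
    (over the retained genes) is returned alongside.
    """
    sub = np.atleast_2d(np.asarray(sub, dtype=float))
    if sub.shape[0] < 2:
        raise ValueError("pc1 needs ≥ 2 genes in the set")
    y = sub.T  # N×s
    sd = y.std(axis=0, ddof=1)
    dropped = np.where(sd <= 0)[0].tolist()
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes with variation in the set")
    yk = (y[:, keep] - y[:, keep].mean(axis=0)) / sd[keep]
    _, _, vt = np.linalg.svd(yk, full_matrices=False)
    v1 = vt[0]
    scores = yk @ v1
    centroid = set_centroid(sub)
    c = centroid - centroid.mean()
    if scores @ c < 0:
        scores = -scores
        v1 = -v1
    return scores, v1, dropped


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def compute_set_features(
    ds: ExpressionDataset,
    coll: GeneSetCollection | None,
    statistic: str,
    min_tstat_size: int = DEFAULT_MIN_TSTAT_SIZE,
    sd_eps: float = SD_EPS,
    medoid_columns: Sequence[int] | None = None,
) -> SetFeatureMatrix:
    """Compute one set statistic for every set, giving a set×sample matrix.

    ``raw`` ignores the collection and passes the gene-level matrix through
    (the individual-genes baseline).  For ``tstat`` the matrix is
    gene-standardized first and sets smaller than ``min_tstat_size`` are
    excluded (logged, not raised).  ``medoid_columns`` restricts the medoid's
    distance computation to training samples.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    if statistic == "raw":
        return SetFeatureMatrix(
            statistic="raw",
            set_names=[str(f) for f in ds.feature_ids],
            sample_ids=ds.sample_ids.copy(),
            values=ds.values.copy(),
            set_sizes=np.ones(ds.p, dtype=int),
        )
    if coll is None or coll.mapped_members is None:
        raise ValueError("collection must be mapped to the dataset")
    if coll.p is not None and coll.p != ds.p:
        raise ValueError("collection was mapped against a different feature universe")

    X = ds.values
    if statistic == "tstat":
        X = normalize(ds, "gene_standardize").values

    names: list[str] = []
    rows: list[np.ndarray] = []
    sizes: list[int] = []
    excluded: list[tuple[str, str]] = []
    meta: dict = {}

    if statistic == "ustat":
        ranks = stats.rankdata(X, axis=0, method="average")

    for gs, members in zip(coll.sets, coll.mapped_members):
        s = len(members)
        sub = X[members]
        try:
            if statistic == "centroid":
                vec = set_centroid(sub)
            elif statistic == "median":
                vec = set_median(sub)
            elif statistic == "medoid":
                vec, idx = set_medoid(sub, distance_columns=medoid_columns)
                meta.setdefault("medoid_index", {})[gs.name] = int(members[idx])
            elif statistic == "tstat":
                if s < min_tstat_size:
                    excluded.append((gs.name, f"size {s} < {min_tstat_size}"))
                    continue
                vec = set_tstat(sub, s=s, sd_eps=sd_eps)
            elif statistic == "ustat":
                if s >= ds.p:
                    excluded.append((gs.name, "set covers the whole matrix"))
                    continue
                r = ranks[members].sum(axis=0)
                u = r - s * (s + 1) / 2.0
                mu, var = ustat_moments(s, ds.p - s)
                z = (u - mu) / np.sqrt(var)
                pval = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
                vec = np.sign(z) * (-np.log(pval))
            elif statistic == "pc1":
                if s < 2:
                    excluded.append((gs.name, f"size {s} < 2"))
                    continue
                vec, v1, dropped = set_pc1(sub)
                meta.setdefault("pc1_loading", {})[gs.name] = v1
                if dropped:
                    meta.setdefault("pc1_dropped_genes", {})[gs.name] = dropped
        except ValueError as exc:
            excluded.append((gs.name, str(exc)))
            continue
        names.append(gs.name)
        rows.append(vec)
        sizes.append(s)

    if not names:
        raise ValueError(f"no sets usable for statistic {statistic!r}")
    return SetFeatureMatrix(
        statistic=statistic,
        set_names=names,
        sample_ids=ds.sample_ids.copy(),
        values=np.vstack(rows),
        excluded_sets=excluded,
        set_sizes=np.array(sizes, dtype=int),
        meta=meta,
    )
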