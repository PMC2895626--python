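"""Molecular subtyping from ER/HER2 module scores via a Gaussian mixture.

Breast-cancer cohorts separate into clinically meaningful subgroups along
estrogen-receptor (ER/ESR1) and HER2 (ERBB2) signalling activity.  A module
score summarises a signed list of module genes as the mean of sign ×
gene-standardized expression per sample.  The 2-D (ER score, HER2 score)
cloud is clustered with a three-component full-covariance Gaussian mixture
fitted by EM; components are mapped to the ER−/HER2−, ER+/HER2− and HER2+
subtypes by their axis means (highest HER2 mean → HER2+; of the rest, higher
ER mean → ER+/HER2−).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data_io import ExpressionDataset, normalize

SUBTYPE_LABELS = ("ER-/HER2-", "ER+/HER2-", "HER2+")


@dataclass
class ModuleDefinition:
    """A named gene module: gene symbols with ±1 direction signs."""

    name: str
    members: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("module must have at least one member")
        for sym, sign in self.members:
            if sign not in (1, -1):
                raise ValueError(f"sign for {sym!r} must be ±1, got {sign}")


def read_modules(path: str | Path) -> list[ModuleDefinition]:
    """Read a TSV of (module_name, gene_symbol, sign) rows."""
    tab = pd.read_csv(path, sep="\t", header=None,
                      names=["module", "symbol", "sign"], dtype={0: str, 1: str})
    mods = []
    for name, grp in tab.groupby("module", sort=False):
        mods.append(ModuleDefinition(
            name=str(name),
            members=[(str(s), int(g)) for s, g in zip(grp["symbol"], grp["sign"])],
        ))
    return mods


def module_score(
    ds: ExpressionDataset,
    module: ModuleDefinition,
    annotation: dict[str, list[str]] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Signed mean of gene-standardized expression over the module's genes.

    Returns the per-sample score and the list of member symbols that could
    not be mapped onto the matrix (skipped).
    """
    z = normalize(ds, "gene_standardize").values
    row_of = {fid: i for i, fid in enumerate(ds.feature_ids)}
    terms = []
    skipped = []
    for sym, sign in module.members:
        fids = annotation.get(sym, []) if annotation is not None else [sym]
        hit = False
        for fid in fids:
            i = row_of.get(fid)
            if i is not None:
                terms.append(sign * z[i])
                hit = True
        if not hit:
            skipped.append(sym)
    if not terms:
        raise ValueError(f"no genes of module {module.name!r} found in the matrix")
    return np.mean(terms, axis=0), skipped


# ---------------------------------------------------------------------------
# Gaussian mixture by EM
# ---------------------------------------------------------------------------

@dataclass
class GaussianMixtureFit:
    means: np.ndarray  # K×d
    covariances: np.ndarray  # K×d×d
    weights: np.ndarray  # K, sums to 1
    posteriors: np.ndarray  # N×K, rows sum to 1
    log_likelihood_trace: np.ndarray  # of the best restart; non-decreasing
    converged: bool
    regularized: bool = False

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihood_trace[-1])

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.posteriors, axis=1)


def _log_gauss(points: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = points.shape[1]
    chol = np.linalg.cholesky(cov)
    diff = points - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _kmeans_init(points: np.ndarray, k: int, rng: np.random.Generator,
                 n_iter: int = 20) -> np.ndarray:
    """Lloyd iterations from k distinct random points; returns hard labels."""
    n = points.shape[0]
    centers = points[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new = np.argmin(d2, axis=1)
        if (new == labels).all():
            break
        labels = new
        for j in range(k):
            if (labels == j).any():
                centers[j] = points[labels == j].mean(axis=0)
            else:  # re-seed an empty cluster at the farthest point
                centers[j] = points[np.argmax(d2.min(axis=1))]
    return labels


def fit_gaussian_mixture(
    points: np.ndarray,
    n_components: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    reg: float = 1e-6,
) -> GaussianMixtureFit:
    """Full-covariance Gaussian mixture fitted by EM with k-means restarts.

    Each restart is initialised from a k-means partition under the seed; the
    best final log-likelihood wins.  Iteration stops when the log-likelihood
    improves by less than ``tol``; a collapsing covariance is regularised by
    adding ``reg``·I (flagged in the result).  The returned trace is
    non-decreasing up to numerical round-off.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be an N×d matrix")
    n, d = X.shape
    if n < 3 * n_components:
        raise ValueError(f"need ≥ {3 * n_components} points for {n_components} components")
    if np.allclose(X, X[0]):
        raise ValueError("all points identical; mixture is degenerate")
    root = np.random.default_rng(seed)
    best: GaussianMixtureFit | None = None
    for _ in range(n_restarts):
        rng = np.random.default_rng(root.integers(2**31))
        labels = _kmeans_init(X, n_components, rng)
        means = np.empty((n_components, d))
        covs = np.empty((n_components, d, d))
        weights = np.empty(n_components)
        regularized = False
        for j in range(n_components):
            mask = labels == j
            if mask.sum() < 2:
                mask = np.ones(n, dtype=bool)
            means[j] = X[mask].mean(axis=0)
            covs[j] = np.cov(X[mask].T).reshape(d, d) + reg * np.eye(d)
            weights[j] = max(mask.sum() / n, 1e-3)
        weights /= weights.sum()

        trace = []
        converged = False
        for _ in range(max_iter):
            # E-step
            log_prob = np.column_stack([
                np.log(weights[j]) + _log_gauss(X, means[j], covs[j])
                for j in range(n_components)
            ])
            ll = float(logsumexp(log_prob, axis=1).sum())
            resp = np.exp(log_prob - logsumexp(log_prob, axis=1, keepdims=True))
            if trace and ll - trace[-1] < tol:
                trace.append(ll)
                converged = True
                break
            trace.append(ll)
            # M-step
            nk = resp.sum(axis=0)
            weights = nk / n
            for j in range(n_components):
                means[j] = resp[:, j] @ X / nk[j]
                diff = X - means[j]
                cov = (resp[:, j] * diff.T) @ diff / nk[j]
                if np.linalg.eigvalsh(cov).min() < reg:
                    cov = cov + reg * np.eye(d)
                    regularized = True
                covs[j] = cov
        fit = GaussianMixtureFit(
            means=means, covariances=covs, weights=weights, posteriors=resp,
            log_likelihood_trace=np.array(trace), converged=converged,
            regularized=regularized,
        )
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


@dataclass
class SubtypeAssignment:
    sample_ids: np.ndarray
    er_score: np.ndarray
    her2_score: np.ndarray
    labels: np.ndarray  # per-sample subtype string
    posteriors: np.ndarray  # N×3, column order follows component order
    component_labels: list[str]  # subtype of each mixture component
    fit: GaussianMixtureFit = field(repr=False, default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.sample_ids,
            "er_score": self.er_score,
            "her2_score": self.her2_score,
            "subtype": self.labels,
        })


def assign_subtypes(
    fit: GaussianMixtureFit,
    sample_ids: np.ndarray | None = None,
    er_axis: int = 0,
    her2_axis: int = 1,
    er_score: np.ndarray | None = None,
    her2_score: np.ndarray | None = None,
    tol: float = 1e-8,
) -> SubtypeAssignment:
    """Map the three mixture components onto ER/HER2 subtypes.

    The component with the highest HER2-axis mean is HER2+; of the remaining
    two, the one with the higher ER-axis mean is ER+/HER2− and the other
    ER−/HER2−.  Hard sample labels are argmax posteriors.  Component means
    tied beyond ``tol`` raise, prompting a manual mapping.
    """
    if fit.means.shape[0] != 3:
        raise ValueError("subtype assignment expects exactly 3 components")
    her2_means = fit.means[:, her2_axis]
    order = np.argsort(-her2_means, kind="stable")
    if abs(her2_means[order[0]] - her2_means[order[1]]) < tol:
        raise ValueError("HER2-axis component means are tied; map components manually")
    her2_comp = order[0]
    rest = sorted(set(range(3)) - {her2_comp})
    er_means = fit.means[:, er_axis]
    if abs(er_means[rest[0]] - er_means[rest[1]]) < tol:
        raise ValueError("ER-axis component means are tied; map components manually")
    er_pos_comp = rest[0] if er_means[rest[0]] > er_means[rest[1]] else rest[1]
    er_neg_comp = rest[0] if er_pos_comp == rest[1] else rest[1]
    component_labels = [""] * 3
    component_labels[her2_comp] = "HER2+"
    component_labels[er_pos_comp] = "ER+/HER2-"
    component_labels[er_neg_comp] = "ER-/HER2-"
    hard = fit.hard_labels()
    labels = np.array([component_labels[j] for j in hard], dtype=object)
    n = fit.posteriors.shape[0]
    if sample_ids is None:
        sample_ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    return SubtypeAssignment(
        sample_ids=np.asarray(sample_ids, dtype=object),
        er_score=np.asarray(er_score) if er_score is not None else np.full(n, np.nan),
        her2_score=np.asarray(her2_score) if her2_score is not None else np.full(n, np.nan),
        labels=labels,
        posteriors=fit.posteriors,
        component_labels=component_labels,
        fit=fit,
    )


def subtype_samples(
    ds: ExpressionDataset,
    er_module: ModuleDefinition,
    her2_module: ModuleDefinition,
    annotation: dict[str, list[str]] | None = None,
    seed: int = 0,
) -> SubtypeAssignment:
    """Score ER and HER2 modules, fit the 3-component mixture, assign subtypes."""
    er, _ = module_score(ds, er_module, annotation)
    her2, _ = module_score(ds, her2_module, annotation)
    pts = np.column_stack([er, her2])
    fit = fit_gaussian_mixture(pts, n_components=3, seed=seed)
    return assign_subtypes(fit, sample_ids=ds.sample_ids, er_score=er, her2_score=her2)
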