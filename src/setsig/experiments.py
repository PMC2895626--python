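"""Pre-assembled experiment shapes: stability benchmark and null calibrations.

These functions reproduce, on synthetic multi-cohort data at desk scale, the
study designs the package exists for: comparing set-level features against
individual genes with respect to external-validation AUC, bootstrap rank
stability, cross-dataset weight concordance and top-list overlap; plus null
calibrations of the internal-validation AUC and of the KS category
enrichment.  The gene/set comparison follows the equal-feature-count
protocol: the gene list is pre-selected by a classifier trained on a
*reference* cohort (not the one being resampled) and held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .centroid import fit_centroid
from .data_io import map_collection
from .set_statistics import compute_set_features
from .stability import (
    bootstrap_feature_ranks,
    first_common_cutoff,
    ranked_feature_list,
    select_reference_genes,
    spearman_weight_concordance,
)
from .synthetic import SyntheticSpec, generate_collection, generate_datasets
from .validation import SplitPlan, external_validation, internal_validation
from .enrichment import ks_category_enrichment

#: Study conditions of the stability benchmark: five cohorts, 2000 genes,
#: 200 sets of 10–50 genes of which 20 carry the outcome signal (δ=1 on the
#: set factor, within-set correlation 0.6), ~1:4 class imbalance.
BENCHMARK_SPEC = dict(
    p=2000, n_samples=120, class_ratio=0.2, n_sets=200,
    set_size_range=(10, 50), n_informative_sets=20, rho=0.6, delta=1.0,
    n_datasets=5, batch_shift_sd=0.3, missing_frac=0.0,
)


@dataclass
class StabilityBenchmarkResult:
    """One seed's gene-vs-set comparison."""

    seed: int
    width_sets: float  # mean top-15 bootstrap rank-interval width, set centroids
    width_genes: float  # same for the pre-selected genes
    rho_sets: float  # mean pairwise Spearman of weights, set centroids
    rho_genes: float
    first_common_sets: int  # smallest f with an all-cohort-common feature
    first_common_genes: int
    auc_sets: float  # mean external AUC, set centroid features
    auc_genes: float  # mean external AUC, individual genes
    var_auc_tstat: float  # across-pair AUC variance (mean over the k grid), t-stat
    var_auc_genes: float  # same for individual genes


def run_stability_benchmark(
    seed: int,
    spec_overrides: dict | None = None,
    B: int = 25,
    bootstrap_reps: int = 500,
) -> StabilityBenchmarkResult:
    """Run the five-cohort gene-vs-set comparison for one master seed.

    Roles: cohort 0 is the bootstrap dataset, the last cohort is the
    reference used to pre-select the equal-count gene list (it still takes
    part in validation, as in the study design the roles mirror).
    """
    spec = SyntheticSpec(**{**BENCHMARK_SPEC, **(spec_overrides or {}), "seed": seed})
    rng = np.random.default_rng(spec.seed)
    coll, informative = generate_collection(spec, rng)
    datasets, _ = generate_datasets(spec, coll, informative)

    feats_centroid, feats_tstat, labels = [], [], []
    for ds in datasets:
        mapped, _ = map_collection(coll, ds, min_set_size=2)
        feats_centroid.append(compute_set_features(ds, mapped, "centroid"))
        feats_tstat.append(compute_set_features(ds, mapped, "tstat"))
        labels.append(ds.labels)

    n_sets = feats_centroid[0].n_sets
    ref = datasets[-1]
    gene_idx = select_reference_genes(ref.values, ref.labels, n_sets)
    gene_names = [str(f) for f in ref.feature_ids[gene_idx]]

    boot_ds = datasets[0]
    rs_sets = bootstrap_feature_ranks(
        feats_centroid[0].values, boot_ds.labels, n_reps=bootstrap_reps,
        seed=seed, feature_names=feats_centroid[0].set_names)
    rs_genes = bootstrap_feature_ranks(
        boot_ds.values[gene_idx], boot_ds.labels, n_reps=bootstrap_reps,
        seed=seed, feature_names=gene_names)

    set_models = [fit_centroid(fm.values, y, feature_names=fm.set_names)
                  for fm, y in zip(feats_centroid, labels)]
    gene_models = [fit_centroid(ds.values[gene_idx], ds.labels,
                                feature_names=gene_names) for ds in datasets]
    rho_sets = spearman_weight_concordance(set_models)["rho"].mean()
    rho_genes = spearman_weight_concordance(gene_models)["rho"].mean()

    set_lists = [ranked_feature_list(fm.values, y, fm.set_names)
                 for fm, y in zip(feats_centroid, labels)]
    gene_lists = [ranked_feature_list(ds.values[gene_idx], ds.labels, gene_names)
                  for ds in datasets]
    fc_sets = first_common_cutoff(set_lists) or n_sets + 1
    fc_genes = first_common_cutoff(gene_lists) or n_sets + 1

    plan = SplitPlan(B=B, seed=seed)
    n_tstat = feats_tstat[0].n_sets
    # AUC and its across-pair variance are compared along a feature-count
    # grid (truncation by |w| within each training cohort): feature selection
    # is where ranking instability bites, so a full-feature-only comparison
    # would hide it
    grid_small = [8, 32]
    ext_sets = external_validation(
        [(ds.name, fm.values, y) for ds, fm, y in
         zip(datasets, feats_centroid, labels)], plan,
        feature_grid=grid_small + [n_sets])
    ext_genes = external_validation(
        [(ds.name, ds.values, ds.labels) for ds in datasets], plan,
        feature_grid=grid_small + [spec.p])
    ext_tstat = external_validation(
        [(ds.name, fm.values, y) for ds, fm, y in
         zip(datasets, feats_tstat, labels)], plan,
        feature_grid=grid_small + [n_tstat])

    def mean_var(report) -> float:
        return float(report.table.groupby("n_features")["auc"].var().mean())

    return StabilityBenchmarkResult(
        seed=seed,
        width_sets=rs_sets.top_interval_width(15),
        width_genes=rs_genes.top_interval_width(15),
        rho_sets=float(rho_sets),
        rho_genes=float(rho_genes),
        first_common_sets=int(fc_sets),
        first_common_genes=int(fc_genes),
        auc_sets=float(
            ext_sets.table[ext_sets.table["n_features"] == n_sets]["auc"].mean()),
        auc_genes=float(
            ext_genes.table[ext_genes.table["n_features"] == spec.p]["auc"].mean()),
        var_auc_tstat=mean_var(ext_tstat),
        var_auc_genes=mean_var(ext_genes),
    )


def stability_benchmark_table(
    master_seed: int,
    n_seeds: int = 10,
    spec_overrides: dict | None = None,
    B: int = 25,
    bootstrap_reps: int = 500,
) -> pd.DataFrame:
    """Run the benchmark over ``n_seeds`` derived seeds; one row per seed."""
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_seeds)]
    rows = [run_stability_benchmark(s, spec_overrides, B=B,
                                    bootstrap_reps=bootstrap_reps).__dict__
            for s in seeds]
    return pd.DataFrame(rows)


def benchmark_direction_fractions(table: pd.DataFrame) -> dict[str, float]:
    """Fraction of seeds in which each stability direction holds."""
    return {
        "narrower_rank_intervals": float(
            (table["width_sets"] < table["width_genes"]).mean()),
        "higher_weight_concordance": float(
            (table["rho_sets"] > table["rho_genes"]).mean()),
        "earlier_common_feature": float(
            (table["first_common_sets"] < table["first_common_genes"]).mean()),
        "auc_within_margin": float(
            ((table["auc_sets"] - table["auc_genes"]).abs() <= 0.05).mean()),
        "lower_tstat_auc_variance": float(
            (table["var_auc_tstat"] <= table["var_auc_genes"]).mean()),
    }


def permuted_label_internal_auc(
    seed: int,
    n_permutations: int = 20,
    B: int = 25,
    spec_overrides: dict | None = None,
) -> tuple[float, float, int]:
    """Null calibration: internal validation under permuted labels.

    One pooled bagged AUC per label permutation (the permutation is the unit
    of replication — split-level AUCs within a permutation are correlated).
    Returns (mean AUC, standard error of the mean, number of permutations).
    """
    spec = SyntheticSpec(**{
        **BENCHMARK_SPEC, "p": 500, "n_sets": 50,
        **(spec_overrides or {}), "n_datasets": 1, "seed": seed})
    rng = np.random.default_rng(spec.seed)
    coll, informative = generate_collection(spec, rng)
    (ds,), _ = generate_datasets(spec, coll, informative)
    mapped, _ = map_collection(coll, ds, min_set_size=2)
    fm = compute_set_features(ds, mapped, "centroid")
    aucs = []
    for i in range(n_permutations):
        perm_rng = np.random.default_rng(seed + 1000 + i)
        y = ds.labels[perm_rng.permutation(ds.n_samples)]
        rep = internal_validation(fm.values, y, SplitPlan(B=B, seed=seed + i),
                                  feature_grid=[fm.n_sets])
        bagged = rep.table[rep.table["test"].str.endswith(":bagged")]
        aucs.append(float(bagged["auc"].iloc[0]))
    aucs = np.asarray(aucs)
    se = float(aucs.std(ddof=1) / np.sqrt(aucs.size))
    return float(aucs.mean()), se, int(aucs.size)


def ks_null_rejection_rate(
    seed: int,
    n_simulations: int = 1000,
    n_sets: int = 600,
    n_in_category: int = 120,
    alpha: float = 0.05,
) -> float:
    """Fraction of random category assignments rejected by the KS test at α.

    Under the null (category assigned uniformly at random along the ranked
    list) this should be ≈ α.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_simulations):
        cats = np.array(["other"] * n_sets, dtype=object)
        cats[rng.choice(n_sets, n_in_category, replace=False)] = "target"
        res = ks_category_enrichment(cats, "target", method="asymp")
        rejections += res.p_value < alpha
    return rejections / n_simulations
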