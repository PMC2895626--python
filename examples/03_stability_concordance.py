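"""Why set features: rank stability and cross-cohort concordance.

Five synthetic cohorts sharing the same informative sets.  Compares set
centroid features against an equal-count list of individual genes
(pre-selected on a held-out reference cohort) on three stability measures:
bootstrap rank intervals, Spearman correlation of classifier weights between
cohorts, and the top-f list-overlap curve.
"""

from setsig.experiments import run_stability_benchmark

res = run_stability_benchmark(seed=42)

print("bootstrap rank stability (mean width of the top-15 features' "
      "2.5–97.5% rank intervals; smaller = more stable):")
print(f"  set centroids : {res.width_sets:7.1f}")
print(f"  genes         : {res.width_genes:7.1f}")

print("\ncross-cohort weight concordance (mean pairwise Spearman rho over "
      "10 cohort pairs; larger = more reproducible signatures):")
print(f"  set centroids : {res.rho_sets:7.3f}")
print(f"  genes         : {res.rho_genes:7.3f}")

print("\nfirst cutoff f at which some feature is in the top f of all five "
      "cohorts' ranked lists (smaller = earlier agreement):")
print(f"  set centroids : {res.first_common_sets:4d}")
print(f"  genes         : {res.first_common_genes:4d}")

print("\nmean external AUC (20 ordered train/test cohort pairs):")
print(f"  set centroids : {res.auc_sets:7.3f}")
print(f"  genes         : {res.auc_genes:7.3f}")
print("\nSet features predict as well as genes while being far more stable "
      "— the reason gene-level prognostic signatures rarely replicate.")
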