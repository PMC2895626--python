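# setsig

Gene-set summary statistics for stable prognostic signatures in
gene-expression data.

## The problem

Outcome signatures built from individual genes rarely replicate: bootstrap
resampling of one cohort, or a second cohort of the same disease, produces
largely different top-gene lists of similar predictive ability.  `setsig`
implements an alternative: reduce each *predefined gene set* (an MSigDB-style
collection) to one value per sample with an unsupervised **set statistic**,
and use those set-level features — instead of genes — as inputs to a simple
centroid classifier.  Set features predict about as well as genes while
giving far more stable feature rankings, and they come with biological
labels attached.

It is a library for computational biologists working with labelled
expression matrices (bulk microarray or RNA-seq, and single-cell
pseudobulk), plus a thin `setsig` command line for pipeline use.

## What's inside

Six set statistics reduce a set's s×N expression submatrix to an N-vector:
the set **centroid** x̄ⱼᵢ = (1/s)Σₖ x₍ₖ₎ᵢ, **median**, **medoid** (the member
gene closest in Euclidean distance to the centroid profile), the
**t-statistic** x̄ⱼᵢ/(sdⱼᵢ/√s) on gene-standardized data, the **rank-sum
statistic's** signed log p (U = R − s(s+1)/2, U ≈ N(s·s¬/2,
s·s¬(s+s¬+1)/12)), and **PC1** of the set's submatrix.

The **centroid classifier** uses class centroids c⁺, c⁻ (per-class feature
means), weights w = c⁺ − c⁻ and the inner-product rule
ŷ = ⟨z − (c⁺+c⁻)/2, w⟩; AUC is the Mann–Whitney statistic of ŷ.  Validation
is repeated random subsampling (B = 25 splits, 2/3–1/3) with **bagging**,
internally within a cohort and externally across all ordered cohort pairs.
Stability is measured by percentile-bootstrap rank intervals, Spearman
correlation of weight vectors across cohorts, and top-f list-overlap
curves.  Category enrichment along a ranked set list uses the two-sample
Kolmogorov–Smirnov statistic with its Brownian-bridge curve; top-list/set
overlap uses a log-space hypergeometric upper tail that stays exact below
1e-40.  A three-component Gaussian mixture on ER/HER2 module scores
partitions cohorts into ER−/HER2−, ER+/HER2− and HER2+ subtypes.  A
synthetic-data module generates multi-cohort fixtures with known
block-correlated set structure for everything above.

## Worked example

```python
import numpy as np
import setsig as sg
from setsig.synthetic import SyntheticSpec, generate_collection, generate_datasets

spec = SyntheticSpec(p=800, n_samples=120, n_sets=60, n_informative_sets=8,
                     n_datasets=2, batch_shift_sd=0.3, seed=11)
rng = np.random.default_rng(spec.seed)
coll, informative = generate_collection(spec, rng)
datasets, _ = generate_datasets(spec, coll, informative)

ds = datasets[0]
mapped, _ = sg.map_collection(coll, ds, min_set_size=2)
features = sg.compute_set_features(ds, mapped, "centroid")

plan = sg.SplitPlan(B=25, seed=11)
report = sg.internal_validation(features.values, ds.labels, plan,
                                feature_grid=[8, 32, features.n_sets])
```

Running `python examples/02_validation.py` (which does the above for two
cohorts) prints:

```
internal validation (pooled bagged AUC per feature count):
 n_features      auc
          8 0.719618
         32 0.726562
         60 0.722222

external validation (train on one cohort, test on the other):
 train   test      auc
synth0 synth1 0.736111
synth1 synth0 0.737847
```

An AUC near 0.72 means the bagged centroid classifier on set-centroid
features separates five-year event from event-free samples well above
chance (0.5), and the external numbers matching the internal ones show the
model carries across an independently "normalised" cohort without
overfitting.  `examples/03_stability_concordance.py` then shows the point
of set features: top-15 bootstrap rank intervals of width ≈ 22 ranks for
set centroids versus ≈ 50 for genes, cross-cohort weight concordance
ρ ≈ 0.51 versus ≈ 0.07, and a first all-cohort-common feature at f = 11
versus f = 67 — equally predictive, far more stable.

The other examples cover feature computation (`01`), KS category enrichment
and deep-tail Fisher overlaps (`04`), and ER/HER2 mixture subtyping (`05`).
The same steps are scriptable: `setsig simulate | preprocess | features |
train | validate | stability | concordance | enrich | overlap | subtype`,
or end to end with `setsig run --config exp.yaml`.

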