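"""Category enrichment along a ranked set list, and top-list overlap tests.

First, a two-sample Kolmogorov–Smirnov test asking whether one category of
sets concentrates at one end of a ranked list.  Second, the one-sided Fisher
exact (hypergeometric upper-tail) test for the overlap between a top-gene
list and a set's members, computed in log space so that astronomically small
p-values stay exact.
"""

import math

import numpy as np

from setsig.enrichment import hypergeom_logsf, ks_category_enrichment

# --- KS enrichment: category "C4" planted at the top of a ranked list -------
rng = np.random.default_rng(0)
n_sets, n_c4 = 200, 40
ranks_c4 = rng.choice(80, size=n_c4, replace=False)  # C4 concentrated early
cats = np.array(["other"] * n_sets, dtype=object)
cats[ranks_c4] = "C4"
res = ks_category_enrichment(cats.tolist(), "C4")
print(f"KS enrichment of C4 along the ranked list: D = {res.d:.3f}, "
      f"p = {res.p_value:.2e}")
print("(D is the maximum gap between the in-category and out-of-category "
      "rank CDFs; the bridge curve res.bridge draws the running difference)")

# --- Fisher overlap: the worked deep-tail rows ------------------------------
print("\noverlap of a 512-gene top list with co-expression sets "
      "(universe = 22,215 probesets):")
for name, overlap, size in (("neighbourhood-of-CCNA2", 48, 99),
                            ("neighbourhood-of-HMMR", 42, 78)):
    logp = hypergeom_logsf(overlap, size, 512, 22215)
    print(f"  {name}: {overlap}/{size} genes in the top list → "
          f"p = 10^{logp / math.log(10):.1f}")
print("Both tails are far below 1e-40 — overlaps this strong cannot arise "
      "by chance; the sets and the genes point to the same biology.")
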