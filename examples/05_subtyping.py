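"""ER/HER2 molecular subtyping from module scores.

Builds a cohort whose ESR1 and ERBB2 expression define three latent
populations, scores the ER and HER2 modules per sample, fits a
three-component Gaussian mixture to the 2-D score cloud and maps components
onto the ER−/HER2−, ER+/HER2− and HER2+ subtypes.
"""

import numpy as np
import pandas as pd

import setsig as sg
from setsig.subtyping import ModuleDefinition, subtype_samples

rng = np.random.default_rng(3)
n_per = 80  # samples per latent population
er_state = np.repeat([0.0, 1.0, 0.3], n_per)
her2_state = np.repeat([0.0, 0.0, 1.0], n_per)
values = np.vstack([
    4 * er_state + rng.normal(0, 0.4, er_state.size),     # ESR1
    0.5 * er_state + rng.normal(0, 0.4, er_state.size),   # XBP1 (ER-correlated)
    4 * her2_state + rng.normal(0, 0.4, her2_state.size),  # ERBB2
    rng.normal(size=er_state.size),                        # unrelated gene
])
ds = sg.ExpressionDataset(
    name="combined",
    feature_ids=["ESR1", "XBP1", "ERBB2", "OTHER"],
    sample_ids=[f"s{i:03d}" for i in range(er_state.size)],
    values=values,
)

er = ModuleDefinition("ER", [("ESR1", 1), ("XBP1", 1)])
her2 = ModuleDefinition("HER2", [("ERBB2", 1)])
assign = subtype_samples(ds, er, her2, seed=0)

counts = pd.Series(assign.labels).value_counts()
print("subtype counts over", len(assign.labels), "samples:")
print(counts.to_string())
print("\ncomponent means (ER score, HER2 score):")
for label, mean in zip(assign.component_labels, assign.fit.means):
    print(f"  {label:10s} ({mean[0]:+.2f}, {mean[1]:+.2f})")
print("\nThe mixture recovers the three planted populations; per-subtype "
      "signature analyses (features → centroid classifier → consensus rank) "
      "can then be run on each subgroup separately.")
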