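"""Perturb tumor patches and measure per-feature robustness via ICC.

Each slice is perturbed with small rotations (R), translations (T), noise
(N), mask volume changes (V) and contour randomization (C); a one-way
random-effects ICC per (feature, class) measures how stable each feature
is.  Features with ICC < 0.75 under any class are excluded.
"""

import pandas as pd

from radiorobust import io as rio
from radiorobust.perturb import perturbation_suite
from radiorobust.preprocess import normalize_iqr, patches_from_volume
from radiorobust.robustness import family_summary, icc_table, robust_filter
from radiorobust.synthetic import make_cohort
from radiorobust.tda import extract_tda
from radiorobust.types import CohortConfig

cfg = CohortConfig(n_pos=1, n_neg=2, seed=5, shape=(64, 64, 40),
                   tumor_radius=9.0)
cohort, _ = make_cohort(cfg)
patches = []
for vs in cohort:
    patches.extend(patches_from_volume(normalize_iqr(vs)))
print(f"{len(patches)} patches")

orig = rio.feature_table(patches, extract_tda)
pert_rows = []
for sp in patches:
    for spec, psp in perturbation_suite(sp, seed=1):
        pert_rows.append(
            rio.feature_table([psp], extract_tda, spec.perturbation_id)
        )
pert = pd.concat(pert_rows, ignore_index=True)

table = icc_table(orig, pert)
print("\nmean ICC by perturbation class:")
print(table[list("RNTVC")].mean().round(3).to_string())
print("\nmean ICC by feature family:")
print(family_summary(table).round(3).to_string())
survivors = robust_filter(table, cutoff=0.75)
print(f"\n{len(survivors)}/{len(table)} topological features survive the "
      "0.75 cutoff under every perturbation class")
# Mask-changing perturbations (V, C) typically depress ICC the most: they
# alter the region the features are computed on.
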