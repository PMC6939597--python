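"""Shared-reference normalization across three acquisition methods.

Three simulated methods (think RP, HILIC, direct infusion) measure the same
two plasma pools with per-lipid response biases of up to ~3-fold.  Dividing
every concentration by the same method's reference-sample level cancels the
bias; the cross-method CoV falls to the technical level and PCA can no
longer separate the methods.
"""

import pandas as pd

from lipidharmony import (
    centroid_separation, cross_method_cov, pca_scores,
    reference_normalize, summarize_reference, to_concentration,
)
from lipidharmony.simulate import SimulationConfig, build_is_map, generate

cfg = SimulationConfig(
    classes=("PC", "LPC", "PE", "SM", "TG"), lipids_per_class=15,
    technical_cov=0.08, bias_sigma_log=0.5, seed=1,
)
tables, truth = generate(cfg)
is_map = build_is_map(cfg)
concs = {m: to_concentration(t, truth.species_index, is_map, method=m)
         for m, t in tables.items()}

normalized = {}
for m, c in concs.items():
    normalized[m], _ = reference_normalize(c, summarize_reference(c, "mean"))


def separation(tabs):
    study = pd.concat({m: c.study_values() for m, c in tabs.items()}, axis=1)
    scores, _ = pca_scores(study.T.to_numpy(), 2)
    return centroid_separation(scores, [m for m, _ in study.T.index])


pre = cross_method_cov(concs, sample="poolA")
post = cross_method_cov(normalized, sample="poolA")
print(f"median cross-method CoV over 15 measurements (5 replicates × 3 methods):")
print(f"  before normalization: {100 * pre.median():5.1f}%")
print(f"  after  normalization: {100 * post.median():5.1f}%   "
      f"(injected technical noise: 8%)")
print(f"PCA centroid separation (between-method / within-method):")
print(f"  before: {separation(concs):6.2f}   after: {separation(normalized):6.2f}")
print("\nAfter normalization the methods agree to within the technical noise; "
      "the score plot\nno longer separates them, only the two plasma pools.")
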