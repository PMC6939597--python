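"""Median-fold alignment of two laboratories to a shared reference sample.

Two sites measure the same study samples with site-specific per-lipid biases
and share replicates of one pooled reference.  Dividing each site's values by
the per-lipid median of its reference replicates (then rescaling by the
cross-site median factor) restores agreement.
"""

from lipidharmony import median_fold_align, pairwise_correlation, to_concentration
from lipidharmony.simulate import SimulationConfig, build_is_map, generate

cfg = SimulationConfig(
    classes=("PC", "LPC", "PE", "SM", "TG"), lipids_per_class=15,
    methods=("site1", "site2"), technical_cov=0.08, bias_sigma_log=0.5, seed=2,
)
tables, truth = generate(cfg)
is_map = build_is_map(cfg)
concs = {m: to_concentration(t, truth.species_index, is_map, method=m)
         for m, t in tables.items()}

means = {m: c.study_values().mean(axis=1) for m, c in concs.items()}
r_pre, n = pairwise_correlation(means["site1"], means["site2"], scale="log10")

aligned = median_fold_align(concs, rescale="grand-median")
ameans = {m: c.study_values().mean(axis=1) for m, c in aligned.items()}
r_post, _ = pairwise_correlation(ameans["site1"], ameans["site2"], scale="log10")

print(f"log10-scale Pearson r between sites over {n} lipids "
      f"(panel spans ~3 orders of magnitude):")
print(f"  before alignment: r = {r_pre:.3f}")
print(f"  after  alignment: r = {r_post:.4f}")
print("\nThe residual scatter before alignment is the per-lipid site bias; "
      "median-fold\ncorrection to the shared reference removes it.")
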