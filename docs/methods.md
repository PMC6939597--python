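# Methods

## Species model and nomenclature

Lipids are handled at the species ("bond type") level: class code, total
chain carbons C, total double bonds D, and a bond-type qualifier — diacyl
ester, ether (`O-`), plasmenyl/vinyl-ether (`P-`), or a dihydroxy sphingoid
base (`d`). sn-positions, double-bond positions, oxidized lipids and adduct
chemistry are out of scope. Individual chains are retained when a name
states them (`Cer d18:1/17:0`); a trailing `-d<n>` marks a deuterated
internal standard, which is treated as an opaque feature (its own isotope
envelope is never computed — it only ever serves as a denominator).

Elemental compositions come from per-class affine templates
`count(element) = a·C + b·D + c`, shipped as `data/class_templates.yaml` and
overridable. The shipped coefficients were derived by structural assembly
(glycerol or sphingoid backbone + head group + fatty acyls, with one water
per condensation) and the test suite re-derives them against an independent
assembly oracle; e.g. PC → C(C+8) H(2C−2D+16) N O₈ P, TG → C(C+3) H(2C−2D+2)
O₆. Ether species are the diacyl composition −O +2H; plasmenyl `P-C:D` is
evaluated as `O-C:(D+1)` (the vinyl-ether double bond belongs to the
composition, the name keeps its `P-` form). SM and Cer assume a d-type
(dihydroxy) base uniformly, since sum-level names do not identify the base.

## Isotope model and M+2 correction

Isotopologues are aggregated at nominal mass: the probability that a
molecule's total neutron excess equals *j* is obtained by convolving
per-element isotope distributions (truncated polynomial multiplication with
binary exponentiation, exact for the retained orders), then expressed
relative to the monoisotopic peak (a₀ = 1). No isotopic fine structure is
computed: at the ~20 ppm extraction windows of high-resolution full-scan
lipidomics the donor's whole M+2 cluster is co-integrated, so the aggregated
model is the appropriate one. Abundances (IUPAC/CIAAW representative
values) ship as `data/abundances.yaml`.

Only the within-class, same-carbon, ΔDB = 1 interference (Δm = 2 Da) is
corrected; no lipid pair in scope differs by 1 Da, so M+1 is untouched.
Each series is processed in decreasing double-bond order (lightest species
first), subtracting the already-corrected neighbor's predicted M+2.
Ether/plasmenyl species form separate series from diacyl species (their
compositions differ). Negative corrected intensities — possible under noise
— are clamped to zero and flagged per feature rather than propagated. The
correction is exposed as an explicit, optional pipeline stage, since
chromatographically resolved data (RP) may not need it.

## Quantitation

`c_ij = (I_ij / I_IS(i),j) · A_IS(i) / V`, with spiked amount A in pmol and
plasma volume V in µL, so units are pmol/µL ≡ µmol/L plasma. Defaults:
V = 10 µL; A = 100 pmol per class (the ceramide spike is 100 pmol; the
per-class amounts of a commercial mix vary and are configured per
experiment, so a uniform nominal default is shipped and fully overridable).
Species-level overrides (stable-isotope-labeled analogs) win over the class
standard; plasmenyl and ether species resolve to the diacyl standard of
their class. No species-specific response-factor correction is applied
(class-level, "Level 2" quantitation). Injections with zero/missing IS
intensity yield missing values with a warning; missing never becomes zero,
and downstream statistics use pairwise-complete semantics.

## QC filtering

Three per-lipid filters, all strict inequalities (a statistic exactly at
its threshold fails):

1. CoV < 0.20 over the replicate QC (long-term-reference) injections,
   computed on IS-normalized ratios with the n−1 standard deviation;
2. blank ratio < 0.10 — mean raw intensity over the blank extractions
   divided by the mean over QC injections (intensities, not concentrations,
   because blanks contain IS but no analyte; missing blank values count as
   zero; a `max`-blank variant is available for a stricter cut);
3. dilution R² > 0.90 — OLS with intercept of the IS-normalized response on
   the dilution fraction, restricted to the 0.5–2.0 portion of the
   10–200% seven-point design. The intercept is included because an
   additive background is plausible and an origin-forced fit inflates R² on
   offset data; the in-range-only reading of the design is implemented
   (fitting all seven points is possible by widening the range).

A missing statistic fails its criterion (conservative); a wholly absent
role (no blanks measured, say) fails by default but can be configured to
skip. The report stores every statistic alongside the verdicts so the
survivor list is exactly recomputable from the report.

## Shared-reference normalization and alignment

For each method, every concentration is divided by that method's central
reference-sample value for the lipid; multiplying by a consensus
concentration (MEDM) is optional and restores absolute units, recorded as a
forward-only provenance state (raw → reference-normalized →
consensus-scaled). The central value is the mean for reference
normalization (the quantity is a mean in the defining equation) and the
median for median-fold alignment; both are exposed as a policy. Ratios are
formed on the concentration scale, not the log scale — the defining
equation is linear and medians provide the robustness. Lipids without a
positive reference value (or, when scaling, without a consensus entry) are
dropped and reported, never passed through un-normalized: normalization is
only possible for compounds present in both study and reference material.
Median-fold alignment medians over reference *replicates* per lipid (the
per-lipid reading, consistent with the reference-normalization equation),
not over lipids per sample; `grand-median` rescaling multiplies the
cross-site median factor back in to keep concentration-like units.

The noise-free guarantee, asserted to machine precision in the tests: any
strictly positive per-lipid, per-method multiplicative bias applied
uniformly to study and reference columns cancels exactly.

## Evaluation metrics

- Cross-method CoV pools the replicate-level values of one sample across
  methods (5 replicates × 3 methods → one 15-vector) — replicate values,
  not method means, and within a single sample so biological differences do
  not enter.
- Fold-from-average: each method's mean as a ratio to the unweighted mean
  of method means; rows average to 1 by construction. Percent deviations
  derive from the ratios.
- PCA: column-mean-centered SVD, no variance scaling and no transformation
  (centering is implicit in the usual tooling even when "scaling: none" is
  selected); component signs fixed so each component's largest-magnitude
  loading is positive; input must be complete (restrict to lipids
  quantified everywhere first). The centroid-separation statistic is mean
  between-group centroid distance over mean within-group distance to
  centroid.
- Correlations: Pearson, optionally on log10 scale (the scale of
  cross-platform scatter plots); non-positive pairs are dropped on the log
  scale with the used-pair count reported.

## Synthetic data generator

The generator emulates the study design the workflow assumes, per method:
two plasma pools in `n_replicates` (default 5), `n_qc` = 10 replicate QC
injections, `n_blank` = 4 blank extractions, a 10/25/50/75/100/150/200%
dilution series with 2 replicates per point, and `n_reference` = 5
replicates of a shared reference material. The observation model is

    I = c_true · V/A · I_IS · b(lipid, method) · (1 + ε),

with bias `b ~ LogNormal(0, σ_log)` (default σ_log = 0.5, spanning up to
~3-fold — the scale of reported cross-platform differences) constant within
a method, and technical noise `ε ~ N(0, τ)` truncated at −0.9 (default
τ = 0.08). Noise is attached to the analyte response; the internal-standard
rows are the noiseless denominator, so τ is the CoV of a quantified
concentration. A per-injection global intensity factor (spray variability)
and a sample-dependent bias term (to demonstrate the residual-bias
limitation of reference normalization) are available but default to off.

Concentration profiles are log-normal across lipids with σ_ln = 1.15, so a
75-lipid panel spans roughly three orders of magnitude, as a plasma panel
does. The two pools differ by planted 2-fold changes on 10 lipids drawn
from the below-median-abundance half of the panel (bulk structural lipid
levels are homeostatic between healthy plasma pools; biological variation
concentrates in minor species). The reference material is plasma like the
study pools: its true profile is the pool mix perturbed by
LogNormal(0, 0.3) per lipid, never an unrelated profile — a reference must
share the study matrix for the workflow to apply, and 100-fold
study/reference discrepancies do not occur between human plasma pools.
Reference columns are generated with the *same* bias factors as study
columns of their method, which is precisely the regime the normalization
cancels. Optional stages plant QC failures in disjoint subsets
(blank contamination at 30% of QC signal; a deterministic ±50% alternation
across QC injections giving a guaranteed CoV ≈ 0.53; a flat dilution
response), apply the forward M+2 overlap model, or delete lipids from the
reference to exercise the drop-and-report path. Everything is reproducible
bit-for-bit from (config, seed).

What the generator does *not* emulate: raw spectra, retention-time or
ion-suppression physics, batch drift, heteroscedastic or correlated noise,
missingness mechanisms, and isotope envelopes of deuterated standards.
Passing tests therefore demonstrate the algebraic and statistical behavior
of the workflow under its stated assumptions — multiplicative,
sample-independent method bias — not performance on raw instrument data.

## Problem sizes and numerical choices

The test suite and the reproduction script use a 75-lipid, 3-method design
(5 classes × 15 species) for harmonization checks, a 208-species 13-class
panel for the isotope round trip, and a 450-feature panel for the planted
QC count — sizes chosen to mirror the corresponding study designs while
completing in seconds. Tolerances: isotope patterns agree with exhaustive
enumeration to 1e-9; noise-free round trips (de-isotoping, end-to-end
recovery, bias cancellation) to 1e-9–1e-12 relative; noisy assertions use
the bounds stated with each test. Ties and degenerate inputs: CoV is
undefined (missing) below two values or at non-positive mean; R² of a flat
response is 0; PCA truncates at matrix rank with a warning; zero reference
values drop the lipid with a warning rather than dividing.
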