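"""Shared-reference normalization and median-fold cross-site alignment.

Different acquisition methods (and laboratories) report systematically
different concentrations for the same lipid in the same sample — a per-lipid,
per-method multiplicative bias that survives class-specific internal-standard
quantitation.  Measuring a shared reference material (e.g. NIST SRM 1950
plasma, or a pooled QC) with the study samples lets that bias cancel:

    c_norm(sample j, lipid i) = c(sample j, lipid i) / c̄_ref(lipid i, method)
                                [× c_consensus(lipid i)]

Division by the method's own reference level removes any bias common to study
and reference columns; the optional consensus multiplier (e.g. MEDM — median
of laboratory means) restores absolute µmol/L units, otherwise values are
dimensionless ratios to the reference.  ``median_fold_align`` is the same
idea for multi-site meta-analysis: each site's values are divided per lipid
by the median of that site's shared-reference replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nomenclature import format_shorthand, parse_shorthand
from .tables import ConcentrationTable, NormalizationState, Role

__all__ = [
    "ConsensusValues",
    "ReferenceSummary",
    "summarize_reference",
    "reference_normalize",
    "median_fold_align",
]


@dataclass(frozen=True)
class ConsensusValues:
    """Per-lipid community concentrations for the reference material (µmol/L)."""

    values: Mapping[str, float]
    provenance: str = "MEDM"

    def __post_init__(self) -> None:
        canonical = {}
        for name, value in self.values.items():
            if value <= 0:
                raise ValueError(f"consensus value for {name!r} must be > 0")
            try:
                key = format_shorthand(parse_shorthand(name))
            except Exception:
                key = name  # opaque feature: keep the raw name
            canonical[key] = float(value)
        object.__setattr__(self, "values", canonical)

    @classmethod
    def from_csv(cls, path: str) -> "ConsensusValues":
        df = pd.read_csv(path)
        prov = str(df["provenance"].iloc[0]) if "provenance" in df.columns and len(df) else "MEDM"
        return cls(dict(zip(df["lipid"], df["value"].astype(float))), provenance=prov)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"lipid": list(self.values), "value": list(self.values.values()),
             "unit": "umol/L", "provenance": self.provenance}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ReferenceSummary:
    """Central reference-sample level per lipid for one method/site."""

    values: pd.Series  # lipid → central value
    counts: pd.Series  # lipid → replicate count used
    method: str
    policy: str


def summarize_reference(
    conc: ConcentrationTable, policy: str = "mean"
) -> ReferenceSummary:
    """Central value of the reference-sample replicates, per lipid.

    ``mean`` matches the reference-normalization equation (c̄); ``median``
    is the robust choice used for median-fold alignment.
    """
    if policy not in ("mean", "median"):
        raise ValueError("policy must be 'mean' or 'median'")
    ref = conc.subset_role(Role.REFERENCE)
    if ref.shape[1] == 0:
        raise ValueError(f"no reference-sample columns in table for {conc.method!r}")
    central = ref.mean(axis=1) if policy == "mean" else ref.median(axis=1)
    counts = ref.notna().sum(axis=1)
    all_missing = counts == 0
    if all_missing.any():
        warnings.warn(
            f"lipids with all-missing reference values in {conc.method!r}: "
            f"{list(central.index[all_missing])}",
            stacklevel=2,
        )
    return ReferenceSummary(central, counts, conc.method, policy)


def reference_normalize(
    conc: ConcentrationTable,
    ref: ReferenceSummary,
    consensus: ConsensusValues | None = None,
) -> tuple[ConcentrationTable, list[str]]:
    """Normalize a table to its method's reference-sample levels.

    Every value is divided by the same-method reference central value of its
    lipid; with ``consensus`` the ratio is multiplied by the consensus
    concentration, restoring µmol/L.  Lipids without a positive reference
    value (or, when scaling, without a consensus value) are dropped; the
    second return value lists them.
    """
    if ref.method != conc.method:
        raise ValueError(
            f"reference summary is for method {ref.method!r}, table is {conc.method!r}"
        )
    dropped: list[str] = []
    keep: list[str] = []
    for lipid in conc.lipids:
        r = ref.values.get(lipid, np.nan)
        if not (r > 0):
            dropped.append(lipid)
            continue
        if consensus is not None and lipid not in consensus.values:
            dropped.append(lipid)
            continue
        keep.append(lipid)
    if dropped:
        warnings.warn(
            f"{len(dropped)} lipid(s) dropped during normalization for "
            f"{conc.method!r} (no usable reference/consensus value)",
            stacklevel=2,
        )
    values = conc.values.loc[keep].div(ref.values.loc[keep], axis=0)
    state = NormalizationState.REFERENCE_NORMALIZED
    if consensus is not None:
        scale = pd.Series({lip: consensus.values[lip] for lip in keep})
        values = values.mul(scale, axis=0)
        state = NormalizationState.CONSENSUS_SCALED
    return conc.with_values(values, state=state), dropped


def median_fold_align(
    site_tables: Mapping[str, ConcentrationTable],
    rescale: str = "ratio",
) -> dict[str, ConcentrationTable]:
    """Median-fold correction of several sites to their shared reference.

    Per lipid and site, the scale factor is the median of that site's
    reference-sample replicates; study values are divided by it.  With
    ``rescale='grand-median'`` the cross-site median factor is multiplied
    back in, keeping concentration-like units.  Lipids missing a positive
    reference level at a site are excluded from that site's output.
    """
    if rescale not in ("ratio", "grand-median"):
        raise ValueError("rescale must be 'ratio' or 'grand-median'")
    if len(site_tables) < 2:
        raise ValueError("alignment needs at least two sites")

    factors: dict[str, pd.Series] = {}
    for site, table in site_tables.items():
        summary = summarize_reference(table, policy="median")
        factors[site] = summary.values

    common = None
    for site, f in factors.items():
        ok = set(f.index[f > 0])
        common = ok if common is None else common & ok
    factor_frame = pd.DataFrame({s: f for s, f in factors.items()}).loc[sorted(common)]
    grand = factor_frame.median(axis=1)

    aligned: dict[str, ConcentrationTable] = {}
    for site, table in site_tables.items():
        f = factors[site]
        keep = [lip for lip in table.lipids if lip in common]
        values = table.values.loc[keep].div(f.loc[keep], axis=0)
        if rescale == "grand-median":
            values = values.mul(grand.loc[keep], axis=0)
        aligned[site] = table.with_values(
            values, state=NormalizationState.REFERENCE_NORMALIZED
        )
    return aligned
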