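"""In-memory containers: intensity matrices and concentration matrices.

A :class:`MeasurementTable` is a features × injections intensity matrix plus
an injection-metadata frame (sample, role, method, batch, dilution fraction,
replicate).  A :class:`ConcentrationTable` is the quantified counterpart:
lipids × injections in µmol/L plasma for one method/site, with a
normalization-state provenance tag that only moves forward
(raw → reference-normalized → consensus-scaled).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Role", "MeasurementTable", "ConcentrationTable", "SchemaError"]


class SchemaError(ValueError):
    """Input tables violate the expected schema."""


class Role:
    STUDY = "study"
    QC_LTR = "qc_ltr"
    BLANK = "blank"
    REFERENCE = "reference"
    DILUTION = "dilution"

    ALL = (STUDY, QC_LTR, BLANK, REFERENCE, DILUTION)


METADATA_COLUMNS = ("sample", "role", "method", "batch", "dilution_fraction", "replicate")


def _validate_injections(injections: pd.DataFrame) -> pd.DataFrame:
    meta = injections.copy()
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            if col in ("batch", "replicate"):
                meta[col] = 0
            elif col == "dilution_fraction":
                meta[col] = np.nan
            else:
                raise SchemaError(f"injection metadata lacks column {col!r}")
    unknown = set(meta["role"]) - set(Role.ALL)
    if unknown:
        raise SchemaError(f"unknown injection roles: {sorted(unknown)}")
    is_dil = meta["role"] == Role.DILUTION
    if meta.loc[is_dil, "dilution_fraction"].isna().any():
        bad = meta.index[is_dil & meta["dilution_fraction"].isna()].tolist()
        raise SchemaError(f"dilution injections missing dilution_fraction: {bad}")
    if meta.loc[~is_dil, "dilution_fraction"].notna().any():
        bad = meta.index[~is_dil & meta["dilution_fraction"].notna()].tolist()
        raise SchemaError(f"non-dilution injections carry a dilution_fraction: {bad}")
    return meta


@dataclass(frozen=True)
class MeasurementTable:
    intensities: pd.DataFrame
    injections: pd.DataFrame
    deisotoped: bool = False
    clamped_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "injections", _validate_injections(self.injections))
        missing = set(self.intensities.columns) ^ set(self.injections.index)
        if missing:
            raise SchemaError(
                f"intensity columns and injection metadata disagree on: {sorted(missing)}"
            )
        # align metadata row order with the matrix columns
        object.__setattr__(
            self, "injections", self.injections.loc[list(self.intensities.columns)]
        )
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise SchemaError("negative intensities are not allowed")

    @property
    def features(self) -> list[str]:
        return list(self.intensities.index)

    def columns_with_role(self, role: str) -> list[str]:
        return list(self.injections.index[self.injections["role"] == role])

    def subset_role(self, role: str) -> pd.DataFrame:
        return self.intensities[self.columns_with_role(role)]

    def with_intensities(self, intensities: pd.DataFrame, **updates) -> "MeasurementTable":
        return replace(self, intensities=intensities, **updates)


class NormalizationState:
    RAW = "raw"
    REFERENCE_NORMALIZED = "reference-normalized"
    CONSENSUS_SCALED = "consensus-scaled"

    ORDER = (RAW, REFERENCE_NORMALIZED, CONSENSUS_SCALED)


@dataclass(frozen=True)
class ConcentrationTable:
    """Lipid × injection concentrations (µmol/L plasma) for one method/site."""

    values: pd.DataFrame
    injections: pd.DataFrame
    method: str
    state: str = NormalizationState.RAW

    def __post_init__(self) -> None:
        if self.state not in NormalizationState.ORDER:
            raise SchemaError(f"unknown normalization state {self.state!r}")
        object.__setattr__(self, "injections", _validate_injections(self.injections))
        missing = set(self.values.columns) ^ set(self.injections.index)
        if missing:
            raise SchemaError(
                f"value columns and injection metadata disagree on: {sorted(missing)}"
            )
        object.__setattr__(
            self, "injections", self.injections.loc[list(self.values.columns)]
        )

    @property
    def lipids(self) -> list[str]:
        return list(self.values.index)

    def columns_with_role(self, role: str) -> list[str]:
        return list(self.injections.index[self.injections["role"] == role])

    def subset_role(self, role: str) -> pd.DataFrame:
        return self.values[self.columns_with_role(role)]

    def study_values(self) -> pd.DataFrame:
        return self.subset_role(Role.STUDY)

    def advance_state(self, new_state: str) -> str:
        order = NormalizationState.ORDER
        if order.index(new_state) < order.index(self.state):
            raise SchemaError(
                f"normalization state may only move forward "
                f"({self.state!r} → {new_state!r})"
            )
        return new_state

    def with_values(self, values: pd.DataFrame, state: str | None = None) -> "ConcentrationTable":
        new_state = self.state if state is None else self.advance_state(state)
        meta = self.injections.loc[[c for c in values.columns]]
        return ConcentrationTable(values, meta, self.method, new_state)
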