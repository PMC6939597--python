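"""Internal-standard quantitation: intensities → concentrations in µmol/L plasma.

Each lipid class carries one spiked internal standard (IS) of known amount;
the analyte-to-IS intensity ratio times the spiked amount, divided by the
plasma volume processed, gives the concentration:

    c_ij = (I_ij / I_IS(i),j) × amount_IS(i) / V_plasma      [pmol/µL ≡ µmol/L]

Species-level overrides map an endogenous lipid to a species-specific
(isotope-labeled) standard; plasmenyl and ether species resolve to the diacyl
IS of their class.  No species-specific response-factor correction is applied
(class-level, "Level 2" quantitation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .nomenclature import LipidSpecies
from .tables import ConcentrationTable, MeasurementTable, Role

__all__ = [
    "InternalStandardMap",
    "ISMappingError",
    "resolve_internal_standard",
    "to_concentration",
    "DEFAULT_PLASMA_VOLUME_UL",
]

#: µL of plasma behind one processed sample aliquot
DEFAULT_PLASMA_VOLUME_UL = 10.0


class ISMappingError(KeyError):
    pass


@dataclass(frozen=True)
class InternalStandardMap:
    """lipid class → (IS feature id, spiked pmol); optional species overrides."""

    class_map: Mapping[str, tuple[str, float]]
    species_overrides: Mapping[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scope, mapping in (("class", self.class_map), ("species", self.species_overrides)):
            for key, (feature, amount) in mapping.items():
                if amount <= 0:
                    raise ValueError(
                        f"spiked amount for {scope} {key!r} must be > 0, got {amount}"
                    )

    @classmethod
    def from_yaml(cls, path: str) -> "InternalStandardMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            class_map={
                k: (v["feature"], float(v["amount_pmol"]))
                for k, v in raw.get("classes", {}).items()
            },
            species_overrides={
                k: (v["feature"], float(v["amount_pmol"]))
                for k, v in raw.get("species", {}).items()
            },
        )


def resolve_internal_standard(
    species: LipidSpecies, is_map: InternalStandardMap
) -> tuple[str, float]:
    """Return (IS feature id, spiked pmol) for a species.

    A species-level override wins; otherwise the class IS is used.  Ether and
    plasmenyl species fall back to the diacyl standard of their class.
    """
    override = is_map.species_overrides.get(species.name)
    if override is not None:
        return override
    entry = is_map.class_map.get(species.lipid_class)
    if entry is None:
        raise ISMappingError(
            f"no internal standard mapped for class {species.lipid_class!r}"
        )
    return entry


def to_concentration(
    table: MeasurementTable,
    species_index: Mapping[str, LipidSpecies],
    is_map: InternalStandardMap,
    plasma_volume_ul: float = DEFAULT_PLASMA_VOLUME_UL,
    method: str = "",
) -> ConcentrationTable:
    """Quantify all mapped features of a (de-isotoped) measurement table.

    Features without a parsed species are skipped; internal-standard features
    are consumed as denominators, not quantified.  Injections whose IS
    intensity is zero or missing get missing values for the affected lipids,
    with a warning.
    """
    if plasma_volume_ul <= 0:
        raise ValueError("plasma volume must be positive")
    intens = table.intensities
    rows: dict[str, pd.Series] = {}
    bad_is: set[str] = set()
    for feature, species in species_index.items():
        if species.is_internal_standard or feature not in intens.index:
            continue
        is_feature, amount = resolve_internal_standard(species, is_map)
        if is_feature not in intens.index:
            raise ISMappingError(
                f"internal-standard feature {is_feature!r} absent from the table"
            )
        is_row = intens.loc[is_feature]
        invalid = ~(is_row > 0)
        if invalid.any():
            bad_is.update(is_row.index[invalid])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = intens.loc[feature] / is_row
        conc = ratio * amount / plasma_volume_ul
        conc[invalid] = np.nan
        rows[species.name] = conc
    if bad_is:
        warnings.warn(
            f"zero or missing internal-standard intensity in injections "
            f"{sorted(bad_is)}; affected values set to missing",
            stacklevel=2,
        )
    values = pd.DataFrame(rows).T
    values = values.reindex(columns=intens.columns)
    return ConcentrationTable(values, table.injections, method=method)
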