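"""Aggregated nominal-mass isotopologue patterns and M+2 interference correction.

Within a lipid class, species that differ by one double bond differ by 2 Da:
the two-neutron isotopologue (M+2) of the more unsaturated species lands on
the monoisotopic peak of its saturated analog and inflates its signal.  At the
extraction windows typical of high-resolution full-scan lipidomics the donor's
whole M+2 cluster is co-integrated, so isotopologues are aggregated at nominal
mass (no fine structure).  ``deisotope`` walks each double-bond series from
the most unsaturated (lightest) species downward, subtracting the predicted
M+2 contribution of the already-corrected neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .nomenclature import LipidSpecies, composition, ClassTemplate
from .tables import MeasurementTable

__all__ = [
    "AbundanceTable",
    "IsotopePattern",
    "load_abundances",
    "default_abundances",
    "isotope_pattern",
    "m2_ratio",
    "deisotope",
]


class UnknownElementError(KeyError):
    pass


@dataclass(frozen=True)
class AbundanceTable:
    """Per-element natural isotope abundances as (offset, abundance) pairs.

    Offsets are neutron excess over the lightest stable isotope; abundances
    per element sum to 1.
    """

    elements: Mapping[str, tuple[tuple[int, float], ...]]

    def __post_init__(self) -> None:
        for el, pairs in self.elements.items():
            total = sum(p for _, p in pairs)
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"abundances for {el} sum to {total}, not 1")
            if any(off < 0 or not (0 <= p <= 1) for off, p in pairs):
                raise ValueError(f"invalid offset/abundance pair for {el}")

    def distribution(self, element: str, depth: int) -> np.ndarray:
        if element not in self.elements:
            raise UnknownElementError(f"no isotope data for element {element!r}")
        dist = np.zeros(depth + 1)
        for offset, abundance in self.elements[element]:
            if offset <= depth:
                dist[offset] += abundance
        return dist


@dataclass(frozen=True)
class IsotopePattern:
    """Relative abundances a_0..a_k of isotopologues M+0..M+k, a_0 = 1."""

    abundances: tuple[float, ...]

    @property
    def a1(self) -> float:
        return self.abundances[1] if len(self.abundances) > 1 else 0.0

    @property
    def a2(self) -> float:
        return self.abundances[2] if len(self.abundances) > 2 else 0.0

    def __getitem__(self, j: int) -> float:
        return self.abundances[j]


_DEFAULT_ABUNDANCES: AbundanceTable | None = None


def load_abundances(path: str) -> AbundanceTable:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return AbundanceTable(
        {el: tuple((int(o), float(p)) for o, p in pairs) for el, pairs in raw.items()}
    )


def default_abundances() -> AbundanceTable:
    global _DEFAULT_ABUNDANCES
    if _DEFAULT_ABUNDANCES is None:
        path = resources.files("lipidharmony.data") / "abundances.yaml"
        _DEFAULT_ABUNDANCES = load_abundances(str(path))
    return _DEFAULT_ABUNDANCES


def isotope_pattern(
    comp: Mapping[str, int],
    depth: int = 2,
    abundances: AbundanceTable | None = None,
) -> IsotopePattern:
    """Aggregated nominal-mass isotope pattern of a composition.

    The probability that the molecule's total neutron excess equals j is the
    convolution of the per-atom isotope distributions, truncated at ``depth``;
    the result is reported relative to the monoisotopic peak (a_0 = 1).
    Per-element powers are computed by binary exponentiation of the truncated
    polynomial, which is exact for the retained orders.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if abundances is None:
        abundances = default_abundances()

    pattern = np.zeros(depth + 1)
    pattern[0] = 1.0
    for element, count in comp.items():
        if count == 0:
            continue
        if count < 0:
            raise ValueError(f"negative count for element {element}")
        base = abundances.distribution(element, depth)
        pattern = _convolve_trunc(pattern, _power_trunc(base, count, depth), depth)
    if pattern[0] <= 0:
        raise ValueError("monoisotopic probability vanished; cannot normalize")
    return IsotopePattern(tuple(pattern / pattern[0]))


def _convolve_trunc(a: np.ndarray, b: np.ndarray, depth: int) -> np.ndarray:
    return np.convolve(a, b)[: depth + 1]


def _power_trunc(base: np.ndarray, n: int, depth: int) -> np.ndarray:
    result = np.zeros(depth + 1)
    result[0] = 1.0
    acc = base.copy()
    while n:
        if n & 1:
            result = _convolve_trunc(result, acc, depth)
        n >>= 1
        if n:
            acc = _convolve_trunc(acc, acc, depth)
    return result


def m2_ratio(
    species: LipidSpecies,
    templates: Mapping[str, ClassTemplate] | None = None,
    abundances: AbundanceTable | None = None,
) -> float:
    """M+2 abundance relative to the monoisotopic peak for a species."""
    return isotope_pattern(composition(species, templates), 2, abundances).a2


class AmbiguousSeriesError(ValueError):
    """Two features map to the same (class, bond type, carbons, double bonds)."""


def deisotope(
    table: MeasurementTable,
    species_index: Mapping[str, LipidSpecies],
    templates: Mapping[str, ClassTemplate] | None = None,
    abundances: AbundanceTable | None = None,
) -> MeasurementTable:
    """Remove M+2 isotopic interference along double-bond series.

    Within each (class, bond type, total carbons) group, species are processed
    in decreasing double-bond order (lightest mass first):

        corrected(C:D) = measured(C:D) − corrected(C:D+1) × m2_ratio(C:D+1)

    Only the ΔDB = 1 neighbor donates (Δmass = 2 Da).  Species with no such
    neighbor pass through unchanged; features absent from ``species_index``
    (opaque features, internal standards) are untouched.  Negative corrected
    intensities are clamped to zero and flagged in ``clamped_features``.
    """
    values = table.intensities.copy()
    series: dict[tuple, dict[int, str]] = {}
    for feature, species in species_index.items():
        if feature not in values.index or species.is_internal_standard:
            continue
        key = species.series_key()
        group = series.setdefault(key, {})
        if species.total_double_bonds in group:
            raise AmbiguousSeriesError(
                f"duplicate species {species.name}: features "
                f"{group[species.total_double_bonds]!r} and {feature!r}"
            )
        group[species.total_double_bonds] = feature

    clamped: list[str] = []
    for key, group in series.items():
        for dbs in sorted(group, reverse=True):
            donor = group.get(dbs + 1)
            if donor is None:
                continue
            feature = group[dbs]
            ratio = m2_ratio(species_index[donor], templates, abundances)
            corrected = values.loc[feature] - values.loc[donor] * ratio
            if (corrected < 0).any():
                clamped.append(feature)
                corrected = corrected.clip(lower=0)
            values.loc[feature] = corrected

    return table.with_intensities(
        values, deisotoped=True, clamped_features=tuple(sorted(clamped))
    )
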