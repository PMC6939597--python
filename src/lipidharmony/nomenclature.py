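"""Lipid shorthand nomenclature: parsing, canonical formatting, elemental composition.

Lipids are handled at the species ("bond type") level: a class code, total
acyl-chain carbons, total double bonds, and a bond-type qualifier
(diacyl ester, ether ``O-``, plasmenyl ``P-``, or a dihydroxy sphingoid base
``d``).  Individual chains (``Cer d18:1/17:0``) are kept when the name states
them.  Elemental compositions are derived from per-class affine templates in
(carbons, double bonds), shipped as editable YAML and overridable at run time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "BondType",
    "LipidSpecies",
    "ClassTemplate",
    "LipidParseError",
    "TemplateError",
    "parse_shorthand",
    "format_shorthand",
    "composition",
    "load_class_templates",
    "default_class_templates",
]


class LipidParseError(ValueError):
    """A shorthand name could not be parsed; the message names the bad token."""


class TemplateError(KeyError):
    """No composition template is available for a lipid class."""


class BondType:
    DIACYL = "diacyl"
    ETHER = "ether"       # O- prefix: one chain alkyl-ether linked
    PLASMENYL = "plasmenyl"  # P- prefix: vinyl-ether (plasmalogen)
    SPHINGOID = "sphingoid-d"  # d-prefixed dihydroxy long-chain base

    ALL = (DIACYL, ETHER, PLASMENYL, SPHINGOID)


#: classes built on a sphingoid base; always bond_type sphingoid-d here
SPHINGOID_CLASSES = frozenset({"SM", "Cer"})

#: controlled vocabulary of class codes
KNOWN_CLASSES = (
    "PC", "LPC", "PE", "LPE", "PI", "PS", "PG", "PA",
    "SM", "Cer", "DG", "TG", "CE",
)


@dataclass(frozen=True)
class Chain:
    carbons: int
    double_bonds: int
    kind: str = "acyl"  # acyl | sphingoid-d | ether | plasmenyl

    def __str__(self) -> str:
        prefix = {"sphingoid-d": "d", "ether": "O-", "plasmenyl": "P-"}.get(self.kind, "")
        return f"{prefix}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid at species level — the unit of quantitation."""

    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    bond_type: str = BondType.DIACYL
    chains: tuple[Chain, ...] | None = None
    is_internal_standard: bool = False
    label_deuterium: int = 0

    def __post_init__(self) -> None:
        if self.lipid_class not in KNOWN_CLASSES:
            raise LipidParseError(f"unknown lipid class code {self.lipid_class!r}")
        if self.total_carbons <= 0:
            raise LipidParseError(f"total carbons must be positive, got {self.total_carbons}")
        if self.total_double_bonds < 0:
            raise LipidParseError(
                f"double-bond count must be non-negative, got {self.total_double_bonds}"
            )
        if self.bond_type not in BondType.ALL:
            raise LipidParseError(f"unknown bond type {self.bond_type!r}")
        if self.lipid_class in SPHINGOID_CLASSES and self.bond_type != BondType.SPHINGOID:
            raise LipidParseError(
                f"{self.lipid_class} species carry a sphingoid-d base; got {self.bond_type!r}"
            )
        if self.chains is not None:
            c = sum(ch.carbons for ch in self.chains)
            d = sum(ch.double_bonds for ch in self.chains)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise LipidParseError(
                    f"chain sums {c}:{d} inconsistent with totals "
                    f"{self.total_carbons}:{self.total_double_bonds}"
                )

    @property
    def name(self) -> str:
        return format_shorthand(self)

    def series_key(self) -> tuple[str, str, int]:
        """Group key for a double-bond series: same class, bond type, carbons.

        Members of one series differ by 2 Da per double bond, which is what the
        M+2 interference correction walks along.
        """
        return (self.lipid_class, self.bond_type, self.total_carbons)

    def __str__(self) -> str:
        return self.name


_TOKEN_RE = re.compile(
    r"^(?P<prefix>O-|P-|d)?(?P<carbons>\d+):(?P<dbs>\d+)$"
)
_LABEL_RE = re.compile(r"[-(]d(?P<count>\d+)\)?$")


def _parse_token(token: str) -> tuple[int, int, str | None]:
    m = _TOKEN_RE.match(token)
    if m is None:
        raise LipidParseError(f"malformed carbon:double-bond token {token!r}")
    prefix = m.group("prefix")
    kind = {None: None, "O-": "ether", "P-": "plasmenyl", "d": "sphingoid-d"}[prefix]
    return int(m.group("carbons")), int(m.group("dbs")), kind


def parse_shorthand(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name like ``PC 34:1`` or ``Cer d18:1/17:0``.

    Grammar: class code, whitespace or underscore, then either a summed token
    (optionally ``O-``/``P-``/``d``-prefixed) or ``/``-separated chain tokens.
    A trailing ``-d<n>`` or ``(d<n>)`` marks a deuterated internal standard.
    Formatting a parsed species and re-parsing is the identity.
    """
    if not name or not name.strip():
        raise LipidParseError("empty lipid name")
    text = name.strip()

    deuterium = 0
    label = _LABEL_RE.search(text)
    if label is not None:
        deuterium = int(label.group("count"))
        text = text[: label.start()]

    parts = re.split(r"[\s_]+", text.strip(), maxsplit=1)
    if len(parts) != 2:
        raise LipidParseError(f"cannot split class and chain tokens in {name!r}")
    cls, rest = parts
    if cls not in KNOWN_CLASSES:
        raise LipidParseError(f"unknown lipid class code {cls!r} in {name!r}")

    chain_tokens = rest.split("/")
    parsed = [_parse_token(tok) for tok in chain_tokens]

    if len(parsed) == 1:
        carbons, dbs, kind = parsed[0]
        if cls in SPHINGOID_CLASSES:
            if kind not in (None, "sphingoid-d"):
                raise LipidParseError(
                    f"{cls} takes a 'd' sphingoid prefix, not {chain_tokens[0]!r}"
                )
            bond_type = BondType.SPHINGOID
        else:
            bond_type = {
                None: BondType.DIACYL,
                "ether": BondType.ETHER,
                "plasmenyl": BondType.PLASMENYL,
            }.get(kind)
            if bond_type is None:
                raise LipidParseError(
                    f"'d' sphingoid prefix is not valid for class {cls}"
                )
        return LipidSpecies(
            cls, carbons, dbs, bond_type,
            is_internal_standard=deuterium > 0, label_deuterium=deuterium,
        )

    # explicit chains
    chains = []
    for i, (carbons, dbs, kind) in enumerate(parsed):
        if kind == "sphingoid-d" and i != 0:
            raise LipidParseError("sphingoid 'd' base must be the first chain")
        chains.append(Chain(carbons, dbs, kind or "acyl"))
    if cls in SPHINGOID_CLASSES:
        if chains[0].kind != "sphingoid-d":
            raise LipidParseError(
                f"{cls} chains must start with a d-prefixed sphingoid base"
            )
        if len(chains) > 2:
            raise LipidParseError(
                f"{cls} carries a base and one amide-linked chain, got {len(chains)}"
            )
        bond_type = BondType.SPHINGOID
    else:
        kinds = {ch.kind for ch in chains}
        if "ether" in kinds:
            bond_type = BondType.ETHER
        elif "plasmenyl" in kinds:
            bond_type = BondType.PLASMENYL
        else:
            bond_type = BondType.DIACYL
    return LipidSpecies(
        cls,
        sum(ch.carbons for ch in chains),
        sum(ch.double_bonds for ch in chains),
        bond_type,
        chains=tuple(chains),
        is_internal_standard=deuterium > 0,
        label_deuterium=deuterium,
    )


def format_shorthand(species: LipidSpecies) -> str:
    """Canonical shorthand name; ``parse_shorthand`` inverts it."""
    if species.chains is not None:
        body = "/".join(str(ch) for ch in species.chains)
    else:
        prefix = {
            BondType.DIACYL: "",
            BondType.ETHER: "O-",
            BondType.PLASMENYL: "P-",
            BondType.SPHINGOID: "d",
        }[species.bond_type]
        body = f"{prefix}{species.total_carbons}:{species.total_double_bonds}"
    name = f"{species.lipid_class} {body}"
    if species.label_deuterium:
        name += f"-d{species.label_deuterium}"
    return name


# ---------------------------------------------------------------------------
# elemental composition


@dataclass(frozen=True)
class ClassTemplate:
    """Affine composition rule per element as functions of (C, D).

    Each element maps to coefficients ``(a, b, c)`` meaning
    ``count = a*C + b*D + c`` where C is total chain carbons and D total
    double bonds.  ``chain_count`` is the number of chains the class carries.
    """

    lipid_class: str
    elements: Mapping[str, tuple[float, float, float]]
    chain_count: int

    def evaluate(self, carbons: int, double_bonds: int) -> dict[str, int]:
        comp: dict[str, int] = {}
        for element, (a, b, c) in self.elements.items():
            n = a * carbons + b * double_bonds + c
            count = int(round(n))
            if abs(n - count) > 1e-9 or count < 0:
                raise TemplateError(
                    f"template for {self.lipid_class} yields invalid {element} "
                    f"count {n} at {carbons}:{double_bonds}"
                )
            if count:
                comp[element] = count
        return comp


# (a, b, c) per element: count = a*C + b*D + c, for the diacyl / d-sphingoid form
_DEFAULT_TEMPLATES: dict[str, dict] = {
    "PC":  {"elements": {"C": (1, 0, 8),  "H": (2, -2, 16), "N": (0, 0, 1), "O": (0, 0, 8),  "P": (0, 0, 1)}, "chain_count": 2},
    "LPC": {"elements": {"C": (1, 0, 8),  "H": (2, -2, 18), "N": (0, 0, 1), "O": (0, 0, 7),  "P": (0, 0, 1)}, "chain_count": 1},
    "PE":  {"elements": {"C": (1, 0, 5),  "H": (2, -2, 10), "N": (0, 0, 1), "O": (0, 0, 8),  "P": (0, 0, 1)}, "chain_count": 2},
    "LPE": {"elements": {"C": (1, 0, 5),  "H": (2, -2, 12), "N": (0, 0, 1), "O": (0, 0, 7),  "P": (0, 0, 1)}, "chain_count": 1},
    "PI":  {"elements": {"C": (1, 0, 9),  "H": (2, -2, 15),                 "O": (0, 0, 13), "P": (0, 0, 1)}, "chain_count": 2},
    "PS":  {"elements": {"C": (1, 0, 6),  "H": (2, -2, 10), "N": (0, 0, 1), "O": (0, 0, 10), "P": (0, 0, 1)}, "chain_count": 2},
    "PG":  {"elements": {"C": (1, 0, 6),  "H": (2, -2, 11),                 "O": (0, 0, 10), "P": (0, 0, 1)}, "chain_count": 2},
    "PA":  {"elements": {"C": (1, 0, 3),  "H": (2, -2, 5),                  "O": (0, 0, 8),  "P": (0, 0, 1)}, "chain_count": 2},
    "SM":  {"elements": {"C": (1, 0, 5),  "H": (2, -2, 13), "N": (0, 0, 2), "O": (0, 0, 6),  "P": (0, 0, 1)}, "chain_count": 2},
    "Cer": {"elements": {"C": (1, 0, 0),  "H": (2, -2, 1),  "N": (0, 0, 1), "O": (0, 0, 3)},                  "chain_count": 2},
    "TG":  {"elements": {"C": (1, 0, 3),  "H": (2, -2, 2),                  "O": (0, 0, 6)},                  "chain_count": 3},
    "DG":  {"elements": {"C": (1, 0, 3),  "H": (2, -2, 4),                  "O": (0, 0, 5)},                  "chain_count": 2},
    "CE":  {"elements": {"C": (1, 0, 27), "H": (2, -2, 44),                 "O": (0, 0, 2)},                  "chain_count": 1},
}


def _templates_from_mapping(raw: Mapping[str, Mapping]) -> dict[str, ClassTemplate]:
    out = {}
    for cls, entry in raw.items():
        elements = {
            el: tuple(float(x) for x in coeffs)
            for el, coeffs in entry["elements"].items()
        }
        out[cls] = ClassTemplate(cls, elements, int(entry["chain_count"]))
    return out


def default_class_templates() -> dict[str, ClassTemplate]:
    """Built-in templates, identical to the shipped ``class_templates.yaml``."""
    try:
        path = resources.files("lipidharmony.data") / "class_templates.yaml"
        return load_class_templates(str(path))
    except (FileNotFoundError, ModuleNotFoundError):
        return _templates_from_mapping(_DEFAULT_TEMPLATES)


def load_class_templates(path: str) -> dict[str, ClassTemplate]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _templates_from_mapping(raw)


def composition(
    species: LipidSpecies,
    templates: Mapping[str, ClassTemplate] | None = None,
) -> dict[str, int]:
    """Elemental composition {symbol: count} of a species.

    Ether (``O-``) species are the diacyl composition minus one O plus two H
    (an ether in place of an ester); plasmenyl ``P-C:D`` is treated as
    ``O-C:(D+1)`` — the vinyl-ether double bond is part of the composition but
    the species keeps its P- name.
    """
    if templates is None:
        templates = default_class_templates()
    tpl = templates.get(species.lipid_class)
    if tpl is None:
        raise TemplateError(
            f"no composition template for class {species.lipid_class!r}"
        )
    carbons, dbs = species.total_carbons, species.total_double_bonds
    if species.bond_type == BondType.PLASMENYL:
        dbs += 1  # vinyl-ether double bond
    comp = tpl.evaluate(carbons, dbs)
    if species.bond_type in (BondType.ETHER, BondType.PLASMENYL):
        comp["O"] = comp.get("O", 0) - 1
        comp["H"] = comp.get("H", 0) + 2
        if comp["O"] < 0:
            raise TemplateError(
                f"ether modifier drives O below zero for {species.name}"
            )
    if species.label_deuterium:
        comp["H"] = comp.get("H", 0) - species.label_deuterium
        comp["D"] = species.label_deuterium
        if comp["H"] < 0:
            raise TemplateError(f"more deuteriums than hydrogens in {species.name}")
    if comp.get("C", 0) < 1:
        raise TemplateError(f"composition of {species.name} has no carbon")
    return comp
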