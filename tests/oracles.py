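"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: compositions are
assembled from molecular building blocks (backbones, head groups, fatty
acids) instead of affine templates, and isotope patterns are computed by
exhaustive enumeration over isotope assignments instead of truncated
convolution.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from math import comb, prod


def _merge(*parts: dict, minus: list[dict] = ()) -> dict:
    total: Counter = Counter()
    for p in parts:
        total.update(p)
    for m in minus:
        total.subtract(m)
    assert all(v >= 0 for v in total.values())
    return {k: v for k, v in total.items() if v}


WATER = {"H": 2, "O": 1}
GLYCEROL = {"C": 3, "H": 8, "O": 3}
PHOSPHOCHOLINE = {"C": 5, "H": 14, "N": 1, "O": 4, "P": 1}
PHOSPHOETHANOLAMINE = {"C": 2, "H": 8, "N": 1, "O": 4, "P": 1}
PHOSPHOINOSITOL = {"C": 6, "H": 13, "O": 9, "P": 1}
PHOSPHOSERINE = {"C": 3, "H": 8, "N": 1, "O": 6, "P": 1}
PHOSPHOGLYCEROL = {"C": 3, "H": 9, "O": 6, "P": 1}
PHOSPHORIC_ACID = {"H": 3, "O": 4, "P": 1}
CHOLESTEROL = {"C": 27, "H": 46, "O": 1}


def fatty_acid(c: int, d: int, chains: int = 1) -> dict:
    """Summed formula of ``chains`` free fatty acids with total carbons c and
    total double bonds d: each acid is C_i H_{2C_i − 2d_i} O2."""
    return {"C": c, "H": 2 * c - 2 * d, "O": 2 * chains}


def sphingoid_base(c: int, d: int) -> dict:
    # dihydroxy ("d") long-chain base, e.g. sphingosine d18:1 = C18H37NO2
    return {"C": c, "H": 2 * c - 2 * d + 3, "N": 1, "O": 2}


def assemble(lipid_class: str, c: int, d: int) -> dict:
    """Structural-assembly composition for the diacyl / d-sphingoid form."""
    fa = fatty_acid
    if lipid_class == "PC":
        return _merge(GLYCEROL, fa(c, d, 2), PHOSPHOCHOLINE, minus=[WATER] * 3)
    if lipid_class == "LPC":
        return _merge(GLYCEROL, fa(c, d, 1), PHOSPHOCHOLINE, minus=[WATER] * 2)
    if lipid_class == "PE":
        return _merge(GLYCEROL, fa(c, d, 2), PHOSPHOETHANOLAMINE, minus=[WATER] * 3)
    if lipid_class == "LPE":
        return _merge(GLYCEROL, fa(c, d, 1), PHOSPHOETHANOLAMINE, minus=[WATER] * 2)
    if lipid_class == "PI":
        return _merge(GLYCEROL, fa(c, d, 2), PHOSPHOINOSITOL, minus=[WATER] * 3)
    if lipid_class == "PS":
        return _merge(GLYCEROL, fa(c, d, 2), PHOSPHOSERINE, minus=[WATER] * 3)
    if lipid_class == "PG":
        return _merge(GLYCEROL, fa(c, d, 2), PHOSPHOGLYCEROL, minus=[WATER] * 3)
    if lipid_class == "PA":
        return _merge(GLYCEROL, fa(c, d, 2), PHOSPHORIC_ACID, minus=[WATER] * 3)
    if lipid_class == "TG":
        return _merge(GLYCEROL, fa(c, d, 3), minus=[WATER] * 3)
    if lipid_class == "DG":
        return _merge(GLYCEROL, fa(c, d, 2), minus=[WATER] * 2)
    if lipid_class == "CE":
        return _merge(CHOLESTEROL, fa(c, d, 1), minus=[WATER])
    if lipid_class == "Cer":
        # amide condensation of base (d part of totals) with one fatty acid;
        # totals already sum base + acyl, so split arbitrarily: use d18:x base
        base_c, base_d = 18, min(d, 1)
        return _merge(sphingoid_base(base_c, base_d), fa(c - base_c, d - base_d),
                      minus=[WATER])
    if lipid_class == "SM":
        cer = assemble("Cer", c, d)
        return _merge(cer, PHOSPHOCHOLINE, minus=[WATER])
    raise KeyError(lipid_class)


# --- isotope-pattern oracles -------------------------------------------------


def per_atom_expansion(comp: dict, abundances, depth: int) -> list[float]:
    """Exhaustive expansion over every atom's isotope choice (small molecules)."""
    atoms = []
    for el, n in comp.items():
        atoms.extend([abundances.elements[el]] * n)
    probs: defaultdict[int, float] = defaultdict(float)
    for choice in itertools.product(*atoms):
        offset = sum(o for o, _ in choice)
        if offset <= depth:
            probs[offset] += prod(p for _, p in choice)
    a0 = probs[0]
    return [probs[j] / a0 for j in range(depth + 1)]


def _int_compositions(n: int, k: int):
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _int_compositions(n - first, k - 1):
            yield (first, *rest)


def multinomial_pattern(comp: dict, abundances, depth: int) -> list[float]:
    """Exact pattern via per-element multinomial enumeration (no truncation
    inside an element), convolved over elements as exact dictionaries."""
    total: dict[int, float] = {0: 1.0}
    for el, n in comp.items():
        pairs = abundances.elements[el]
        el_dist: defaultdict[int, float] = defaultdict(float)
        for counts in _int_compositions(n, len(pairs)):
            coef = 1
            remaining = n
            for cnt in counts:
                coef *= comb(remaining, cnt)
                remaining -= cnt
            p = coef * prod(ab**cnt for (_, ab), cnt in zip(pairs, counts))
            offset = sum(off * cnt for (off, _), cnt in zip(pairs, counts))
            el_dist[offset] += p
        new: defaultdict[int, float] = defaultdict(float)
        for o1, p1 in total.items():
            for o2, p2 in el_dist.items():
                if o1 + o2 <= depth:
                    new[o1 + o2] += p1 * p2
        total = dict(new)
    a0 = total[0]
    return [total.get(j, 0.0) / a0 for j in range(depth + 1)]
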