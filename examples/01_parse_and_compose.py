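"""Parse lipid shorthand names and derive elemental compositions.

Shows the species-level model: class code, total chain carbons : double
bonds, bond-type prefixes (O-/P-/d), and the per-class composition
templates used downstream for isotope prediction.
"""

from lipidharmony import composition, isotope_pattern, m2_ratio, parse_shorthand

for name in ["PC 34:1", "PC P-36:4", "SM d36:2", "Cer d18:1/17:0", "LPC 18:1-d7"]:
    sp = parse_shorthand(name)
    print(f"{name:16s} class={sp.lipid_class:3s} totals={sp.total_carbons}:{sp.total_double_bonds}"
          f" bond_type={sp.bond_type}"
          + (" (internal standard)" if sp.is_internal_standard else ""))

sp = parse_shorthand("PC 34:1")
comp = composition(sp)
pat = isotope_pattern(comp, depth=2)
print(f"\nPC 34:1 composition: "
      + " ".join(f"{el}{n}" for el, n in comp.items()))
print(f"isotopologue abundances relative to M+0: "
      f"M+1 = {pat.a1:.4f}, M+2 = {pat.a2:.4f}")
print(f"m2_ratio('PC 34:2') = {m2_ratio(parse_shorthand('PC 34:2')):.4f}")
print("\nThe M+2 value is the fraction of a species' monoisotopic signal that "
      "lands 2 Da higher,\non top of its analog with one double bond fewer — "
      "the interference the correction removes.")
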