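# Elemental composition templates per lipid class, for the diacyl /
# d-sphingoid form of the class.  Each element maps to affine coefficients
# [a, b, c]: count = a*C + b*D + c, with C = total chain carbons and
# D = total double bonds.  Ether (O-) species subtract one O and add two H;
# plasmenyl (P-) species are evaluated as O- with one extra double bond.
# Validated against structural assembly (glycerol/sphingoid backbone + head
# group + acyl chains) and LIPID MAPS formulas.
PC:
  chain_count: 2
  elements: {C: [1, 0, 8], H: [2, -2, 16], N: [0, 0, 1], O: [0, 0, 8], P: [0, 0, 1]}
LPC:
  chain_count: 1
  elements: {C: [1, 0, 8], H: [2, -2, 18], N: [0, 0, 1], O: [0, 0, 7], P: [0, 0, 1]}
PE:
  chain_count: 2
  elements: {C: [1, 0, 5], H: [2, -2, 10], N: [0, 0, 1], O: [0, 0, 8], P: [0, 0, 1]}
LPE:
  chain_count: 1
  elements: {C: [1, 0, 5], H: [2, -2, 12], N: [0, 0, 1], O: [0, 0, 7], P: [0, 0, 1]}
PI:
  chain_count: 2
  elements: {C: [1, 0, 9], H: [2, -2, 15], O: [0, 0, 13], P: [0, 0, 1]}
PS:
  chain_count: 2
  elements: {C: [1, 0, 6], H: [2, -2, 10], N: [0, 0, 1], O: [0, 0, 10], P: [0, 0, 1]}
PG:
  chain_count: 2
  elements: {C: [1, 0, 6], H: [2, -2, 11], O: [0, 0, 10], P: [0, 0, 1]}
PA:
  chain_count: 2
  elements: {C: [1, 0, 3], H: [2, -2, 5], O: [0, 0, 8], P: [0, 0, 1]}
SM:
  chain_count: 2
  elements: {C: [1, 0, 5], H: [2, -2, 13], N: [0, 0, 2], O: [0, 0, 6], P: [0, 0, 1]}
Cer:
  chain_count: 2
  elements: {C: [1, 0, 0], H: [2, -2, 1], N: [0, 0, 1], O: [0, 0, 3]}
TG:
  chain_count: 3
  elements: {C: [1, 0, 3], H: [2, -2, 2], O: [0, 0, 6]}
DG:
  chain_count: 2
  elements: {C: [1, 0, 3], H: [2, -2, 4], O: [0, 0, 5]}
CE:
  chain_count: 1
  elements: {C: [1, 0, 27], H: [2, -2, 44], O: [0, 0, 2]}
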