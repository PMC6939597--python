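# Natural isotopic abundances per element as [mass-number offset, abundance]
# pairs, offset = neutron excess over the lightest stable isotope.
# Representative values from the IUPAC/CIAAW isotopic-abundance tables.
# D (deuterium label positions) is treated as a fixed, pure isotope.
H:
  - [0, 0.999885]
  - [1, 0.000115]
C:
  - [0, 0.9893]
  - [1, 0.0107]
N:
  - [0, 0.99636]
  - [1, 0.00364]
O:
  - [0, 0.99757]
  - [1, 0.00038]
  - [2, 0.00205]
P:
  - [0, 1.0]
S:
  - [0, 0.9499]
  - [1, 0.0075]
  - [2, 0.0425]
  - [4, 0.0001]
D:
  - [0, 1.0]
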