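"""M+2 isotope-interference correction along a double-bond series.

Builds a PC 34:x series where each measured area includes the M+2
isotopologue of the next more-unsaturated analog, then inverts the
interference.  The saturated species PC 34:0 is pure interference here and
corrects to zero — the situation in which isotope correction removes
apparently 'detected' saturated lipids.
"""

import pandas as pd

from lipidharmony import deisotope, m2_ratio, parse_shorthand
from lipidharmony.tables import MeasurementTable

names = [f"PC 34:{d}" for d in range(4)]
index = {n: parse_shorthand(n) for n in names}
true = pd.Series({"PC 34:3": 8000.0, "PC 34:2": 12000.0, "PC 34:1": 9000.0,
                  "PC 34:0": 0.0})

measured = true.copy()
for n in names:
    donor = f"PC 34:{index[n].total_double_bonds + 1}"
    if donor in true:
        measured[n] = true[n] + true[donor] * m2_ratio(index[donor])

meta = pd.DataFrame({"sample": "LTR", "role": "qc_ltr", "method": "HILIC",
                     "batch": 0, "replicate": 1, "dilution_fraction": float("nan")},
                    index=["inj1"])
table = MeasurementTable(measured.to_frame("inj1"), meta)
corrected = deisotope(table, index)

print(f"{'species':10s} {'true':>10s} {'measured':>10s} {'corrected':>10s}")
for n in names:
    print(f"{n:10s} {true[n]:10.1f} {measured[n]:10.1f} "
          f"{corrected.intensities.loc[n, 'inj1']:10.1f}")
print("\nPC 34:0's measured area was entirely the M+2 cluster of PC 34:1; "
      "after correction it is 0.")
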