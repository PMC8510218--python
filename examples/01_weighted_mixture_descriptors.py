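"""Build molar-fraction-weighted mixture descriptors for a tiny dataset.

Each binary-mixture data point combines the descriptor vectors of its two
components: the sum form d_pmix = x1*D1 + x2*D2 and the absolute-
difference form d_nmix = |x1*D1 - x2*D2|, plus temperature and halide
indicator passthrough columns.
"""

import pandas as pd

from mixqspr.io import ComponentDescriptorTable, MixtureDataset
from mixqspr.features import compute_wm_features

components = ComponentDescriptorTable(
    pd.DataFrame(
        {"MATS4p": [1.2, 0.8, 0.5], "MAXDN": [0.4, 1.1, 0.9]},
        index=["choline_chloride", "urea", "glycerol"],
    )
)
records = pd.DataFrame(
    [
        # reline (1:2 choline chloride : urea) at two temperatures
        ["r1", "choline_chloride", "urea", 1 / 3, 2 / 3, 298.15, 1, 0, 1.197],
        ["r2", "choline_chloride", "urea", 1 / 3, 2 / 3, 308.15, 1, 0, 1.192],
        # glyceline (1:2 choline chloride : glycerol)
        ["r3", "choline_chloride", "glycerol", 1 / 3, 2 / 3, 298.15, 1, 0, 1.180],
    ],
    columns=["record_id", "comp1_id", "comp2_id", "x1", "x2", "T_K",
             "has_Cl", "has_Br", "y"],
)
dataset = MixtureDataset(records, components)
matrix = compute_wm_features(dataset, mode="both")

print(matrix.to_frame().round(4).to_string(index=False))
print()
print("Each *_pmix column is the mole-fraction-weighted sum of the two")
print("components' descriptor values; *_nmix is the weighted absolute")
print("difference. T_K/has_Cl/has_Br pass through from the mixture table;")
print("y is the observed density in g/cm3.")
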