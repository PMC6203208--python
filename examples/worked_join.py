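"""Combine two small experiment matrices into one cross-experiment table.

Builds the three-gene breast-cancer example: an expression matrix with two
samples and a methylation matrix with two samples, one tissue sample shared
between them.  The combined matrix full-outer-joins them on the truncated
barcode; samples measured by a single experiment show '?' across the whole
other block.
"""

import omicrules as om

rna = om.build_matrix(
    {
        "TCGA-A1-A0SD-01A-11R-A115-07": {"GDA": 0.6, "SCN3A": 28.4, "SCN3B": 43.6},
        "TCGA-A7-A4SD-01A-11R-A266-07": {"GDA": 0.0, "SCN3A": 6.4, "SCN3B": 1.9},
    },
    {
        "TCGA-A1-A0SD-01A-11R-A115-07": "normal",
        "TCGA-A7-A4SD-01A-11R-A266-07": "tumoral",
    },
    "rnaSeq",
)
meth = om.build_matrix(
    {
        "TCGA-A7-A4SD-01A-11D-A268-05": {"GDA": 1.6, "SCN3A": 2.3, "SCN3B": 2.0},
        "TCGA-GI-A2C9-01A-11D-A21R-05": {"GDA": 1.9, "SCN3A": 2.7, "SCN3B": 2.3},
    },
    {
        "TCGA-A7-A4SD-01A-11D-A268-05": "tumoral",
        "TCGA-GI-A2C9-01A-11D-A21R-05": "tumoral",
    },
    "dnaMeth",
)

combined = om.combine_matrices(meth, rna)
with_classes = combined.data.copy()
with_classes["Class"] = combined.classes
print(with_classes.to_string())
print()
print(
    f"{combined.n} rows (union of tissue samples), "
    f"{combined.m} = {meth.m} + {rna.m} feature columns."
)
print("NaN above renders as '?' on disk: that experiment was not performed")
print("on that tissue sample; TCGA-A7-A4SD-01A was measured by both.")
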