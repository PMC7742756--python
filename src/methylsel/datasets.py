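"""Small published reference tables used for consistency checks.

``REPORTED_F2_DMCS`` holds the seven candidate differentially methylated
CpGs reported for the great tit fast- vs slow-exploring F2 sibling
comparison (RRBS, 8 families, 233,198 tested sites): genomic position,
p-value, printed -log10(p), FE - SE methylation difference in percent,
and the annotated feature/gene.  These printed values serve as a fixed
input for exercising the DMC-calling rule and threshold arithmetic.
"""

from __future__ import annotations

import pandas as pd

#: Number of CpG sites entering each published comparison (post-filter).
N_TESTS_SEL_POOLS = 1_521_921
N_TESTS_F2C_POOLS = 4_963_579
N_TESTS_RRBS = 233_198

_ROWS = [
    # chrom, accession, pos, p, printed -log10(p), meth diff (%), feature, gene
    ("4", "NC_031771.1", 10_648_394, 1.37e-07, 6.86, -27.88, "gene_body", "LRBA"),
    ("5", "NC_031774.1", 54_093_387, 9.74e-09, 8.01, 32.13, "", ""),
    ("10", "NC_031779.1", 1_734_466, 2.43e-08, 7.62, -30.29, "gene_body", "SEMA7A"),
    ("10", "NC_031779.1", 1_734_483, 1.54e-07, 6.81, -27.71, "gene_body", "SEMA7A"),
    ("19", "NC_031787.1", 8_103_120, 5.14e-08, 7.29, 18.57, "TSS", "MRM1"),
    ("25LG2", "NC_031794.1", 166_118, 4.79e-08, 7.92, -29.71, "promoter", "LOC107214669"),
    ("28", "NC_031797.1", 3_222_562, 1.48e-09, 8.83, -36.00, "promoter", "SBNO2"),
]


def reported_f2_dmcs() -> pd.DataFrame:
    """The seven reported F2-sibling candidate DMCs as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "chrom", "accession", "pos", "p", "neglog10p", "meth_diff_pct",
            "feature", "gene",
        ],
    )


REPORTED_F2_DMCS = reported_f2_dmcs()
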