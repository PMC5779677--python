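"""Published summary statistics for *Sphaerium* karyotypes and rDNA groups.

These are the printed population-level numbers for *Sphaerium nucleus*
(Slovak ``S``, Lithuanian ``L`` and Czech ``C`` populations) and
*S. corneum* var. *mamillanum* (Estonian ``E`` population): per-pair
karyotype summaries (mean +/- SD of absolute length in μm, relative
length in %, and centromeric index, over N_KARYOTYPES = 10 measured
karyotypes per population), metaphase chromosome-count distributions, and
the group-level mean number-of-differences matrices for the ITS1 and 16S
rDNA datasets. They serve as reference values for validation and as
generative truths for the synthetic-data module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Karyotypes measured per population for the per-pair summaries.
N_KARYOTYPES = 10

_SUMMARY_COLUMNS = (
    "pair",
    "abs_mean",
    "abs_sd",
    "rel_mean",
    "rel_sd",
    "ci_mean",
    "ci_sd",
    "printed_class",
)

# S. nucleus per-pair summaries; one printed class per pair across the
# three populations. (The Czech pair-3 relative-length SD is printed with
# a dropped decimal point and is transcribed as 0.50.)
_NUCLEUS = {
    "S": [
        (1, 7.86, 1.34, 12.70, 0.97, 47.15, 2.48, "m"),
        (2, 6.95, 1.18, 11.19, 0.56, 45.23, 2.74, "m"),
        (3, 5.36, 0.81, 8.67, 0.58, 37.59, 1.39, "m-sm"),
        (4, 4.93, 0.70, 7.96, 0.43, 44.70, 2.70, "m"),
        (5, 4.76, 0.62, 7.71, 0.47, 42.45, 3.99, "m"),
        (6, 4.55, 0.67, 7.36, 0.50, 44.68, 3.62, "m"),
        (7, 4.38, 0.59, 7.08, 0.45, 38.98, 4.99, "m-sm"),
        (8, 4.20, 0.62, 6.79, 0.40, 44.24, 2.69, "m"),
        (9, 4.06, 0.48, 6.58, 0.31, 46.15, 2.06, "m"),
        (10, 3.88, 0.42, 6.31, 0.58, 46.98, 1.49, "m"),
        (11, 3.59, 0.40, 5.80, 0.26, 37.60, 3.12, "sm-m"),
        (12, 3.04, 0.48, 4.91, 0.28, 32.19, 3.50, "sm"),
        (13, 2.84, 0.42, 4.60, 0.26, 45.95, 4.38, "m"),
        (14, 1.43, 0.15, 2.33, 0.32, 50.00, 3.46, "m"),
    ],
    "L": [
        (1, 9.47, 2.03, 11.86, 0.65, 44.90, 2.88, "m"),
        (2, 8.43, 1.61, 10.61, 0.60, 42.35, 3.61, "m"),
        (3, 7.19, 1.41, 9.05, 0.51, 38.06, 1.53, "m-sm"),
        (4, 6.44, 1.22, 8.11, 0.37, 43.32, 3.85, "m"),
        (5, 6.32, 1.16, 7.97, 0.37, 41.63, 4.14, "m"),
        (6, 5.97, 1.13, 7.51, 0.20, 44.58, 2.25, "m"),
        (7, 5.79, 0.97, 7.32, 0.29, 37.51, 3.27, "m-sm"),
        (8, 5.66, 1.05, 7.13, 0.34, 44.21, 4.34, "m"),
        (9, 5.51, 1.16, 6.92, 0.35, 42.62, 3.69, "m"),
        (10, 4.98, 0.96, 6.28, 0.52, 42.28, 4.50, "m"),
        (11, 4.81, 0.86, 6.08, 0.35, 36.60, 4.00, "sm-m"),
        (12, 3.89, 0.71, 4.91, 0.34, 28.78, 3.03, "sm"),
        (13, 3.07, 0.42, 3.91, 0.26, 42.78, 2.47, "m"),
        (14, 1.81, 0.18, 2.35, 0.44, 42.91, 4.55, "m"),
    ],
    "C": [
        (1, 8.80, 1.76, 12.14, 0.77, 45.27, 2.78, "m"),
        (2, 8.00, 1.04, 11.15, 0.50, 44.97, 3.24, "m"),
        (3, 6.60, 1.16, 9.15, 0.50, 37.33, 3.07, "m-sm"),
        (4, 5.91, 0.94, 8.20, 0.29, 40.86, 3.18, "m"),
        (5, 5.68, 0.76, 7.91, 0.31, 40.15, 3.57, "m"),
        (6, 5.40, 0.76, 7.51, 0.26, 44.38, 2.97, "m"),
        (7, 5.23, 0.75, 7.27, 0.31, 39.24, 3.19, "m-sm"),
        (8, 5.14, 0.79, 7.13, 0.32, 43.05, 3.30, "m"),
        (9, 4.96, 0.69, 6.89, 0.21, 44.73, 3.32, "m"),
        (10, 4.69, 0.65, 6.53, 0.25, 43.60, 2.47, "m"),
        (11, 4.31, 0.62, 5.98, 0.31, 37.01, 4.36, "sm-m"),
        (12, 3.30, 0.49, 4.60, 0.45, 28.80, 2.34, "sm"),
        (13, 2.81, 0.40, 3.92, 0.37, 42.77, 3.08, "m"),
        (14, 1.16, 0.10, 1.62, 0.24, 43.07, 1.63, "m"),
    ],
}

# S. corneum var. mamillanum (Estonian population), 15 pairs.
_MAMILLANUM = [
    (1, 9.02, 0.83, 11.97, 0.40, 48.06, 1.20, "m"),
    (2, 8.07, 0.95, 10.68, 0.09, 43.45, 4.94, "m"),
    (3, 7.23, 1.32, 9.54, 0.55, 41.61, 1.89, "m"),
    (4, 6.45, 0.31, 8.58, 0.67, 38.84, 4.72, "m-sm"),
    (5, 6.25, 1.67, 8.19, 1.18, 44.06, 2.76, "m"),
    (6, 5.47, 0.56, 7.25, 0.17, 43.12, 3.52, "m"),
    (7, 4.56, 0.55, 6.04, 0.03, 40.25, 5.26, "m-sm"),
    (8, 4.28, 0.68, 5.65, 0.19, 40.77, 1.35, "m"),
    (9, 4.29, 0.62, 5.67, 0.11, 40.88, 4.06, "m"),
    (10, 3.80, 0.84, 5.00, 0.48, 44.40, 4.42, "m"),
    (11, 3.56, 0.28, 4.73, 0.22, 44.04, 1.77, "m"),
    (12, 3.46, 0.37, 4.59, 0.09, 42.20, 1.29, "m"),
    (13, 3.29, 0.48, 4.35, 0.09, 41.55, 4.16, "m"),
    (14, 3.08, 0.04, 4.10, 0.46, 40.23, 2.25, "m"),
    (15, 2.74, 0.02, 3.66, 0.49, 40.65, 2.55, "m"),
]


def nucleus_karyotype_summaries() -> dict[str, pd.DataFrame]:
    """Per-pair karyotype summaries for the three *S. nucleus* populations."""
    return {
        pop: pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
        for pop, rows in _NUCLEUS.items()
    }


def mamillanum_karyotype_summary() -> pd.DataFrame:
    """Per-pair karyotype summary for *S. corneum* var. *mamillanum*."""
    return pd.DataFrame(_MAMILLANUM, columns=_SUMMARY_COLUMNS)


# Metaphase chromosome-count distributions per population. The published
# table bins 34 and 35 together; for the Estonian population the split
# 34:18 / 35:2 is known (18 cells carried the modal 4 Bs), for the
# *S. nucleus* populations the binned cells are assigned to 34.
# Tetraploid ("4n") cells are represented at exactly twice the modal
# number.
def metaphase_counts() -> dict[str, dict[int, int]]:
    return {
        "L": {27: 8, 28: 150, 34: 4, 36: 20, 56: 3},
        "S": {27: 2, 28: 48, 32: 15, 34: 1, 36: 11},
        "C": {27: 4, 28: 31, 32: 6, 56: 1},
        "E": {30: 60, 32: 2, 34: 18, 35: 2, 36: 4},
    }


def nucleus_modal_number() -> int:
    return 28


def mamillanum_modal_number() -> int:
    return 30


# Group-level mean number-of-differences matrices for the rDNA datasets.
# Within-group means are None for singleton groups.

def its1_group_table() -> pd.DataFrame:
    """ITS1 groups: representative ungapped length and difference matrix."""
    labels = [
        "nucleus_Ukraine",
        "nucleus_LithSlovRus",
        "nucleus_Czech",
        "corneum",
        "solidum",
    ]
    lengths = [550, 554, 556, 542, 542]
    m = np.array(
        [
            [0, 4, 4, 3, 4],
            [4, 0, 2, 3, 4],
            [4, 2, 0, 3, 4],
            [3, 3, 3, 0, 1],
            [4, 4, 4, 1, 0],
        ],
        dtype=float,
    )
    df = pd.DataFrame(m, index=labels, columns=labels)
    df.insert(0, "bp", lengths)
    return df


def s16_group_table() -> pd.DataFrame:
    """16S groups: representative ungapped length, difference matrix, within means."""
    labels = [
        "nucleus_Ukraine",
        "nucleus_LithRus",
        "nucleus_Slovakia",
        "nucleus_Czech",
        "corneum_2n36",
        "corneum",
        "solidum",
    ]
    lengths = [475, 475, 475, 474, 474, 474, 474]
    m = np.array(
        [
            [0, 6, 10, 13, 9, 14.14, 13.29],
            [6, 0, 4, 8, 9, 10.14, 9.29],
            [10, 4, 0, 12, 13, 14.14, 13.29],
            [13, 8, 12, 0, 14, 8.14, 7.29],
            [9, 9, 13, 14, 0, 9.43, 12.29],
            [14.14, 10.14, 14.14, 8.14, 9.43, 0, 5.14],
            [13.29, 9.29, 13.29, 7.29, 12.29, 5.14, 0],
        ]
    )
    within = [None, 0.0, 0.0, 0.0, 0.0, 0.86, 1.43]
    df = pd.DataFrame(m, index=labels, columns=labels)
    df.insert(0, "bp", lengths)
    df["within"] = within
    return df


def s16_nucleus_block() -> pd.DataFrame:
    """The integer-valued 16S block for the four *S. nucleus* haplotype groups."""
    df = s16_group_table()
    keep = [
        "nucleus_Ukraine",
        "nucleus_LithRus",
        "nucleus_Slovakia",
        "nucleus_Czech",
    ]
    return df.loc[keep, keep]
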