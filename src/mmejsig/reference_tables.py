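"""Reference contingency counts from a published whole-genome indel survey.

Two healthy-donor lymphoblastoid cell lines (LCL) were compared with their
parental primary B cells by whole-genome sequencing; deletions were scored
for junction microhomology (mh) and stratified by a minimum-mh threshold T.
The rows below record, for each subject and each T, how many pre-existing
(B-cell ∩ LCL) and newly arisen (LCL-unique) deletions were considered and
how many carried mh >= T, together with the p-value as printed in the
source report. The p-values are a pure function of the counts, so they
serve as an external validation set for :func:`mmejsig.stats.proportion_chisq`
(continuity correction on). Printed decimal p-values are truncated at the
shown precision; scientific-notation ones are rounded to three significant
digits.

Columns: (subject, T, pre_with_mh, pre_total, new_with_mh, new_total, printed_p)
``printed_p`` is None where the report shows "NS" (p >= 0.05).
"""

from __future__ import annotations

from typing import List, Optional, Tuple

Row = Tuple[int, int, int, int, int, int, Optional[str]]

# Short deletions, 2-29 bp.
SHORT_DELETION_ROWS: List[Row] = [
    (1, 2, 13190, 17090, 11710, 13950, "5.58E-50"),
    (1, 3, 9199, 12415, 7295, 9294, "7.15E-14"),
    (1, 4, 7485, 10613, 5381, 7342, "5.74E-05"),
    (1, 5, 5342, 7842, 3959, 5673, "0.04"),
    (1, 6, 4697, 6965, 3385, 5011, None),
    (1, 7, 3776, 5698, 2773, 4211, None),
    (1, 8, 3366, 5189, 2438, 3813, None),
    (1, 9, 2513, 4043, 1880, 3085, None),
    (1, 10, 2221, 3680, 1654, 2770, None),
    (1, 11, 1790, 3071, 1376, 2375, None),
    (1, 12, 1596, 2857, 1230, 2167, None),
    (1, 13, 1149, 2188, 949, 1776, None),
    (1, 14, 1020, 2024, 843, 1639, None),
    (1, 15, 837, 1682, 716, 1429, None),
    (1, 16, 708, 1515, 624, 1283, None),
    (1, 17, 497, 1176, 474, 1039, None),
    (1, 18, 443, 1096, 417, 971, None),
    (1, 19, 346, 932, 311, 793, None),
    (1, 20, 299, 847, 258, 706, None),
    (2, 2, 13570, 17868, 10146, 12059, "1.01E-65"),
    (2, 3, 9666, 13293, 6104, 7760, "9.56E-22"),
    (2, 4, 7889, 11493, 4505, 6071, "1.63E-14"),
    (2, 5, 5723, 8680, 3311, 4686, "2.88E-08"),
    (2, 6, 5070, 7847, 2838, 4137, "1.28E-05"),
    (2, 7, 4172, 6529, 2320, 3497, "0.015"),
    (2, 8, 3713, 5962, 2046, 3169, "0.033"),
    (2, 9, 2781, 4718, 1623, 2608, "0.006"),
    (2, 10, 2500, 4342, 1441, 2380, "0.019"),
    (2, 11, 2017, 3639, 1206, 2056, "0.019"),
    (2, 12, 1803, 3372, 1104, 1908, "0.002"),
    (2, 13, 1291, 2606, 852, 1538, "0.0003"),
    (2, 14, 1136, 2408, 773, 1419, "1.50E-05"),
    (2, 15, 928, 2044, 656, 1240, "3.55E-05"),
    (2, 16, 779, 1824, 572, 1123, "1.60E-05"),
    (2, 17, 576, 1461, 448, 938, "6.72E-05"),
    (2, 18, 481, 1333, 396, 862, "5.14E-06"),
    (2, 19, 369, 1099, 318, 732, "2.42E-05"),
    (2, 20, 309, 1005, 263, 671, "0.0004"),
]

# Long deletions, 30-500 bp. All exceed the 20 bp threshold ceiling, so the
# considered totals are constant across T (869/966 for subject 1, 1283/911
# for subject 2).
LONG_DELETION_ROWS: List[Row] = [
    (1, 2, 664, 869, 761, 966, None),
    (1, 3, 622, 869, 714, 966, None),
    (1, 4, 559, 869, 662, 966, None),
    (1, 5, 542, 869, 640, 966, None),
    (1, 6, 531, 869, 620, 966, None),
    (1, 7, 516, 869, 601, 966, None),
    (1, 8, 500, 869, 581, 966, None),
    (1, 9, 483, 869, 558, 966, None),
    (1, 10, 465, 869, 533, 966, None),
    (1, 11, 452, 869, 515, 966, None),
    (1, 12, 437, 869, 495, 966, None),
    (1, 13, 418, 869, 476, 966, None),
    (1, 14, 403, 869, 462, 966, None),
    (1, 15, 385, 869, 443, 966, None),
    (1, 16, 361, 869, 425, 966, None),
    (1, 17, 332, 869, 411, 966, None),
    (1, 18, 311, 869, 392, 966, "0.039"),
    (1, 19, 295, 869, 379, 966, "0.02"),
    (1, 20, 276, 869, 364, 966, "0.009"),
    (2, 2, 958, 1283, 702, 911, None),
    (2, 3, 895, 1283, 668, 911, None),
    (2, 4, 822, 1283, 611, 911, None),
    (2, 5, 796, 1283, 591, 911, None),
    (2, 6, 759, 1283, 576, 911, None),
    (2, 7, 721, 1283, 556, 911, "0.026"),
    (2, 8, 702, 1283, 537, 911, None),
    (2, 9, 677, 1283, 518, 911, None),
    (2, 10, 651, 1283, 503, 911, "0.042"),
    (2, 11, 632, 1283, 484, 911, None),
    (2, 12, 600, 1283, 463, 911, None),
    (2, 13, 576, 1283, 454, 911, "0.024"),
    (2, 14, 553, 1283, 444, 911, "0.01"),
    (2, 15, 526, 1283, 432, 911, "0.003"),
    (2, 16, 502, 1283, 410, 911, "0.006"),
    (2, 17, 474, 1283, 391, 911, "0.005"),
    (2, 18, 443, 1283, 376, 911, "0.001"),
    (2, 19, 417, 1283, 361, 911, "0.0006"),
    (2, 20, 395, 1283, 341, 911, "0.001"),
]


def numeric_rows(rows: List[Row]) -> List[Row]:
    """Rows whose reported p-value is numeric (below the NS cutoff)."""
    return [r for r in rows if r[6] is not None]


def printed_tolerance(printed: str) -> float:
    """One unit in the last printed digit — covers both truncation (used for
    the decimal cells) and rounding (used for the scientific cells)."""
    s = printed.upper()
    if "E" in s:
        mant, exp = s.split("E")
        ndec = len(mant.split(".")[1]) if "." in mant else 0
        return 10.0 ** (int(exp) - ndec)
    ndec = len(s.split(".")[1]) if "." in s else 0
    return 10.0 ** (-ndec)
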