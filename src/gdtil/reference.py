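"""Published per-subject benchmark results for the reference evaluation.

These are the per-subject decoding summaries reported for this method on
its two benchmark evaluations: a six-subject activities-of-daily-living
motor-imagery study (incremental arm-movement pairs, subjects A1-A6) and
the public nine-subject four-class motor-imagery benchmark (subjects
B1-B9).  They serve as worked-example inputs for the aggregation layer in
:mod:`gdtil.metrics` — the summary statistics (means, sample standard
deviations, average transfer/forgetting rates) are recomputed from these
columns, not stored.

All accuracies are percentages; transfer/forgetting rates are percentages
as defined in :mod:`gdtil.metrics`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ADL_SUBJECTS", "ADL_SINGLE_PAIR_ACC", "ADL_TWO_PAIR_ACC",
    "ADL_FTR_SR", "ADL_FTR_SL", "ADL_BFR_FR", "ADL_BFR_FL",
    "IV2A_SUBJECTS", "IV2A_BINARY_ACC", "IV2A_THREE_TASK_ACC", "IV2A_FOUR_TASK_ACC",
]

ADL_SUBJECTS = ("A1", "A2", "A3", "A4", "A5", "A6")

# initial task: one motor-imagery pair (binary decoding)
ADL_SINGLE_PAIR_ACC = np.array([93.26, 89.18, 93.62, 85.97, 75.60, 84.64])
# after incrementally adding the second pair (four classes)
ADL_TWO_PAIR_ACC = np.array([85.96, 82.71, 89.05, 82.34, 69.47, 71.64])

# forward transfer rates (%) for the added sideways-raising / -lowering tasks
ADL_FTR_SR = np.array([3.13, 4.15, 0.69, 1.29, 3.03, 4.44])
ADL_FTR_SL = np.array([2.24, 3.01, 0.75, 1.31, 4.58, 4.01])

# backward forgetting rates (%) for the old forward-raising / -lowering tasks
ADL_BFR_FR = np.array([9.09, 6.97, 4.18, 4.33, 7.27, 14.09])
ADL_BFR_FL = np.array([6.64, 5.72, 5.71, 5.04, 6.41, 15.77])

IV2A_SUBJECTS = ("B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B9")

IV2A_BINARY_ACC = np.array([97.12, 75.01, 94.64, 89.77, 88.17, 83.47, 95.50, 94.15, 93.15])
IV2A_THREE_TASK_ACC = np.array([94.05, 70.02, 90.70, 84.90, 83.74, 76.55, 91.53, 90.61, 88.31])
IV2A_FOUR_TASK_ACC = np.array([89.66, 62.86, 86.70, 81.68, 79.34, 72.59, 87.55, 86.28, 85.20])
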