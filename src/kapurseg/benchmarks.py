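"""Published benchmark numbers used by the worked examples.

Mean evaluation metrics (percent) of ten breast-MRI lesion segmentation
methods over a 100-slice T2-weighted DCE-MRI benchmark, as reported in
the study this package implements, plus the printed one-way ANOVA sums
of squares on the DSC.  These are transcription constants: they are the
*inputs* of the worked statistics/TOPSIS examples, never the outputs of
this package's own computations.
"""

from __future__ import annotations

import pandas as pd

from .stats_mcda import DecisionMatrix

METHODS = ("GTORBL", "GTO", "MVO", "PSO", "SMA",
           "AOA", "TSA", "HMRF", "CMRF", "IMRF")

# criterion -> per-method mean value (%), methods in METHODS order
BENCHMARK_MEANS = {
    "accuracy":    (99.31, 98.13, 97.91, 96.86, 96.25, 97.89, 97.63, 97.59, 95.72, 96.83),
    "sensitivity": (95.45, 90.96, 90.32, 90.94, 87.88, 89.91, 88.98, 85.59, 86.76, 87.26),
    "specificity": (99.37, 98.28, 97.98, 96.92, 96.31, 97.99, 97.68, 97.65, 95.78, 96.91),
    "precision":   (86.33, 83.91, 79.79, 78.96, 82.74, 82.11, 80.92, 79.49, 75.01, 78.83),
    "gm":          (97.41, 93.82, 92.58, 92.71, 91.92, 91.95, 91.49, 92.63, 91.72, 92.21),
    "f1":          (91.54, 87.04, 83.86, 83.54, 85.87, 83.69, 83.05, 82.04, 81.51, 82.97),
    "fpr":         (0.63, 1.62, 2.32, 3.08, 3.69, 2.01, 2.32, 2.35, 4.22, 3.10),
    "dsc":         (91.54, 87.04, 83.86, 83.54, 85.87, 83.69, 83.05, 82.04, 81.51, 82.97),
}

# printed one-way ANOVA decomposition of the per-slice DSC values
# (10 methods x 100 slices): sums of squares and degrees of freedom
ANOVA_SS_BETWEEN = 7937.32
ANOVA_DF_BETWEEN = 9
ANOVA_SS_WITHIN = 162786.5
ANOVA_DF_WITHIN = 990


def benchmark_decision_matrix(weights: dict[str, float] | None = None) -> DecisionMatrix:
    """The 10-method x 8-criterion decision matrix, FPR as the sole cost."""
    values = pd.DataFrame(BENCHMARK_MEANS, index=list(METHODS))
    is_benefit = {c: c != "fpr" for c in values.columns}
    return DecisionMatrix(values=values, is_benefit=is_benefit, weights=weights)
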