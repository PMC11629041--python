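"""Published benchmark metrics for KOA functional-test regression.

Cross-validated training-set metric triples (MAE in seconds, MAPE in
percent, RMSE in seconds) reported for the training-mean baseline and each
candidate regressor on the 40 m fast-paced walk test (``fpwt40``) and timed
up-and-go test (``tugt``) prediction tasks in a 92-patient knee
osteoarthritis cohort, together with the relative-index (RI) values printed
alongside them.  Used to validate the RI arithmetic of
:func:`plantargait.models.compute_ri`: applying it to each (baseline,
model) pair must reproduce the printed RI to three decimals.
"""

from __future__ import annotations

from typing import Dict, Tuple

#: task -> model -> (MAE s, MAPE %, RMSE s)
BENCHMARK_CV_METRICS: Dict[str, Dict[str, Tuple[float, float, float]]] = {
    "fpwt40": {
        "Baseline": (4.925, 16.461, 6.219),
        "LR": (3.793, 12.426, 4.966),
        "SVM": (3.318, 10.653, 4.526),
        "RF": (2.59, 8.407, 3.546),
        "AdaBoost": (2.541, 8.137, 3.546),
        "XGBoost": (2.495, 7.758, 3.527),
        "LGBM": (2.373, 7.473, 3.381),
        "Stack (linear)": (2.518, 7.921, 3.432),
        "Stack (SVM)": (2.223, 6.929, 3.152),
        "SAE": (2.345, 7.42, 3.334),
        "WAE": (2.34, 7.399, 3.329),
    },
    "tugt": {
        "Baseline": (2.475, 20.969, 3.267),
        "LR": (1.739, 14.174, 2.285),
        "SVM": (1.717, 13.859, 2.318),
        "RF": (1.538, 12.396, 2.16),
        "AdaBoost": (1.399, 11.218, 2.043),
        "XGBoost": (1.306, 10.365, 1.891),
        "LGBM": (1.397, 11.012, 1.944),
        "Stack (linear)": (1.473, 11.775, 2.033),
        "Stack (SVM)": (1.3, 10.2, 1.873),
        "SAE": (1.347, 10.701, 1.945),
        "WAE": (1.339, 10.633, 1.936),
    },
}

#: task -> model -> printed RI (baseline RI is 0 by definition)
BENCHMARK_RI: Dict[str, Dict[str, float]] = {
    "fpwt40": {
        "LR": 0.676, "SVM": 0.951, "RF": 1.393, "AdaBoost": 1.42,
        "XGBoost": 1.455, "LGBM": 1.521, "Stack (linear)": 1.456,
        "Stack (SVM)": 1.621, "SAE": 1.537, "WAE": 1.54,
    },
    "tugt": {
        "LR": 0.922, "SVM": 0.936, "RF": 1.126, "AdaBoost": 1.274,
        "XGBoost": 1.399, "LGBM": 1.315, "Stack (linear)": 1.221,
        "Stack (SVM)": 1.415, "SAE": 1.35, "WAE": 1.359,
    },
}
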