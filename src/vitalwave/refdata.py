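"""Reference measurement records bundled for validation arithmetic.

Small printed datasets from the validation experiments of a 77 GHz FMCW
vital-sign radar platform, shipped with the package so the error
arithmetic (percent rate errors, mutation-count averages, fold-accuracy
means, worked apnea-detection accuracies) can be recomputed without any
external files.
"""
from __future__ import annotations

#: frame-mutation counts for 20 subjects at three radar-to-chest distances (cm)
MUTATION_COUNTS = {
    10: [9, 8, 10, 9, 9, 8, 11, 9, 8, 9, 10, 11, 9, 8, 8, 9, 10, 9, 9, 8],
    30: [7, 5, 8, 6, 6, 6, 8, 5, 6, 6, 8, 7, 6, 5, 5, 5, 8, 6, 5, 6],
    50: [13, 10, 13, 12, 12, 11, 13, 13, 12, 12, 14, 12, 13, 10, 11, 12, 13, 12, 14, 12],
}

#: (radar, respiratory belt) breaths-per-minute pairs, ten repeat measurements
RESP_RATE_PAIRS = [
    (19, 20), (18, 19), (16, 17), (17, 18), (22, 21),
    (16, 15), (20, 19), (18, 19), (20, 19), (19, 20),
]

#: (radar, pulse oximeter) beats-per-minute pairs, ten repeat measurements
HEART_RATE_PAIRS = [
    (70, 69), (67, 69), (67, 69), (67, 68), (67, 67),
    (68, 70), (68, 69), (70, 69), (70, 71), (70, 70),
]

#: per-fold accuracies (%) of the 10-fold cross-validation runs
CV_FOLD_ACCURACY = {
    "svm": [100.00, 97.50, 95.00, 98.75, 98.75, 98.75, 97.50, 98.75, 95.00, 98.75],
    "knn": [90.00, 88.75, 88.75, 88.75, 90.00, 91.25, 90.00, 88.75, 90.00, 87.50],
}

#: worked apnea-judgment example, respiration channel: detected vs actual
#: (start, stop) point indices of the apnea run
RESP_APNEA_DETECTED = (90, 143)
RESP_APNEA_ACTUAL = (84, 145)

#: worked apnea-judgment example, heart-rate channel
HEART_APNEA_DETECTED = (92, 138)
HEART_APNEA_ACTUAL = (83, 139)

#: hold-out evaluation error structure on 400 balanced test samples
#: (80 per class); keys are (true, predicted) label pairs, values counts
SVM_HOLDOUT_ERRORS = {(5, 1): 7}
KNN_HOLDOUT_ERRORS = {(1, 5): 21, (2, 5): 19, (2, 4): 4, (4, 2): 1}
HOLDOUT_PER_CLASS = 80
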