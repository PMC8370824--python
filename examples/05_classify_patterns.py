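"""Classify the five breathing patterns with SVM and KNN.

A balanced synthetic corpus (40 traces per pattern) is featurized, split
50/50 into train/test, and both classifiers are evaluated.  The printed
accuracy is the fraction of correctly labelled test traces and kappa is
the chance-corrected agreement; with balanced classes the chance level is
20%, so kappa = (accuracy - 0.2) / 0.8.
"""
import numpy as np

import vitalwave as vw

data = vw.build_feature_dataset(n_per_pattern=40, seed=0)
rng = np.random.default_rng(0)
idx = rng.permutation(len(data))
half = len(data) // 2
train, test = data.subset(idx[:half]), data.subset(idx[half:])

for model in ("svm", "knn"):
    pred = vw.train_predict(train, test, model=model, seed=0)
    report = vw.confusion_and_kappa(test.labels, pred)
    print(f"{model}: accuracy {100 * report.accuracy:.2f}%  kappa {report.kappa:.6f}")
    print("confusion (rows = true, cols = predicted):")
    print(report.confusion)
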