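"""Fit an uncorrelated shrunken centroid classifier on synthetic
multiclass miRNA profiles and classify held-out samples.

Builds a 4-class data set in which each class over-expresses four of
its own miRNAs by three noise standard deviations, fits the classifier
at a moderate shrinkage (delta=1.0) with correlation pruning at
rho=0.9, and reports how many miRNAs survive shrinkage and the
held-out accuracy. With well-separated classes the classifier should
keep roughly the informative miRNAs and classify nearly perfectly.
"""

import numpy as np

from sfssclass import fit, make_classification_data, predict_matrix

train, _, truth = make_classification_data(
    K=4, p=60, n_k=15, p_info=4, effect=3.0, seed=1
)
test, test_labels, _ = make_classification_data(
    K=4, p=60, n_k=25, p_info=4, effect=3.0, seed=2
)

model = fit(train, delta=1.0, rho=0.9)
pred, scores, ties = predict_matrix(test, model)
truth_labels = [test_labels[s] for s in test.sample_ids]
acc = np.mean([p == t for p, t in zip(pred, truth_labels)])

informative = truth.all_informative()
kept = set(model.selected_features)
print(f"features kept after shrinkage + decorrelation: {len(kept)} of {train.n_features}")
print(f"  informative miRNAs among them: {len(kept & informative)} of {len(informative)}")
print(f"held-out accuracy on {test.n_samples} samples: {acc:.3f}")
print("-> shrinkage discards uninformative miRNAs; accuracy near 1.0 means the")
print("   class centroids separate cleanly at three noise standard deviations.")
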