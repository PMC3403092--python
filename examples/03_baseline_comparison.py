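"""Compare LPFS against the filter and wrapper baselines on one dataset.

Runs the two-sample statistic, fold change, SVM-RFE, and the LP selector on
the same planted synthetic data and prints how their selections overlap.
"""

import numpy as np

from lpfs import (
    SelectionResult,
    fold_change,
    generate,
    lambda_path,
    overlap_venn,
    planted_spec,
    svm_rfe,
    t_statistic,
)

ds, truth = generate(planted_spec(seed=2, n_features=100, m1=10, m2=10,
                                  n_planted=4, shift=4.0))
k = len(truth.planted)

t = np.abs(t_statistic(ds))
fc = fold_change(ds)
fc_eff = np.maximum(fc, 1.0 / fc)  # symmetric up/down effect
rfe = svm_rfe(ds, stop_at=k, accuracy_curve=False)
path = lambda_path(ds)

results = [
    SelectionResult("t", "t-stat", {ds.feature_ids[i] for i in np.argsort(-t)[:k]}),
    SelectionResult("fc", "fold-change", {ds.feature_ids[i] for i in np.argsort(-fc_eff)[:k]}),
    SelectionResult("svm-rfe", "SVM-RFE", {ds.feature_ids[i] for i in rfe.surviving}),
    SelectionResult("lpfs", "LPFS", {ds.feature_ids[i] for i in path.chosen_solution.selected}),
]
planted_ids = {ds.feature_ids[i] for i in truth.planted}
print(f"planted markers: {sorted(planted_ids)}")
for r in results:
    hits = len(r.selected & planted_ids)
    print(f"{r.label:>12}: {sorted(r.selected)}  ({hits}/{len(r.selected)} planted)")

venn = overlap_venn(results)
full = venn.regions[(True, True, True, True)]
print(f"\nmarkers found by all four methods: {full}")
print("pairwise Jaccard:")
print(venn.jaccard.round(2))
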