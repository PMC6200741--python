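"""Compare learners with the Friedman / Iman-Davenport / Finner cascade.

Builds per-fold AUC blocks from a nested-CV run, checks the parametric
gates (Shapiro-Wilk normality, Bartlett homoscedasticity), runs the
rank-based omnibus test, and applies Finner's step-down post-hoc
procedure against the best-ranked learner.
"""

import pepqsar as pq
from pepqsar.model_eval import NestedCVConfig, make_fast_learners, run_nested_cv
from pepqsar.stats_compare import PerformanceBlockMatrix

dataset = pq.generate_dataset(pq.paper_like_config(seed=0))
matrix = pq.remove_zero_features(pq.featurize_dataset(dataset))

table = run_nested_cv(
    matrix, dataset.label_vector(), make_fast_learners(200),
    NestedCVConfig(outer_folds=5, outer_repeats=2, seed=7),
    fs_k=200, fs_mode="fold", dataset_label="AAC_DC_TC_200",
)

blocks = pq.performance_blocks([table], metric="auc", blocks="fold")
report = pq.run_cascade(PerformanceBlockMatrix.from_frame(blocks))
print(report.summary())
# A significant omnibus p with Finner rejections marks learners whose
# mean rank is worse than the control's beyond chance, with the
# family-wise error controlled across all pairwise-to-control tests.
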