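"""Interpret the fitted elastic-net models: which features drive ANTI calls?

Aggregates glmnet coefficients across every (repeat, fold) model,
reports the top features by summed coefficient magnitude, and breaks the
selected features down by descriptor family.
"""

import pepqsar as pq
from pepqsar.model_eval import NestedCVConfig, make_fast_learners, run_nested_cv

dataset = pq.generate_dataset(pq.paper_like_config(seed=0))
matrix = pq.remove_zero_features(pq.featurize_dataset(dataset))

table = run_nested_cv(
    matrix, dataset.label_vector(),
    make_fast_learners(200, families=("GLMNET",)),
    NestedCVConfig(outer_folds=5, outer_repeats=2, seed=7),
    fs_k=200, fs_mode="fold", dataset_label="AAC_DC_TC_200",
)

imp = pq.aggregate_betas(table.coefficients)
top10 = pq.top_k_report(imp, 10)
print(top10.to_string(index=False))
# anti_associated=True means a positive summed coefficient: higher
# feature values push the model toward the ANTI class. The planted
# motifs (e.g. DC:SP) should appear with anti_associated=True.

ranking = pq.rank_features_ttest(matrix, dataset.label_vector())
selected = pq.select_top_k(ranking, matrix, 200)
comp = pq.descriptor_composition(matrix, selected)
print()
print(comp.to_string(index=False))
# Share columns each sum to 100%: they show how the descriptor-family
# mix of the feature space shifts once the t-test filter keeps only the
# 200 most discriminative features.
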