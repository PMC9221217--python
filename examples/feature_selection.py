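"""MRMR ranking plus the sequential-feature-collection window search.

Builds a feature table with three informative columns hidden among noise,
ranks all features by the greedy minimal-redundancy maximal-relevance
criterion, then searches every contiguous window of the ranking with an
inner-LOOCV SVM evaluator to find the optimal feature subset.
"""

from atlasfusion import (
    ClassifierConfig,
    CohortSpec,
    SelectionConfig,
    mrmr_rank,
    mutual_information,
    simulate_feature_table,
)
from atlasfusion.classify import select_features

spec = CohortSpec(n_positive=20, n_negative=20, effect_size=2.0, seed=3)
table = simulate_feature_table(spec, n_features=16, n_informative=3)
print(f"table: {table.n_subjects} subjects x {table.n_features} features; "
      "informative columns are 0, 1, 2\n")

ranked = mrmr_rank(table, k=10)
print("MRMR top 10 (feature index: relevance in bits):")
for idx in ranked:
    rel = mutual_information(table.values[:, idx], table.labels)
    print(f"  {idx:2d}: {rel:.3f}")

config = ClassifierConfig(sfc_hyperparams=(1.0, 0.125))  # fixed-C/gamma evaluator
result = select_features(table, config, SelectionConfig(mrmr_k=10))
print(f"\nSFC window over the ranking: {result.window} "
      f"({result.n_evaluations} windows evaluated)")
print(f"selected feature indices: {result.selected_ids}")
print(f"inner-LOOCV accuracy of the window: {result.window_score:.3f}")
print(
    "\nThe planted columns dominate the top of the ranking and the chosen"
    "\nwindow; the window search considers every contiguous run of the"
    "\nranked list, L(L-1)/2 evaluations for a ranking of length L."
)
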