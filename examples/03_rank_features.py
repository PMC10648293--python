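"""Rank one nerve's features by minimum-redundancy maximum-relevance.

After IQR normalization, the 33 left-ulnar features are ranked by greedy
quotient MRMR against the sevoflurane concentration; the top ten are what
the regression models see.
"""

from ssepml import (
    GeneratorConfig,
    apply_normalizer,
    assemble_feature_table,
    fit_iqr_normalizer,
    generate_cohort,
    make_regression_problem,
    mrmr_rank,
)
from ssepml.features import META_COLUMNS, TARGET_COLUMN, nerve_columns

cohort = generate_cohort(GeneratorConfig(n_patients=4, trials_per_nerve=12, seed=11))
table = assemble_feature_table(cohort)

keep = [c for c in table.columns if c in META_COLUMNS or c == TARGET_COLUMN]
sub = table[keep + nerve_columns("left_ulnar")]
norm = fit_iqr_normalizer(sub, columns=nerve_columns("left_ulnar"))
X, y = make_regression_problem(apply_normalizer(sub, norm), "left_ulnar")

result = mrmr_rank(X, y, k=10)
print(f"{result.n_significant} of {X.shape[1]} features carry information about "
      "the concentration; top ten by MRMR importance:")
for i, name in enumerate(result.order, 1):
    print(f" {i:2d}. {name:40s} score {result.scores[name]:.3f}")
# The first score is the relevance MI (nats); later scores are the greedy
# relevance/redundancy quotients, so they are not monotone in rank.
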