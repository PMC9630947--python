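"""Explain single subjects' inclusion with local linear surrogates.

Takes the pruned inclusion tree as the black box, picks one correctly
classified matched and one correctly classified unmatched subject, and
prints each subject's feature weights, support/contradict direction, and
explanation fit (the weighted R-squared of the local surrogate).
"""

import numpy as np

from matchexplain import (
    LimeConfig,
    MatchSpec,
    TreeControl,
    encode_design,
    explain_instance,
    fit_logistic,
    fit_population_explainer,
    generate_cohort,
    load_preset,
    nearest_neighbor_match,
)
from matchexplain.cart_engine import predict
from matchexplain.lime_explainer import build_training_summary

cfg = load_preset("hn_ncdb", seed=1)
cohort = generate_cohort(cfg)
X, names = encode_design(cohort, cfg.covariates)
scores = fit_logistic(X, cohort["T"], column_names=names).scores
inclusion = nearest_neighbor_match(
    scores, cohort["T"].to_numpy(), MatchSpec()
).inclusion

cov = [c.name for c in cfg.covariates]
cat = [c.name for c in cfg.covariates if c.kind == "categorical"]
tree, _, _ = fit_population_explainer(
    cohort, inclusion, TreeControl(seed=2), covariate_columns=cov
)

lime_cfg = LimeConfig(seed=3)
summary = build_training_summary(cohort[cov], lime_cfg,
                                 categorical_columns=cat)


def black_box(rows):
    p, _, _ = predict(tree, rows[cov])
    return p


_, predicted, _ = predict(tree, cohort[cov])
for group in ("in", "out"):
    idx = np.flatnonzero((predicted == group) & (inclusion == group))[0]
    exp = explain_instance(black_box, cohort[cov].iloc[idx], summary,
                           lime_cfg, subject_id=int(idx))
    subj = cohort.iloc[idx]
    print(f"\nsubject {idx} (age {subj['age']}, {subj['site']}) - "
          f"{group}, P(in) = {exp.probability:.2f}")
    print(f"explanation fit (weighted R^2): {exp.explanation_fit:.3f}")
    for f in exp.features:
        print(f"  {f['description']:<28} weight {f['weight']:+.3f} "
              f"({f['direction']})")
print("\nLarge-weight features are the ones locally driving the tree's")
print("in/out decision for that subject; 'supports' means the feature pushes")
print("toward the predicted label. A low fit warns that no linear local")
print("story captures the black box around that subject.")
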