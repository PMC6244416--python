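"""Train and validate the calibrated episignature classifier.

Splits the 28 cases 75/25 (stratified by subtype), matches 6:1 controls to
the 21 training cases, runs the feature cascade (|Δβ| ≥ 5% → top 1000 by
moderated p → AUC > 0.85 → prune r² > 0.85), trains the RBF-SVM with
10-fold CV and Platt calibration, and scores the held-out samples.
"""

import pandas as pd

import episig as es

study = es.simulate_study(seed=7)
samples = study.cohort.samples
cases = samples[samples["group"] != "control"]
pool = samples[samples["group"] == "control"]

train_cases, test_cases = es.train_test_split_stratified(cases, 0.75, seed=7)
matched = es.match_controls(cases.loc[train_cases], pool, ratio=6, seed=7)
print(f"training: {len(matched.case_ids)} cases, "
      f"{len(matched.control_ids)} matched controls")

train = study.cohort.subset_samples(matched.all_ids)
cells = es.estimate_cell_composition(train, study.panel)
panel = es.build_feature_panel(train, train.samples,
                               case_labels=("A", "B", "C", "D"),
                               cell_proportions=cells.proportions)
print(f"feature panel after the cascade: {len(panel.probe_ids)} probes")

labels = pd.Series([1] * len(matched.case_ids) + [0] * len(matched.control_ids),
                   index=matched.all_ids)
model = es.train_classifier(train.betas, labels, panel, seed=7)
print(f"10-fold CV accuracy {model.cv_accuracy:.3f} "
      f"at cost={model.cost}, gamma={model.gamma:.4g}")

held_controls = [s for s in pool.index if s not in set(matched.control_ids)]
report = es.score_samples(model, study.cohort.betas[test_cases + held_controls])
print(f"held-out cases  (n={len(test_cases)}): "
      f"scores {report.loc[test_cases, 'score'].min():.3f}"
      f"-{report.loc[test_cases, 'score'].max():.3f}")
print(f"held-out controls (n={len(held_controls)}): "
      f"max score {report.loc[held_controls, 'score'].max():.3f}")
# Scores are Platt-calibrated probabilities of carrying the episignature;
# the diagnostic call uses the 0.5 cutoff, so the two ranges above should
# sit on opposite sides of it with a wide margin.
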