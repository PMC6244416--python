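"""The diagnostic episignature classifier.

Feature selection is a fixed four-stage cascade — (1) drop probes whose
case-vs-control Δβ is below the array's reliably detectable range (5%),
(2) rank the rest by moderated p from a covariate-adjusted regression
(batch and blood cell composition in the model matrix) and keep the top
1000, (3) keep probes whose individual ROC AUC exceeds 0.85, (4) greedily
prune probes whose squared Pearson correlation with an already-kept probe
exceeds 0.85.  The surviving probes feed an RBF-kernel SVM whose cost and
gamma are chosen by stratified 10-fold cross-validation; out-of-fold
decision values calibrate a Platt sigmoid so every scored sample receives
a probability in [0, 1], dichotomised at 0.5.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cohort import MethylationCohort
from .discovery import build_design_matrix, discover_probes

__all__ = ["FeaturePanel", "TrainedModel", "rank_candidate_probes", "probe_auc",
           "prune_correlated", "build_feature_panel", "train_classifier",
           "score_samples", "train_test_split_stratified"]


@dataclass
class FeaturePanel:
    """Ordered probe panel surviving the feature-selection cascade."""

    probe_ids: list[str]
    stats: pd.DataFrame                  # per probe: p, delta_beta, auc
    top_n: int = 1000
    min_delta: float = 0.05
    min_auc: float = 0.85
    max_corr: float = 0.85


@dataclass
class TrainedModel:
    """Fitted RBF-SVM with Platt calibration and its feature panel."""

    panel: FeaturePanel
    svm: SVC
    cost: float
    gamma: float
    platt_a: float
    platt_b: float
    cv_folds: int
    cv_accuracy: float
    training_scores: pd.Series
    threshold: float = 0.5
    provenance_hash: str = ""

    def to_json(self) -> str:
        """Portable metadata (panel, hyperparameters, calibration); the SVM
        itself is an in-memory object and is not serialized here."""
        return json.dumps({
            "probe_ids": self.panel.probe_ids,
            "cost": self.cost, "gamma": self.gamma,
            "platt_a": self.platt_a, "platt_b": self.platt_b,
            "cv_folds": self.cv_folds, "cv_accuracy": self.cv_accuracy,
            "threshold": self.threshold, "provenance_hash": self.provenance_hash,
        }, indent=1)


def rank_candidate_probes(cohort: MethylationCohort, design_samples: pd.DataFrame,
                          case_labels, cell_proportions: pd.DataFrame | None = None,
                          top_n: int = 1000, min_delta: float = 0.05) -> pd.DataFrame:
    """Stage 1–2 of the cascade: effect filter, then moderated-p ranking.

    Fits the moderated model with sex, batch and cell-type proportions as
    covariates (so probes confounded by batch or cell composition lose
    rank), drops probes with |Δβ| < ``min_delta``, sorts ascending by p
    (ties by probe id) and truncates to ``top_n``.
    """
    design = build_design_matrix(design_samples, case_labels,
                                 cell_proportions=cell_proportions,
                                 covariates=("sex",), include_batch=True)
    sub = cohort.subset_samples(design_samples.index)
    st = discover_probes(sub, design, case_labels)
    st = st[st["delta_beta"].abs() >= min_delta]
    order = np.lexsort((st.index.to_numpy(), st["p"].to_numpy()))
    return st.iloc[order].head(top_n)


def probe_auc(case_values, control_values) -> float:
    """Per-probe ROC AUC by the Mann–Whitney pair count, direction-normalized.

    Fraction of (case, control) pairs with case > control, ties counted ½;
    returns max(AUC, 1−AUC) so hypo- and hypermethylated probes score alike.
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    greater = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    auc = (greater + 0.5 * ties) / (a.size * b.size)
    return float(max(auc, 1.0 - auc))


def prune_correlated(betas: pd.DataFrame, candidates: list[str],
                     max_corr: float = 0.85) -> list[str]:
    """Greedy sweep in rank order: drop a probe if its squared Pearson
    correlation with any already-kept probe exceeds ``max_corr``."""
    kept: list[str] = []
    x = betas.loc[candidates].to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x ** 2).sum(axis=1))
    norms[norms == 0] = 1.0
    x = x / norms[:, None]
    kept_idx: list[int] = []
    for i, pid in enumerate(candidates):
        if kept_idx:
            r2 = (x[kept_idx] @ x[i]) ** 2
            if (r2 > max_corr).any():
                continue
        kept_idx.append(i)
        kept.append(pid)
    return kept


def build_feature_panel(cohort: MethylationCohort, design_samples: pd.DataFrame,
                        case_labels, cell_proportions: pd.DataFrame | None = None,
                        top_n: int = 1000, min_delta: float = 0.05,
                        min_auc: float = 0.85, max_corr: float = 0.85
                        ) -> FeaturePanel:
    """Run the full cascade and return the surviving, still-ordered panel."""
    ranked = rank_candidate_probes(cohort, design_samples, case_labels,
                                   cell_proportions, top_n, min_delta)
    sub = cohort.subset_samples(design_samples.index)
    is_case = sub.samples["group"].isin(case_labels).to_numpy()
    case_b = sub.betas.loc[ranked.index].to_numpy()[:, is_case]
    ctrl_b = sub.betas.loc[ranked.index].to_numpy()[:, ~is_case]
    ranked = ranked.copy()
    ranked["auc"] = [probe_auc(case_b[i], ctrl_b[i]) for i in range(len(ranked))]
    ranked = ranked[ranked["auc"] > min_auc]
    kept = prune_correlated(sub.betas, list(ranked.index), max_corr)
    return FeaturePanel(kept, ranked.loc[kept, ["p", "delta_beta", "auc"]],
                        top_n, min_delta, min_auc, max_corr)


def _fit_platt(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt sigmoid fit P(case|f) = 1/(1+exp(A·f+B)) on decision values.

    Uses the standard smoothed targets t+ = (N++1)/(N++2), t− = 1/(N−+2)
    and minimizes the cross-entropy in a numerically stable form.
    """
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll_stable(params):
        a, b = params
        z = a * decision + b
        # -sum t·log P + (1−t)·log(1−P), P = 1/(1+e^z)
        return float(np.sum(t * np.logaddexp(0.0, z)
                            + (1 - t) * np.logaddexp(0.0, -z)))

    res = minimize(nll_stable, x0=np.array([-1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    a, b = res.x
    return float(a), float(b)


def _platt_score(decision: np.ndarray, a: float, b: float) -> np.ndarray:
    z = a * decision + b
    return 1.0 / (1.0 + np.exp(z))


def train_test_split_stratified(samples: pd.DataFrame, train_fraction: float = 0.75,
                                stratify: str = "group", seed: int = 0
                                ) -> tuple[list[str], list[str]]:
    """75/25 split stratified by subtype, largest-remainder apportionment.

    The training set size is round(train_fraction · n); each stratum
    contributes its floor share and the remainder goes to the strata with
    the largest fractional parts (ties by label order), so small subtypes
    stay represented on both sides when possible.
    """
    rng = np.random.default_rng(seed)
    n_train_total = int(round(train_fraction * len(samples)))
    groups = samples.groupby(stratify, sort=True).groups
    floors, remainders = {}, {}
    for g, idx in groups.items():
        exact = train_fraction * len(idx)
        floors[g] = int(np.floor(exact))
        remainders[g] = exact - floors[g]
    short = n_train_total - sum(floors.values())
    for g in sorted(remainders, key=lambda g: (-remainders[g], g))[:max(0, short)]:
        floors[g] += 1
    train, test = [], []
    for g, idx in groups.items():
        idx = list(idx)
        rng.shuffle(idx)
        train.extend(idx[:floors[g]])
        test.extend(idx[floors[g]:])
    return sorted(train), sorted(test)


def train_classifier(betas: pd.DataFrame, labels: pd.Series, panel: FeaturePanel,
                     cv_folds: int = 10, cost_grid=None, gamma_grid=None,
                     seed: int = 0) -> TrainedModel:
    """Grid-searched RBF-SVM with Platt calibration.

    ``betas`` is probe × sample; ``labels`` is 1 (case) / 0 (control) per
    sample.  Cost and gamma are chosen by mean accuracy over stratified
    ``cv_folds``-fold CV; the model is refit on all data at the best pair,
    and the Platt sigmoid is fitted on the out-of-fold decision values of
    that pair so the probabilities are honestly calibrated.
    """
    y = labels.loc[betas.columns].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    x = betas.loc[panel.probe_ids].to_numpy().T        # samples × probes
    d = len(panel.probe_ids)
    if cost_grid is None:
        cost_grid = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
    if gamma_grid is None:
        gamma_grid = [1 / (4 * d), 1 / (2 * d), 1 / d, 2 / d, 4 / d]

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    best = None
    for cost in cost_grid:
        for gamma in gamma_grid:
            correct = 0
            oof = np.zeros(len(y))
            for tr, te in folds:
                svm = SVC(C=cost, gamma=gamma, kernel="rbf")
                svm.fit(x[tr], y[tr])
                pred = svm.predict(x[te])
                correct += int((pred == y[te]).sum())
                oof[te] = svm.decision_function(x[te])
            acc = correct / len(y)
            key = (acc, -cost, -gamma)
            if best is None or key > best[0]:
                best = (key, cost, gamma, acc, oof.copy())
    _, cost, gamma, cv_accuracy, oof = best

    a, b = _fit_platt(oof, y)
    svm = SVC(C=cost, gamma=gamma, kernel="rbf")
    svm.fit(x, y)
    train_scores = pd.Series(_platt_score(svm.decision_function(x), a, b),
                             index=betas.columns, name="score")
    digest = hashlib.sha256(
        np.ascontiguousarray(betas.loc[panel.probe_ids].to_numpy()).tobytes()
    ).hexdigest()[:16]
    return TrainedModel(panel=panel, svm=svm, cost=cost, gamma=gamma,
                        platt_a=a, platt_b=b, cv_folds=cv_folds,
                        cv_accuracy=cv_accuracy, training_scores=train_scores,
                        provenance_hash=digest)


def score_samples(model: TrainedModel, betas: pd.DataFrame) -> pd.DataFrame:
    """Platt-calibrated scores for new samples (probe × sample betas).

    Every panel probe must be present; the report carries the score in
    [0, 1] and the class call at the 0.5 threshold.
    """
    missing = [p for p in model.panel.probe_ids if p not in betas.index]
    if missing:
        raise ValueError(f"input is missing {len(missing)} panel probes: "
                         f"{missing[:5]}...")
    x = betas.loc[model.panel.probe_ids].to_numpy().T
    scores = _platt_score(model.svm.decision_function(x), model.platt_a,
                          model.platt_b)
    return pd.DataFrame({"score": scores,
                         "class": np.where(scores > model.threshold,
                                           "case", "control")},
                        index=betas.columns)
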