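"""Score-based autism-status classification.

The study's design is deliberately spartan: section off a stratified 20%
of the cohort as the training set, fit an *unadjusted* single-predictor
logistic model of autism status on one inequality score, and report
accuracy, sensitivity, and specificity of the 0.5-threshold prediction on
the remaining 80%.  Training on the minority split is unconventional but
is the published procedure, kept as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import schema
from .stats import is_case

__all__ = [
    "ClassificationMetrics",
    "ScoreClassifier",
    "stratified_partition",
    "fit_score_classifier",
    "classification_metrics",
    "evaluate_score_classifiers",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion-matrix metrics (percentages) at a probability threshold.

    Sensitivity takes confirmed-autistic as the positive class.  The exact
    identity accuracy = prevalence*sensitivity + (1-prevalence)*specificity
    holds whenever both class-wise rates are defined.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    n_train: int
    n_test: int
    seed: int | None = None
    undefined: str = ""


@dataclass
class ScoreClassifier:
    """Monotone single-score classifier: logistic fit or midpoint fallback."""

    score_name: str
    intercept: float
    slope: float
    fallback: bool = False

    def predict_proba(self, scores: pd.Series | np.ndarray) -> np.ndarray:
        x = np.asarray(scores, dtype=float)
        eta = self.intercept + self.slope * x
        return 1.0 / (1.0 + np.exp(-eta))


def stratified_partition(records: pd.DataFrame, train_fraction: float = 0.2,
                         seed: int = 0, case_mask: pd.Series | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the cohort into (train, test), sampling ``train_fraction`` of
    each group without replacement.  Train and test are disjoint and their
    union is the cohort."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    case = (case_mask if case_mask is not None else is_case(records)).astype(bool)
    rng = np.random.default_rng(seed)
    train_idx = []
    for flag in (True, False):
        members = records.index[case == flag]
        if len(members) < 5:
            raise ValueError(
                f"group {'case' if flag else 'control'} has only "
                f"{len(members)} members; refusing to split")
        k = int(round(train_fraction * len(members)))
        chosen = rng.choice(members.to_numpy(), size=k, replace=False)
        train_idx.extend(chosen)
    train_mask = records.index.isin(train_idx)
    return records.loc[train_mask], records.loc[~train_mask]


def fit_score_classifier(train_scores: pd.Series, train_case: pd.Series,
                         score_name: str = "score") -> ScoreClassifier:
    """Unadjusted logistic model of autism status on one score.

    On perfectly separated training scores the logistic MLE diverges; the
    classifier then falls back to a midpoint-threshold rule (equivalent
    decision boundary, flagged on the result).
    """
    keep = train_scores.notna()
    x = train_scores[keep].astype(float).to_numpy()
    y = train_case[keep].astype(float).to_numpy()
    lo_pos, hi_neg = x[y == 1].min(), x[y == 0].max()
    lo_neg, hi_pos = x[y == 0].min(), x[y == 1].max()
    separated = (lo_pos > hi_neg) or (lo_neg > hi_pos)
    if not separated:
        X = sm.add_constant(x)
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            if np.all(np.isfinite(fit.bse)) and fit.bse.max() <= 50:
                return ScoreClassifier(score_name, float(fit.params[0]),
                                       float(fit.params[1]))
        except Exception:
            pass
        separated = True
    # midpoint-threshold fallback: steep logistic centred between the groups
    log.warning("separation on training scores for %s; midpoint rule used",
                score_name)
    direction = 1.0 if x[y == 1].mean() >= x[y == 0].mean() else -1.0
    boundary = (lo_pos + hi_neg) / 2.0 if direction > 0 else (hi_pos + lo_neg) / 2.0
    steep = 1e3 / max(np.ptp(x), 1e-9)
    return ScoreClassifier(score_name, float(-direction * steep * boundary),
                           float(direction * steep), fallback=True)


def classification_metrics(classifier: ScoreClassifier,
                           test_scores: pd.Series, test_case: pd.Series,
                           threshold: float = 0.5,
                           n_train: int = 0, seed: int | None = None,
                           ) -> ClassificationMetrics:
    """Confusion-matrix accuracy/sensitivity/specificity (%) on the test set."""
    keep = test_scores.notna()
    if not keep.any():
        raise ValueError("test set has no defined scores")
    x = test_scores[keep].astype(float)
    y = test_case[keep].astype(bool).to_numpy()
    pred = classifier.predict_proba(x) >= threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    n = tp + tn + fp + fn
    undefined = ""
    if tp + fn == 0:
        undefined = "sensitivity"
        log.warning("single-class test set: sensitivity undefined")
    if tn + fp == 0:
        undefined = (undefined + ",specificity").lstrip(",")
        log.warning("single-class test set: specificity undefined")
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return ClassificationMetrics(
        accuracy=100.0 * (tp + tn) / n,
        sensitivity=sens, specificity=spec, threshold=threshold,
        n_train=n_train, n_test=n, seed=seed, undefined=undefined)


def evaluate_score_classifiers(records: pd.DataFrame, scores: pd.DataFrame,
                               score_names=None, train_fraction: float = 0.2,
                               threshold: float = 0.5, seed: int = 0,
                               repeats: int = 1) -> pd.DataFrame:
    """Train/test metrics per score; optionally averaged over seeded repeats."""
    if score_names is None:
        score_names = [c[:-len("_score")] for c in scores.columns
                       if c.endswith("_score")]
    case = is_case(records)
    rows = []
    for name in score_names:
        col = scores[f"{name}_score"]
        per_rep = []
        for r in range(repeats):
            rep_seed = seed + r
            train, test = stratified_partition(records, train_fraction,
                                               seed=rep_seed, case_mask=case)
            clf = fit_score_classifier(col.loc[train.index],
                                       case.loc[train.index], name)
            m = classification_metrics(clf, col.loc[test.index],
                                       case.loc[test.index], threshold,
                                       n_train=len(train), seed=rep_seed)
            per_rep.append(m)
        rows.append({
            "score": name,
            "accuracy": float(np.mean([m.accuracy for m in per_rep])),
            "sensitivity": float(np.mean([m.sensitivity for m in per_rep])),
            "specificity": float(np.mean([m.specificity for m in per_rep])),
            "threshold": threshold, "repeats": repeats,
            "n_train": per_rep[0].n_train, "n_test": per_rep[0].n_test,
            "fallback": any(getattr(m, "undefined", "") for m in per_rep),
        })
    return pd.DataFrame(rows)
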