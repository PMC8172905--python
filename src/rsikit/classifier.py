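"""Random-forest classification of the IFN-gamma-dominant (C2) immune subtype.

Feature importance of the RSI genes for C2 vs non-C2 is quantified as the
mean decrease in Gini impurity (MDG) from a random forest; genes with MDG
strictly above the mean importance are selected, a forest classifier is
trained on them, and performance is reported as accuracy with an exact
binomial 95% CI plus the rank-formulation AUC. Score thresholds are chosen
by the Youden index (sensitivity + specificity - 1) over midpoints between
consecutive distinct observed scores.

Defaults follow the canonical forest settings: 500 trees, sqrt(p) features
per split, unlimited depth; a seed is mandatory wherever randomness enters.
Evaluation defaults to stratified 5-fold cross-validation with metrics
computed on pooled out-of-fold predictions, which avoids the optimism of
resubstitution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError

__all__ = [
    "FeatureImportance",
    "ClassifierReport",
    "Cutpoint",
    "gini_importance",
    "select_features",
    "train_eval",
    "rank_auc",
    "youden_cutpoint",
]


@dataclass
class FeatureImportance:
    """Per-gene mean decrease in Gini (MDG) with the cohort mean."""

    table: pd.DataFrame  # gene, mdg (input order preserved)
    mean_mdg: float


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes.tolist()}")
    return (y == classes.max()).astype(int)


def gini_importance(
    X: pd.DataFrame, y: np.ndarray, n_trees: int = 500, seed: int = 0
) -> FeatureImportance:
    """Forest-based MDG importance of each column of ``X`` for labels ``y``.

    The forest uses Gini impurity, ``n_trees`` trees and sqrt(p) candidate
    features per split. Importances are impurity decreases averaged over
    trees (normalised to sum to one; only the ordering and the above-mean
    rule consume them).
    """
    yb = _check_binary(y)
    if X.isna().any().any():
        raise ValidationError("missing values in feature matrix")
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features="sqrt",
        random_state=seed, n_jobs=1,
    )
    rf.fit(X.to_numpy(), yb)
    table = pd.DataFrame({"gene": X.columns, "mdg": rf.feature_importances_})
    return FeatureImportance(table, float(table["mdg"].mean()))


def select_features(fi: FeatureImportance) -> list[str]:
    """Genes with MDG strictly above the mean importance, input order kept."""
    if len(fi.table) < 2:
        raise ValidationError("need >= 2 scored genes to select features")
    keep = fi.table["mdg"] > fi.mean_mdg
    return fi.table.loc[keep, "gene"].tolist()


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation (ties count half)."""
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both classes")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class ClassifierReport:
    """Cross-validated (or held-out) performance of the C2 forest."""

    selected_genes: list[str]
    accuracy: float
    accuracy_ci: tuple[float, float]  # exact binomial (Clopper-Pearson) 95% CI
    auc: float
    roc_points: pd.DataFrame  # fpr, tpr, threshold
    confusion: dict[str, int]
    oof_scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    seed: int = 0
    scheme: str = "stratified-5-fold"


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    order = np.argsort(-scores, kind="stable")
    y = labels[order].astype(bool)
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    fpr = np.concatenate([[0.0], fp / max(fp[-1], 1)])
    tpr = np.concatenate([[0.0], tp / max(tp[-1], 1)])
    thr = np.concatenate([[np.inf], scores[order]])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def train_eval(
    X: pd.DataFrame,
    y: np.ndarray,
    scheme: str = "kfold",
    n_splits: int = 5,
    test_size: float = 0.3,
    n_trees: int = 500,
    seed: int = 0,
) -> ClassifierReport:
    """Train the forest on the selected genes and evaluate it.

    ``scheme='kfold'`` (default) pools out-of-fold class-1 probabilities
    from a stratified ``n_splits``-fold split; ``scheme='holdout'`` uses a
    single stratified split of ``test_size``. Accuracy carries an exact
    binomial 95% CI; AUC uses the rank formulation on the pooled scores.
    """
    yb = _check_binary(np.asarray(y))
    Xa = X.to_numpy()
    rng_seed = seed
    if scheme == "kfold":
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                   random_state=rng_seed)
        splits = list(splitter.split(Xa, yb))
        scheme_label = f"stratified-{n_splits}-fold"
    elif scheme == "holdout":
        from sklearn.model_selection import train_test_split

        idx = np.arange(len(yb))
        tr, te = train_test_split(idx, test_size=test_size, stratify=yb,
                                  random_state=rng_seed)
        splits = [(tr, te)]
        scheme_label = f"holdout-{test_size}"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    oof = np.full(len(yb), np.nan)
    for tr, te in splits:
        if len(np.unique(yb[tr])) < 2:
            raise ValidationError("degenerate split: one class missing in training")
        rf = RandomForestClassifier(
            n_estimators=n_trees, criterion="gini", max_features="sqrt",
            random_state=rng_seed, n_jobs=1,
        )
        rf.fit(Xa[tr], yb[tr])
        oof[te] = rf.predict_proba(Xa[te])[:, 1]
    mask = ~np.isnan(oof)
    scores, labels = oof[mask], yb[mask]
    pred = (scores >= 0.5).astype(int)
    correct = int((pred == labels).sum())
    n = labels.size
    ci = binomtest(correct, n).proportion_ci(confidence_level=0.95, method="exact")
    return ClassifierReport(
        selected_genes=list(X.columns),
        accuracy=correct / n,
        accuracy_ci=(float(ci.low), float(ci.high)),
        auc=rank_auc(scores, labels),
        roc_points=_roc_points(scores, labels),
        confusion={
            "tp": int(((pred == 1) & (labels == 1)).sum()),
            "fp": int(((pred == 1) & (labels == 0)).sum()),
            "tn": int(((pred == 0) & (labels == 0)).sum()),
            "fn": int(((pred == 0) & (labels == 1)).sum()),
        },
        oof_scores=scores,
        labels=labels,
        seed=seed,
        scheme=scheme_label,
    )


@dataclass
class Cutpoint:
    """Optimal score threshold with achieved sensitivity/specificity."""

    value: float
    criterion: str
    sensitivity: float
    specificity: float
    direction: str  # '>=': positives score at or above the cutpoint


def youden_cutpoint(scores: np.ndarray, labels: np.ndarray) -> Cutpoint:
    """Cutpoint maximising the Youden index over observed-score midpoints.

    Candidates are midpoints between consecutive distinct scores. The
    direction (positives above vs below the cutpoint) is chosen to maximise
    the index; ties between candidates break toward the lower cutpoint.
    """
    scores = np.asarray(scores, float)
    labels = _check_binary(np.asarray(labels)).astype(bool)
    if not labels.any() or labels.all():
        raise ValidationError("both classes must be present")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValidationError("scores are constant; no cutpoint exists")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    pos, neg = scores[labels], scores[~labels]
    best = None
    for direction in (">=", "<="):
        for c in candidates:
            if direction == ">=":
                sens = float((pos >= c).mean())
                spec = float((neg < c).mean())
            else:
                sens = float((pos <= c).mean())
                spec = float((neg > c).mean())
            j = sens + spec - 1.0
            if best is None or j > best[0] + 1e-12:
                best = (j, c, sens, spec, direction)
    _, c, sens, spec, direction = best
    return Cutpoint(float(c), "youden", sens, spec, direction)
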