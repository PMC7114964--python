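"""Random-forest habitat model: live-coral presence / cover-class per mound.

Delineated mounds are the samples. Predictors are the morphometric and
acoustic attributes of each mound plus the joined maximum current speed.
Highly correlated predictors are reduced before fitting (keeping, within
each correlated group, the predictor explaining most response variation).
The forest is trained on a stratified two-thirds of the samples; out-of-bag
statistics are reported for the training partition and sensitivity,
specificity and AUC for the held-out third. Variable importance is the
permutation-based mean decrease in accuracy, and response curves are
partial-dependence profiles of the presence probability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

__all__ = [
    "ModelConfig",
    "EvaluationReport",
    "DEFAULT_PREDICTORS",
    "select_predictors",
    "train_rf",
    "evaluate_confusion",
    "evaluate_binary",
    "predict_map",
    "response_curves",
]

#: Candidate predictor columns considered by the model (attribute-table names).
DEFAULT_PREDICTORS = [
    "Area",
    "Index",
    "MBG_Width",
    "MBG_Length",
    "MBG_W_L",
    "MBG_Orient",
    "MinWD",
    "MaxWD",
    "MeanWD",
    "ConfCL_WD",
    "MinVRelief",
    "MaxVRelief",
    "Min_Rug",
    "Max_Rug",
    "Mean_Rug",
    "Min_BS",
    "Max_BS",
    "Mean_BS",
    "InitialSlp",
    "MaxCurrent",
]


@dataclass
class ModelConfig:
    """Forest and evaluation settings.

    Defaults: 1500 trees, 6 candidate variables per split, one-third of the
    samples held out (stratified), correlated predictors pruned above
    r² = 0.95.
    """

    n_trees: int = 1500
    vars_per_split: int = 6
    test_fraction: float = 1 / 3
    correlation_cutoff: float = 0.95
    seed: int = 0
    target: str = "presence_absence"  # or "cover_class_5"

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.target not in ("presence_absence", "cover_class_5"):
            raise ValueError(f"unknown target {self.target!r}")


@dataclass
class EvaluationReport:
    """Confusion matrix, error rates and (for binary targets) ranking metrics."""

    class_labels: list
    confusion: np.ndarray  # rows = true class, columns = predicted
    class_errors: np.ndarray
    overall_error: float
    oob_error: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    auc: float | None = None
    importance: pd.Series | None = None
    response_curves: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def to_json(self) -> str:
        payload = {
            "class_labels": [str(c) for c in self.class_labels],
            "confusion": self.confusion.tolist(),
            "class_errors": [None if not np.isfinite(e) else e for e in self.class_errors],
            "overall_error": self.overall_error,
            "oob_error": self.oob_error,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }
        if self.importance is not None:
            payload["importance"] = self.importance.to_dict()
        if self.response_curves is not None:
            payload["response_curves"] = {
                k: {"values": v[0].tolist(), "probability": v[1].tolist()}
                for k, v in self.response_curves.items()
            }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# predictor selection
# ---------------------------------------------------------------------------


def _variance_explained(x: pd.Series, y: pd.Series) -> float:
    """Between-class fraction of variance of x under the response grouping."""
    overall = x.var(ddof=0)
    if overall == 0 or not np.isfinite(overall):
        return 0.0
    within = x.groupby(y, observed=True).apply(lambda g: g.var(ddof=0) * len(g)).sum() / len(x)
    return float(1.0 - within / overall)


def select_predictors(
    table: pd.DataFrame,
    response: pd.Series,
    config: ModelConfig = ModelConfig(),
    candidates: list[str] | None = None,
) -> list[str]:
    """Reduce correlated predictors.

    Predictors are grouped by the connected components of the graph whose
    edges join pairs with r² above ``correlation_cutoff``; one survivor per
    group, the predictor explaining the most response variation. Constant
    (or all-NaN) predictors are dropped with a warning.
    """
    cols = [c for c in (candidates or DEFAULT_PREDICTORS) if c in table.columns]
    usable = []
    for c in cols:
        x = table[c]
        if not np.issubdtype(np.asarray(x).dtype, np.number) or x.isna().all():
            warnings.warn(f"predictor {c!r} dropped: non-numeric or empty", stacklevel=2)
            continue
        if np.nanstd(x.to_numpy(dtype=float)) == 0:
            warnings.warn(f"predictor {c!r} dropped: constant", stacklevel=2)
            continue
        usable.append(c)
    if len(usable) < 2:
        return usable
    r2 = table[usable].corr() ** 2
    # connected components of the high-correlation graph
    remaining = set(usable)
    groups: list[list[str]] = []
    while remaining:
        seed_col = min(remaining, key=usable.index)
        comp = {seed_col}
        frontier = [seed_col]
        while frontier:
            cur = frontier.pop()
            for other in list(remaining - comp):
                if r2.loc[cur, other] > config.correlation_cutoff:
                    comp.add(other)
                    frontier.append(other)
        remaining -= comp
        groups.append(sorted(comp, key=usable.index))
    kept = []
    for grp in groups:
        if len(grp) == 1:
            kept.append(grp[0])
        else:
            scores = {c: _variance_explained(table[c], response) for c in grp}
            kept.append(max(grp, key=lambda c: (scores[c], -grp.index(c))))
    return sorted(kept, key=usable.index)


# ---------------------------------------------------------------------------
# evaluation primitives
# ---------------------------------------------------------------------------


def evaluate_confusion(confusion: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class and overall misclassification rates of a confusion matrix.

    Rows are true classes, columns predicted. A class with no samples (zero
    row) yields a NaN class error. Returns (class_errors, overall_error).
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any():
        raise ValueError("confusion matrix must be non-negative")
    row_sums = m.sum(axis=1)
    if row_sums.sum() == 0:
        raise ValueError("confusion matrix is empty")
    with np.errstate(invalid="ignore", divide="ignore"):
        class_errors = (row_sums - np.diag(m)) / row_sums
    overall = float((m.sum() - np.trace(m)) / m.sum())
    return class_errors, overall


def evaluate_binary(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5):
    """Sensitivity, specificity (at the vote threshold) and rank-statistic AUC.

    AUC is the Mann-Whitney statistic: concordant score pairs between the
    positive and negative class, ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the labels")
    pred = scores >= threshold
    sensitivity = float((pred & labels).sum() / n_pos)
    specificity = float((~pred & ~labels).sum() / n_neg)
    ranks = rankdata(scores)
    auc = float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    return sensitivity, specificity, auc


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _prepare_xy(table: pd.DataFrame, predictors: list[str], config: ModelConfig):
    missing = [c for c in predictors if c not in table.columns]
    if missing:
        raise KeyError(f"predictor columns missing from table: {missing}")
    target_col = "CoverClass" if config.target == "cover_class_5" else "Presence"
    if target_col not in table.columns:
        raise KeyError(f"response column {target_col!r} missing from table")
    X = table[predictors].astype(float)
    y = table[target_col]
    if config.target == "presence_absence":
        y = y.astype(bool).astype(int)
    keep = X.notna().all(axis=1) & y.notna()
    return X[keep], y[keep]


def train_rf(
    table: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    predictors: list[str] | None = None,
    compute_importance: bool = True,
    compute_curves: bool = False,
) -> tuple[RandomForestClassifier, EvaluationReport, EvaluationReport]:
    """Fit the forest on a stratified 2/3 split.

    Returns ``(model, training_report, holdout_report)``: the training report
    carries the out-of-bag confusion matrix and OOB error; the holdout report
    carries the confusion on the held-out third plus sensitivity/specificity/
    AUC (binary target) and, on request, permutation importance and partial-
    dependence response curves (both cost many forest evaluations).
    """
    if predictors is None:
        response = table["CoverClass" if config.target == "cover_class_5" else "Presence"]
        predictors = select_predictors(table, response, config)
    X, y = _prepare_xy(table, predictors, config)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("response has a single class; nothing to model")
    # stratified split; re-draw if a test class is empty (tiny classes)
    for attempt in range(10):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            test_size=config.test_fraction,
            random_state=config.seed + attempt,
            stratify=y if min(np.bincount(pd.factorize(y)[0])) >= 2 else None,
        )
        if set(np.unique(y_te)) == set(classes) and set(np.unique(y_tr)) == set(classes):
            break
        warnings.warn("re-drawing the train/test split: a class was empty", stacklevel=2)
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=min(config.vars_per_split, X.shape[1]),
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X_tr, y_tr)

    # out-of-bag statistics on the training partition
    oob_votes = model.oob_decision_function_
    oob_pred = model.classes_[np.nanargmax(oob_votes, axis=1)]
    labels = list(model.classes_)
    train_conf = _confusion(y_tr.to_numpy(), oob_pred, labels)
    tr_errors, tr_overall = evaluate_confusion(train_conf)
    training = EvaluationReport(
        class_labels=labels,
        confusion=train_conf,
        class_errors=tr_errors,
        overall_error=tr_overall,
        oob_error=float(1.0 - model.oob_score_),
    )

    te_pred = model.predict(X_te)
    test_conf = _confusion(y_te.to_numpy(), te_pred, labels)
    te_errors, te_overall = evaluate_confusion(test_conf)
    sens = spec = auc = None
    if config.target == "presence_absence":
        pos_idx = list(model.classes_).index(1)
        scores = model.predict_proba(X_te)[:, pos_idx]
        sens, spec, auc = evaluate_binary(scores, y_te.to_numpy() == 1)
    importance = None
    if compute_importance:
        imp = permutation_importance(
            model, X_te, y_te, scoring="accuracy", n_repeats=10, random_state=config.seed
        )
        importance = pd.Series(
            imp.importances_mean, index=X.columns
        ).sort_values(ascending=False)
    holdout = EvaluationReport(
        class_labels=labels,
        confusion=test_conf,
        class_errors=te_errors,
        overall_error=te_overall,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        importance=importance,
    )
    if compute_curves and config.target == "presence_absence":
        holdout.response_curves = response_curves(model, X_tr)
    return model, training, holdout


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, labels: list) -> np.ndarray:
    m = np.zeros((len(labels), len(labels)), dtype=int)
    index = {lab: i for i, lab in enumerate(labels)}
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    return m


# ---------------------------------------------------------------------------
# prediction and response curves
# ---------------------------------------------------------------------------


def predict_map(model: RandomForestClassifier, table: pd.DataFrame) -> pd.Series:
    """Presence probability (fraction of tree votes) for every feature row."""
    predictors = list(model.feature_names_in_)
    missing = [c for c in predictors if c not in table.columns]
    if missing:
        raise KeyError(f"predictor columns missing from table: {missing}")
    X = table[predictors].astype(float)
    if X.isna().any(axis=1).any():
        bad = table.index[X.isna().any(axis=1)].tolist()
        raise ValueError(f"rows with missing predictor values: {bad}")
    pos_idx = list(model.classes_).index(1)
    proba = model.predict_proba(X)[:, pos_idx]
    return pd.Series(proba, index=table.index, name="PresenceProb")


def response_curves(
    model: RandomForestClassifier,
    table: pd.DataFrame,
    predictors: list[str] | None = None,
    n_grid: int = 25,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Partial-dependence curves of the presence probability.

    For each predictor, a 25-point grid spans its observed range; the curve
    value at a grid point is the mean predicted presence probability over the
    table with the predictor clamped to that point.
    """
    model_cols = list(model.feature_names_in_)
    if predictors is None:
        predictors = model_cols
    unknown = [p for p in predictors if p not in model_cols]
    if unknown:
        raise KeyError(f"predictors not in the model: {unknown}")
    X = table[model_cols].astype(float).dropna()
    pos_idx = list(model.classes_).index(1)
    curves = {}
    for p in predictors:
        grid = np.linspace(X[p].min(), X[p].max(), n_grid)
        probs = np.empty(n_grid)
        for i, v in enumerate(grid):
            Xc = X.copy()
            Xc[p] = v
            probs[i] = model.predict_proba(Xc)[:, pos_idx].mean()
        curves[p] = (grid, probs)
    return curves
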