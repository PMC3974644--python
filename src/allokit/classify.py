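"""Random-forest mode-of-action classifiers and their validation.

Binary (allosteric vs non-allosteric) and ternary (plus allosteric
biologicals) classifiers over the physicochemical descriptor panel,
optionally extended with selected fingerprint bits for congeneric
(target-specific) sets.  Validation follows a 70/30 stratified external
split with out-of-bag scores on the training portion; reports carry the
recall/precision/MCC panel, ROC points, permutation and Gini variable
importances, the feature-class Pearson correlations, and the Pareto
front over (importance, |correlation|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .metrics import (ConfusionMatrix, ValidationMetrics, binary_metrics,
                      roc_curve, ternary_metrics)

__all__ = [
    "ForestModel",
    "ModelReport",
    "split_data",
    "train_classifier",
    "variable_importance",
    "pareto_select",
    "evaluate",
    "run_model",
]


def split_data(features: pd.DataFrame, labels: pd.Series,
               train_fraction: float = 0.7, seed: int = 0):
    """Stratified train/test split; every class needs >=2 records."""
    counts = labels.value_counts()
    if (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(f"classes with fewer than 2 records: {bad}")
    x_tr, x_te, y_tr, y_te = train_test_split(
        features, labels, train_size=train_fraction, random_state=seed,
        stratify=labels, shuffle=True)
    return x_tr, x_te, y_tr, y_te


@dataclass
class ForestModel:
    forest: RandomForestClassifier
    feature_names: list
    classes: list

    def oob_scores(self) -> np.ndarray:
        """Out-of-bag class-probability scores for the training records."""
        return self.forest.oob_decision_function_

    def predict(self, x) -> np.ndarray:
        return self.forest.predict(x)

    def predict_proba(self, x) -> np.ndarray:
        return self.forest.predict_proba(x)


def train_classifier(features: pd.DataFrame, labels: pd.Series,
                     n_trees: int = 500, seed: int = 0) -> ForestModel:
    """Bagged decision-tree ensemble with sqrt(p) features per split and
    per-record out-of-bag scores; supports 2 or 3 classes."""
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True,
        random_state=seed, n_jobs=1)
    forest.fit(features.to_numpy(dtype=float), labels.to_numpy())
    return ForestModel(forest=forest, feature_names=list(features.columns),
                       classes=list(forest.classes_))


def variable_importance(model: ForestModel, features: pd.DataFrame,
                        labels: pd.Series, n_permutations: int = 10,
                        seed: int = 0) -> pd.DataFrame:
    """Permutation importance, Gini importance, and class correlation.

    Permutation importance is the mean accuracy drop on the supplied
    (held-out) records over seeded feature permutations, unscaled.  The
    class correlation is the Pearson correlation between the feature and
    the indicator of the first class (alphabetically); its sign says
    which class the feature "belongs" to.
    """
    rng = np.random.default_rng(seed)
    x = features.to_numpy(dtype=float)
    y = labels.to_numpy()
    base = float(np.mean(model.forest.predict(x) == y))
    drops = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        acc = 0.0
        for _ in range(n_permutations):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            acc += float(np.mean(model.forest.predict(xp) == y))
        drops[j] = base - acc / n_permutations

    indicator = (y == sorted(set(y))[0]).astype(float)
    corr = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.std(col) == 0 or np.std(indicator) == 0:
            corr[j] = 0.0
        else:
            corr[j] = float(np.corrcoef(col, indicator)[0, 1])

    return pd.DataFrame({
        "feature": model.feature_names,
        "permutation_importance": drops,
        "gini_importance": model.forest.feature_importances_,
        "class_correlation": corr,
    })


def pareto_select(importance: pd.DataFrame, top_n: int = 3) -> dict:
    """Pareto front over (permutation importance, |class correlation|),
    then the top features per class by sign of correlation.

    Returns {"front": [features], "<class sign>": [top features]} where
    the positive-correlation class is the first class alphabetically.
    """
    if len(importance) == 0:
        raise ValueError("importance table is empty")
    pts = importance[["permutation_importance", "class_correlation"]].copy()
    pts["abs_corr"] = pts["class_correlation"].abs()
    vals = pts[["permutation_importance", "abs_corr"]].to_numpy()
    n = len(vals)
    dominated = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j and np.all(vals[j] >= vals[i]) and np.any(vals[j] > vals[i]):
                dominated[i] = True
                break
    front = list(importance.loc[~dominated, "feature"])

    def top_for(sign):
        mask = (importance["class_correlation"] * sign) >= 0
        sub = importance[mask].copy()
        sub["_front"] = ~dominated[mask.to_numpy()]
        sub = sub.sort_values(["_front", "permutation_importance"],
                              ascending=[False, False], kind="mergesort")
        return list(sub["feature"].head(top_n))

    return {"front": front, "positive_class": top_for(+1),
            "negative_class": top_for(-1)}


_CANONICAL_ORDER = {"allosteric": 0, "non_allosteric": 1,
                    "allosteric_biological": 2}


def evaluate(y_true, y_pred, labels=None) -> ValidationMetrics:
    """Metric panel with classes in A/B/C role order: A = allosteric,
    B = non-allosteric, C = the biological third class (when present)."""
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    labels = sorted(labels, key=lambda c: (_CANONICAL_ORDER.get(c, 99), c))
    cm = ConfusionMatrix.from_predictions(y_true, y_pred, labels)
    if cm.n_classes == 2:
        return binary_metrics(cm)
    if cm.n_classes == 3:
        return ternary_metrics(cm)
    raise ValueError(f"unsupported number of classes: {cm.n_classes}")


@dataclass
class ModelReport:
    label: str
    set_sizes: dict
    oob_metrics: dict
    external_metrics: dict
    oob_auc: float | None
    external_auc: float | None
    top_features: dict
    importance: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "set_sizes": self.set_sizes,
            "oob": self.oob_metrics,
            "external": self.external_metrics,
            "oob_auc": self.oob_auc,
            "external_auc": self.external_auc,
            "top_features": self.top_features,
        }


def run_model(features: pd.DataFrame, labels: pd.Series, *,
              label: str = "L0", train_fraction: float = 0.7,
              n_trees: int = 500, seed: int = 0,
              importance_permutations: int = 10) -> ModelReport:
    """Train, validate and interpret one classifier end to end."""
    x_tr, x_te, y_tr, y_te = split_data(features, labels, train_fraction,
                                        seed)
    model = train_classifier(x_tr, y_tr, n_trees=n_trees, seed=seed)

    # out-of-bag validation on the training portion
    oob = model.oob_scores()
    oob_pred = np.array(model.classes)[np.nanargmax(oob, axis=1)]
    oob_metrics = evaluate(y_tr, oob_pred, model.classes)

    ext_pred = model.predict(x_te.to_numpy(dtype=float))
    ext_metrics = evaluate(y_te, ext_pred, model.classes)

    oob_auc = ext_auc = None
    if len(model.classes) == 2:
        positive = model.classes[0]  # allosteric class sorts first
        pos_col = model.classes.index(positive)
        mask = ~np.isnan(oob[:, pos_col])
        _, _, _, oob_auc = roc_curve(oob[mask, pos_col],
                                     y_tr.to_numpy()[mask],
                                     positive_label=positive)
        proba = model.predict_proba(x_te.to_numpy(dtype=float))[:, pos_col]
        _, _, _, ext_auc = roc_curve(proba, y_te.to_numpy(),
                                     positive_label=positive)

    importance = variable_importance(model, x_te, y_te,
                                     n_permutations=importance_permutations,
                                     seed=seed)
    top = pareto_select(importance)
    return ModelReport(
        label=label,
        set_sizes={str(c): int((labels == c).sum()) for c in model.classes},
        oob_metrics=oob_metrics.as_dict(),
        external_metrics=ext_metrics.as_dict(),
        oob_auc=oob_auc,
        external_auc=ext_auc,
        top_features=top,
        importance=importance,
    )
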