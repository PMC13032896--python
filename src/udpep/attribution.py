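"""Feature attribution for aggregation-propensity classes.

AP values are binned into three classes (class 1, AP in [1.5, 2), is the
self-assembly sweet spot), three distinct GBDT implementations are trained
on the descriptor panel, features are selected by a multi-model vote
(significant iff importance exceeds that model's mean + 1 SD, selected iff
significant in at least two models), and exact SHAP main / interaction
decompositions quantify how aromaticity, charge, logP and pI drive the
class-1 margin.  The aromaticity threshold claim — one aromatic residue
helps, two or more hinder — is tested by Mann–Whitney U on adjacent
aromatic-count groups with Bonferroni-corrected significance tiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import CapabilityError, DomainError
from .properties import DESCRIPTOR_KEYS, classify_ap_array, descriptor_frame
from .treeshap import ShapDecomposition, extract_ensemble, shap_interactions

__all__ = [
    "FeatureMatrix",
    "build_feature_matrix",
    "stratified_split",
    "ClassifierBundle",
    "train_classifiers",
    "vote_select",
    "shap_decompose",
    "ThresholdTestResult",
    "aromatic_threshold_test",
    "interaction_summary",
    "local_mean_smooth",
    "sign_changes",
]

# Bonferroni-corrected significance tiers (four adjacent-group comparisons).
TIER_CUTOFFS = ((0.001 / 4, "***"), (0.01 / 4, "**"), (0.05 / 4, "*"))


@dataclass(frozen=True)
class FeatureMatrix:
    """Descriptor matrix with AP-class labels; column order is fixed."""

    X: pd.DataFrame
    y: np.ndarray  # ap_class per row
    class_counts: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise DomainError("feature matrix contains missing values")
        if len(self.X) != len(self.y):
            raise DomainError("label / feature length mismatch")
        vals, counts = np.unique(self.y, return_counts=True)
        object.__setattr__(
            self, "class_counts", {int(v): int(c) for v, c in zip(vals, counts)}
        )

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)


def build_feature_matrix(
    records: pd.DataFrame, keys: Sequence[str] | None = None, ph: float = 7.0
) -> FeatureMatrix:
    """Assemble descriptors + class labels from a property table.

    ``records`` needs 'sequence' and 'ap' columns; descriptor columns already
    present are reused, missing ones are computed from the sequence.
    """
    if "ap" not in records.columns or "sequence" not in records.columns:
        raise DomainError("records must contain 'sequence' and 'ap' columns")
    keys = tuple(keys) if keys is not None else DESCRIPTOR_KEYS
    have = [c for c in keys if c in records.columns]
    need = [c for c in keys if c not in records.columns]
    X = records[have].reset_index(drop=True)
    if need:
        extra = descriptor_frame(records["sequence"].tolist()).reset_index(drop=True)
        X = pd.concat([X, extra[need]], axis=1)
    X = X[list(keys)].astype(float)
    y = classify_ap_array(records["ap"].to_numpy(dtype=float))
    return FeatureMatrix(X, y)


def stratified_split(
    fm: FeatureMatrix, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint stratified train/test row indices (class shares preserved)."""
    if min(fm.class_counts.values()) < 2:
        raise DomainError(
            f"every class needs >= 2 members for stratification, got {fm.class_counts}"
        )
    idx = np.arange(len(fm.y))
    train, test = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=fm.y
    )
    return np.sort(train), np.sort(test)


def _default_classifiers(seed: int, fast: bool) -> dict[str, object]:
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    n_est = 100 if fast else 300
    return {
        "xgboost": XGBClassifier(
            n_estimators=n_est, max_depth=3, learning_rate=0.1,
            subsample=0.9, random_state=seed, n_jobs=1, verbosity=0,
            eval_metric="mlogloss",
        ),
        "lightgbm": LGBMClassifier(
            n_estimators=n_est, num_leaves=8, learning_rate=0.1,
            subsample=0.9, subsample_freq=1, random_state=seed, n_jobs=1,
            verbose=-1,
        ),
        "sklearn_gbm": GradientBoostingClassifier(
            n_estimators=max(60, n_est // 2), max_depth=3, learning_rate=0.1,
            subsample=0.9, random_state=seed,
        ),
    }


_SEARCH_SPACES = {
    "xgboost": {
        "n_estimators": [100, 200, 300, 500],
        "max_depth": [2, 3],
        "learning_rate": [0.03, 0.05, 0.1, 0.2],
        "subsample": [0.7, 0.85, 1.0],
    },
    "lightgbm": {
        "n_estimators": [100, 200, 300, 500],
        "num_leaves": [4, 6, 8],
        "learning_rate": [0.03, 0.05, 0.1, 0.2],
        "subsample": [0.7, 0.85, 1.0],
    },
    "sklearn_gbm": {
        "n_estimators": [60, 100, 200],
        "max_depth": [2, 3],
        "learning_rate": [0.03, 0.05, 0.1, 0.2],
        "subsample": [0.7, 0.85, 1.0],
    },
}


@dataclass
class ClassifierBundle:
    """Fitted GBDT trio with held-out metrics and fold-averaged importances."""

    models: dict[str, object]
    metrics: pd.DataFrame          # model x the six classification metrics
    importances: pd.DataFrame      # model x feature (gain-style, CV-averaged)
    feature_names: tuple[str, ...]
    train_idx: np.ndarray
    test_idx: np.ndarray


def _six_metrics(model, X, y) -> dict[str, float]:
    pred = model.predict(X)
    proba = model.predict_proba(X)
    classes = np.unique(y)
    if proba.shape[1] == 2:
        auc = roc_auc_score(y, proba[:, 1])
        pr = average_precision_score(y, proba[:, 1])
    else:
        auc = roc_auc_score(y, proba, multi_class="ovr", average="macro", labels=classes)
        onehot = np.eye(proba.shape[1])[np.searchsorted(classes, y)]
        pr = average_precision_score(onehot, proba, average="macro")
    return {
        "accuracy": accuracy_score(y, pred),
        "precision": precision_score(y, pred, average="macro", zero_division=0),
        "recall": recall_score(y, pred, average="macro", zero_division=0),
        "f1": f1_score(y, pred, average="macro", zero_division=0),
        "roc_auc": auc,
        "pr_auc": pr,
    }


def _gain_importance(model, n_features: int) -> np.ndarray:
    imp = np.asarray(model.feature_importances_, dtype=float)
    out = np.zeros(n_features)
    out[: imp.size] = imp
    return out


def train_classifiers(
    fm: FeatureMatrix,
    seed: int = 0,
    test_fraction: float = 0.2,
    cv_folds: int = 5,
    n_search: int = 0,
    fast: bool = True,
    backends: Sequence[str] = ("xgboost", "lightgbm", "sklearn_gbm"),
) -> ClassifierBundle:
    """Fit the GBDT trio on a stratified split and report the six metrics.

    ``n_search > 0`` runs a stratified-CV random search (selection on
    negative log-loss) over each backend's space before the final refit;
    ``n_search == 0`` uses the documented fixed defaults.  Per-model
    importances are gain-style scores averaged over ``cv_folds`` stratified
    refits on the training data.
    """
    if len(set(fm.y)) < 2:
        raise DomainError("need at least two classes to train classifiers")
    train, test = stratified_split(fm, test_fraction, seed)
    Xtr = fm.X.iloc[train].to_numpy()
    ytr = fm.y[train]
    Xte = fm.X.iloc[test].to_numpy()
    yte = fm.y[test]
    all_models = _default_classifiers(seed, fast)
    unknown = set(backends) - set(all_models)
    if unknown:
        raise CapabilityError(f"unknown classifier backends: {sorted(unknown)}")
    models = {}
    metric_rows = {}
    importance_rows = {}
    d = len(fm.feature_names)
    for name in backends:
        model = all_models[name]
        if n_search > 0:
            from sklearn.model_selection import RandomizedSearchCV

            search = RandomizedSearchCV(
                model,
                _SEARCH_SPACES[name],
                n_iter=n_search,
                cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
                scoring="neg_log_loss",
                random_state=seed,
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                search.fit(Xtr, ytr)
            model = search.best_estimator_
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xtr, ytr)
        models[name] = model
        metric_rows[name] = _six_metrics(model, Xte, yte)
        # fold-averaged importances for the voting step
        folds = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
        acc = np.zeros(d)
        for tr_idx, _ in folds.split(Xtr, ytr):
            clone = type(model)(**model.get_params())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clone.fit(Xtr[tr_idx], ytr[tr_idx])
            acc += _gain_importance(clone, d)
        importance_rows[name] = acc / cv_folds
    metrics = pd.DataFrame(metric_rows).T
    importances = pd.DataFrame(importance_rows, index=list(fm.feature_names)).T
    return ClassifierBundle(models, metrics, importances, fm.feature_names, train, test)


def vote_select(importances: pd.DataFrame, min_votes: int = 2) -> tuple[list[str], pd.DataFrame]:
    """Multi-model voting feature selection.

    A feature is significant for one model iff its importance strictly
    exceeds that model's mean + 1 SD; it is selected iff significant in at
    least ``min_votes`` models.  Returns (selected features, long table with
    per-model thresholds and flags).
    """
    if importances.shape[0] < 2:
        raise DomainError("voting requires importances from at least two models")
    rows = []
    votes = pd.Series(0, index=importances.columns, dtype=int)
    for model, scores in importances.iterrows():
        thr = scores.mean() + scores.std(ddof=0)
        sig = scores > thr
        votes += sig.astype(int)
        for feat in importances.columns:
            rows.append(
                {
                    "model": model,
                    "feature": feat,
                    "importance": float(scores[feat]),
                    "threshold": float(thr),
                    "significant": bool(sig[feat]),
                }
            )
    table = pd.DataFrame(rows)
    table["votes"] = table["feature"].map(votes)
    selected = [f for f in importances.columns if votes[f] >= min_votes]
    return selected, table


def shap_decompose(
    model, X: np.ndarray, class_index: int = 1
) -> ShapDecomposition:
    """Exact SHAP main + interaction decomposition of one class margin.

    Defaults to the class-1 (ideal self-assembly) surface.  Requires a tree
    ensemble supported by :mod:`udpep.treeshap`.
    """
    X = np.asarray(X, dtype=float)
    ens = extract_ensemble(model, X_check=X[:8])
    if class_index >= ens.n_classes:
        class_index = ens.n_classes - 1  # binary models expose one margin
    return shap_interactions(ens, X, class_index=class_index)


@dataclass(frozen=True)
class ThresholdTestResult:
    """Mann–Whitney comparison of SHAP values between adjacent count groups."""

    group_pair: tuple[int, int]
    u_statistic: float
    p_value: float
    tier: str  # '***', '**', '*', or 'NS'
    median_change_pct: float
    n_lo: int
    n_hi: int


def _tier(p: float) -> str:
    for cutoff, label in TIER_CUTOFFS:
        if p < cutoff:
            return label
    return "NS"


def aromatic_threshold_test(
    shap_by_group: Mapping[int, np.ndarray]
) -> list[ThresholdTestResult]:
    """Two-sided Mann–Whitney U across adjacent aromatic-count groups.

    Tiers use the Bonferroni-corrected cutoffs for four comparisons
    (0.001/4, 0.01/4, 0.05/4).  Empty groups are skipped with a warning.
    The median change is reported as a percentage of the lower group's
    absolute median.
    """
    results = []
    counts = sorted(shap_by_group)
    for lo, hi in zip(counts[:-1], counts[1:]):
        a = np.asarray(shap_by_group[lo], dtype=float)
        b = np.asarray(shap_by_group[hi], dtype=float)
        if a.size == 0 or b.size == 0:
            warnings.warn(f"group pair ({lo}, {hi}) has an empty side; skipped", stacklevel=2)
            continue
        u, p = mannwhitneyu(a, b, alternative="two-sided")
        med_a, med_b = float(np.median(a)), float(np.median(b))
        denom = abs(med_a) if abs(med_a) > 1e-12 else np.nan
        change = 100.0 * (med_b - med_a) / denom if np.isfinite(denom) else np.nan
        results.append(
            ThresholdTestResult(
                (lo, hi), float(u), float(p), _tier(p), change, a.size, b.size
            )
        )
    if not results:
        raise DomainError("need at least two non-empty adjacent groups")
    return results


def interaction_summary(
    decomposition: ShapDecomposition,
    feature_names: Sequence[str],
    top_k: int = 10,
) -> pd.DataFrame:
    """Ranked mean |interaction| for all feature pairs (off-diagonal).

    Returns a table with columns feature_i, feature_j, mean_abs_interaction,
    sorted descending; symmetric pairs appear once.
    """
    inter = decomposition.interactions
    d = inter.shape[1]
    if len(feature_names) != d:
        raise DomainError("feature_names length mismatch")
    rows = []
    mean_abs = np.abs(inter).mean(axis=0)
    mean_signed = inter.mean(axis=0)
    for i in range(d):
        for j in range(i + 1, d):
            rows.append(
                {
                    "feature_i": feature_names[i],
                    "feature_j": feature_names[j],
                    "mean_abs_interaction": float(mean_abs[i, j]),
                    "mean_interaction": float(mean_signed[i, j]),
                }
            )
    df = pd.DataFrame(rows).sort_values(
        "mean_abs_interaction", ascending=False, ignore_index=True
    )
    return df.head(top_k) if top_k else df


def dependence_table(
    decomposition: ShapDecomposition,
    X: pd.DataFrame,
    feature: str,
    partner: str,
) -> pd.DataFrame:
    """Per-row (feature value, partner value, interaction value) export."""
    names = list(X.columns)
    i, j = names.index(feature), names.index(partner)
    return pd.DataFrame(
        {
            "feature_value": X[feature].to_numpy(),
            "partner_value": X[partner].to_numpy(),
            "interaction": decomposition.interactions[:, i, j],
        }
    )


def local_mean_smooth(
    x: np.ndarray, y: np.ndarray, window_fraction: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Simple local-mean trend curve over a sliding fraction of the x-range."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    span = (xs[-1] - xs[0]) * window_fraction / 2.0
    smooth = np.array([ys[np.abs(xs - xi) <= span].mean() for xi in xs])
    return xs, smooth


def sign_changes(x: np.ndarray, y: np.ndarray) -> list[float]:
    """x-locations where a smoothed curve crosses zero (linear interpolation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = []
    for i in range(y.size - 1):
        if y[i] == 0.0:
            out.append(float(x[i]))
        elif y[i] * y[i + 1] < 0:
            frac = y[i] / (y[i] - y[i + 1])
            out.append(float(x[i] + frac * (x[i + 1] - x[i])))
    return out
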