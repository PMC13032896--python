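"""Sequence -> property regression protocol.

Designs supply the training sequences; models are tuned by random
hyperparameter search under k-fold cross-validation (selection on CV RMSE),
then evaluated on two complementary test surfaces:

* a **fixed test set** — a seeded draw of sequences from the space excluding
  the design, and
* the **nonfixed test set** — the entire complement of the training
  sequences in the space.

Learning curves track MAE/MSE/RMSE/R2 across the design-size grid, with
inflection points read off the second differences of the metric curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, RandomizedSearchCV
from sklearn.svm import SVR

from .errors import CapabilityError, ConfigError, DomainError
from .peptide_space import SpaceSpec, encode_matrix, index_to_peptide, peptide_to_index
from .uniform_design import DesignSeries, design_to_peptides

__all__ = [
    "SplitSpec",
    "Splits",
    "make_splits",
    "MetricSet",
    "evaluate",
    "BackendSpec",
    "default_backend",
    "tune_and_train",
    "TunedModel",
    "learning_curve",
    "inflection_points",
    "error_profile",
]


# ---------------------------------------------------------------------------
# splits

@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split within the design plus the two test surfaces."""

    train_fraction: float = 0.8
    fixed_test_size: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.fixed_test_size < 1:
            raise ConfigError("fixed_test_size must be positive")


@dataclass(frozen=True)
class Splits:
    """Index sets into the enumerated space (lexicographic peptide ranks)."""

    train: np.ndarray
    validation: np.ndarray
    fixed_test: np.ndarray
    nonfixed_test: np.ndarray
    k: int

    def sequences(self, which: str) -> list[str]:
        idx = getattr(self, which)
        return [index_to_peptide(int(i), self.k) for i in idx]


def make_splits(space: SpaceSpec, design: Sequence[str], spec: SplitSpec) -> Splits:
    """Partition the space around a design sample.

    The design is split ``train_fraction`` / rest into train and validation
    *by run* (repeated level-combinations stay legal design runs); the fixed
    test set is drawn from the space excluding every design sequence; the
    nonfixed test set is the complement of the distinct training sequences.
    """
    rng = np.random.default_rng(spec.seed)
    design_idx = np.array([peptide_to_index(s) for s in design], dtype=np.int64)
    if design_idx.size == 0:
        raise DomainError("design is empty")
    n_total = space.n_total
    n_distinct = np.unique(design_idx).size
    if n_total - n_distinct < spec.fixed_test_size:
        raise DomainError(
            f"design covering {n_distinct} distinct sequences leaves fewer than "
            f"{spec.fixed_test_size} sequences for the fixed test set"
        )
    perm = rng.permutation(design_idx.size)
    n_train = int(round(spec.train_fraction * design_idx.size))
    train = np.sort(design_idx[perm[:n_train]])
    validation = np.sort(design_idx[perm[n_train:]])

    in_design = np.zeros(n_total, dtype=bool)
    in_design[design_idx] = True
    complement = np.flatnonzero(~in_design)
    fixed = np.sort(rng.choice(complement, size=spec.fixed_test_size, replace=False))

    in_train = np.zeros(n_total, dtype=bool)
    in_train[train] = True
    nonfixed = np.flatnonzero(~in_train)
    return Splits(train, validation, fixed, nonfixed, space.k)


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class MetricSet:
    """MAE / MSE / RMSE in property units, R2 against the test mean."""

    mae: float
    mse: float
    rmse: float
    r2: float


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> MetricSet:
    """Standard regression metrics; rmse is sqrt(mse) by construction."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise DomainError("evaluate requires equal-length, non-empty arrays")
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else (1.0 if mse == 0 else -np.inf)
    return MetricSet(float(np.mean(np.abs(err))), mse, float(np.sqrt(mse)), r2)


# ---------------------------------------------------------------------------
# backends and tuning

def _rf_space() -> dict:
    return {
        "n_estimators": sps.randint(100, 1001),
        "max_depth": [5, 10, 20, 40, None],
        "min_samples_leaf": sps.randint(1, 11),
        "max_features": ["sqrt", 0.3, 0.6, 1.0],
    }


def _svm_space() -> dict:
    return {
        "C": sps.loguniform(0.1, 100.0),
        "gamma": sps.loguniform(1e-4, 1.0),
    }


def _gbdt_space() -> dict:
    return {
        "n_estimators": sps.randint(100, 601),
        "learning_rate": sps.loguniform(0.01, 0.3),
        "max_depth": sps.randint(2, 7),
        "subsample": sps.uniform(0.6, 0.4),
    }


@dataclass(frozen=True)
class BackendSpec:
    """A regression backend plus its random-search protocol.

    ``n_search`` sampled configurations are scored by ``cv_folds``-fold CV
    RMSE; the winner is refit on all training data.
    """

    kind: str = "random_forest"
    n_search: int = 50
    cv_folds: int = 5
    seed: int = 0
    search_space: Mapping | None = None
    fixed_params: Mapping | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"random_forest", "support_vector", "gbdt", "transformer"}:
            raise ConfigError(f"unknown backend kind {self.kind!r}")
        if self.n_search < 1 or self.cv_folds < 2:
            raise ConfigError("n_search must be >= 1 and cv_folds >= 2")


def default_backend(kind: str, seed: int = 0, **kwargs) -> BackendSpec:
    return BackendSpec(kind=kind, seed=seed, **kwargs)


def _make_estimator(spec: BackendSpec):
    fixed = dict(spec.fixed_params or {})
    if spec.kind == "random_forest":
        return (
            RandomForestRegressor(random_state=spec.seed, n_jobs=1, **fixed),
            spec.search_space or _rf_space(),
        )
    if spec.kind == "support_vector":
        return SVR(kernel="rbf", **fixed), spec.search_space or _svm_space()
    if spec.kind == "gbdt":
        from xgboost import XGBRegressor

        return (
            XGBRegressor(
                random_state=spec.seed, n_jobs=1, verbosity=0, **fixed
            ),
            spec.search_space or _gbdt_space(),
        )
    if spec.kind == "transformer":
        raise CapabilityError(
            "the transformer backend is handled by udpep.transformer.train_transformer"
        )
    raise ConfigError(spec.kind)


@dataclass
class TunedModel:
    """A refit winner plus its full CV report."""

    model: object
    best_params: dict
    cv_report: pd.DataFrame
    backend: BackendSpec

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(X), dtype=float)


def tune_and_train(X: np.ndarray, y: np.ndarray, backend: BackendSpec) -> TunedModel:
    """Random search + k-fold CV; winner selected on mean CV RMSE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[0] < backend.cv_folds:
        raise DomainError("need |X| == |y| >= cv_folds")
    if float(np.var(y)) == 0.0:
        warnings.warn("response has zero variance; the fitted model is constant", stacklevel=2)
    est, space = _make_estimator(backend)
    if backend.n_search == 1 and not space:
        est.fit(X, y)
        return TunedModel(est, {}, pd.DataFrame(), backend)
    search = RandomizedSearchCV(
        est,
        space,
        n_iter=backend.n_search,
        cv=KFold(backend.cv_folds, shuffle=True, random_state=backend.seed),
        scoring="neg_root_mean_squared_error",
        random_state=backend.seed,
        refit=True,
        n_jobs=1,
        error_score="raise",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
    report = pd.DataFrame(search.cv_results_)
    return TunedModel(search.best_estimator_, dict(search.best_params_), report, backend)


# ---------------------------------------------------------------------------
# learning curves

@dataclass(frozen=True)
class LearningCurve:
    """Metrics per (size, backend, split surface) with detected landmarks."""

    table: pd.DataFrame  # columns: size, backend, split, mae, mse, rmse, r2
    best_points: dict[str, int]        # backend -> size of best fixed-test R2
    inflections: dict[str, list[int]]  # backend -> ranked inflection sizes


def learning_curve(
    series: DesignSeries,
    labels: Mapping[str, float],
    backends: Sequence[BackendSpec],
    split_spec: SplitSpec,
    space: SpaceSpec | None = None,
    label_fn: Callable[[Sequence[str]], np.ndarray] | None = None,
) -> LearningCurve:
    """Train every (size, backend) cell and tabulate both test surfaces.

    ``labels`` maps sequences to the response.  For nonfixed-test evaluation
    of large spaces, ``label_fn`` can generate labels for arbitrary sequence
    lists; without it, nonfixed sequences missing from ``labels`` raise.
    """
    k = series.designs[0].s
    space = space or SpaceSpec(k)
    rows = []
    for size, design in zip(series.sizes, series.designs):
        seqs = design_to_peptides(design)
        missing = [s for s in seqs if s not in labels]
        if missing and label_fn is None:
            raise DomainError(
                f"labels missing for {len(missing)} design sequences, e.g. {missing[:3]}"
            )
        splits = make_splits(space, seqs, split_spec)
        train_seqs = splits.sequences("train")
        X_tr = encode_matrix(train_seqs)
        y_tr = _lookup(labels, label_fn, train_seqs)
        for backend in backends:
            tuned = tune_and_train(X_tr, y_tr, backend)
            for split_name in ("fixed_test", "nonfixed_test"):
                test_seqs = splits.sequences(split_name)
                y_te = _lookup(labels, label_fn, test_seqs)
                pred = tuned.predict(encode_matrix(test_seqs))
                m = evaluate(y_te, pred)
                rows.append(
                    {
                        "size": size,
                        "backend": backend.kind,
                        "split": split_name,
                        "mae": m.mae,
                        "mse": m.mse,
                        "rmse": m.rmse,
                        "r2": m.r2,
                    }
                )
    table = pd.DataFrame(rows)
    best, infl = {}, {}
    for backend in {b.kind for b in backends}:
        sub = table[(table.backend == backend) & (table.split == "fixed_test")]
        sub = sub.sort_values("size")
        if len(sub):
            best[backend] = int(sub.loc[sub.r2.idxmax(), "size"])
        if len(sub) >= 5:
            infl[backend] = inflection_points(
                sub["size"].to_numpy(), sub["r2"].to_numpy()
            )
    return LearningCurve(table, best, infl)


def _lookup(labels, label_fn, seqs) -> np.ndarray:
    if label_fn is not None:
        known = [s for s in seqs if s in labels]
        if len(known) == len(seqs):
            return np.array([labels[s] for s in seqs], dtype=float)
        return np.asarray(label_fn(seqs), dtype=float)
    return np.array([labels[s] for s in seqs], dtype=float)


def inflection_points(
    sizes: np.ndarray, values: np.ndarray, smooth_window: int | None = None
) -> list[int]:
    """Interior grid sizes where |second difference| attains a local maximum.

    Second differences are central and computed on the (optionally
    moving-average smoothed) metric curve; results are ranked by magnitude.
    A curve with constant curvature (e.g. an exact quadratic) has no strict
    local maximum and yields an empty list.
    """
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(values, dtype=float)
    if sizes.size != values.size or sizes.size < 5:
        raise DomainError("need at least five grid points")
    if np.any(np.diff(sizes) <= 0):
        raise DomainError("sizes must be strictly increasing")
    y = values
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(values, kernel, mode="same")
    d2 = np.abs(y[2:] - 2 * y[1:-1] + y[:-2])  # aligned with sizes[1:-1]
    # strict local maxima beyond float noise, so constant-curvature curves
    # (exact quadratics) yield no inflection
    tol = 1e-9 * (d2.max() if d2.size else 0.0)
    peaks = [
        i
        for i in range(1, d2.size - 1)
        if d2[i] > d2[i - 1] + tol and d2[i] > d2[i + 1] + tol
    ]
    peaks.sort(key=lambda i: -d2[i])
    return [int(sizes[i + 1]) for i in peaks]


def error_profile(
    actual: np.ndarray,
    predicted: np.ndarray,
    edges: Sequence[float],
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Per-bin mean percentage error 100*|a - p|/|a|, binned by actual value.

    Samples with |actual| < eps are excluded from the percentages (the ratio
    is undefined near zero) and reported in a separate 'excluded' row.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise DomainError("actual and predicted must be equal-length and non-empty")
    e = np.asarray(list(edges), dtype=float)
    if e.size < 2 or np.any(np.diff(e) <= 0):
        raise DomainError("edges must be strictly increasing")
    ok = np.abs(a) >= eps
    pct = np.full(a.shape, np.nan)
    pct[ok] = 100.0 * np.abs(a[ok] - p[ok]) / np.abs(a[ok])
    which = np.digitize(a, e) - 1  # bin of each sample; -1/underflow, len-1 overflow
    rows = []
    for b in range(e.size - 1):
        sel = ok & (which == b)
        rows.append(
            {
                "bin_lo": e[b],
                "bin_hi": e[b + 1],
                "count": int(sel.sum()),
                "mean_pct_error": float(pct[sel].mean()) if sel.any() else np.nan,
            }
        )
    rows.append(
        {
            "bin_lo": np.nan,
            "bin_hi": np.nan,
            "count": int((~ok).sum()),
            "mean_pct_error": np.nan,
        }
    )
    df = pd.DataFrame(rows)
    df.attrs["excluded_near_zero"] = int((~ok).sum())
    return df
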