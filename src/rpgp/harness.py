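"""Benchmark harness: stratified CV, repeated seeded runs, baselines.

The experimental design: for every repetition ``r`` (seed = ``base_seed +
r``) a random projection is built per target dimension (or skipped for a
full-feature run), the whole dataset is projected once, and a stratified
k-fold split is drawn. Every configured classifier is trained on each
training fold and scored on the matching train/test splits:

* training performance = MCC x 100,
* test performance     = balanced accuracy x 100.

The projection matrix is data-independent, so sharing one ``R`` between
the training and test samples of a fold leaks nothing; by default one
``R`` is shared by all folds of a repetition (regenerate per fold with
``projection_per_fold=True``).

Every (classifier, rp_dim, repeat, fold) record is kept so all aggregates
are recomputable from the raw records — the audit trail a benchmark needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .gp import GPConfig, classify, evolve, to_sexpr
from .io import ExpressionMatrix, LabelVector
from .metrics import (
    confusion,
    percent_correct,
    test_accuracy,
    training_accuracy,
)
from .projection import build_projection, project

__all__ = [
    "CLASSIFIERS",
    "FULL_FEATURES",
    "ExperimentConfig",
    "RunSummary",
    "stratified_folds",
    "fit_baseline",
    "run_experiment",
    "summarize",
]

CLASSIFIERS = ("GP", "DT", "NB", "KNN", "SVM", "RF")

#: Sentinel used in the ``rp_dim`` record column for full-feature runs.
FULL_FEATURES = "full"


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one benchmark experiment."""

    n_folds: int = 10
    n_repeats: int = 30
    rp_dims: tuple = (50, 100, 150)
    classifiers: tuple = CLASSIFIERS
    knn_k: int = 3
    base_seed: int = 0
    gp: GPConfig = field(default_factory=GPConfig)
    projection_per_fold: bool = False
    projection_scheme: str = "gaussian_unit_columns"
    include_full_features: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be positive")
        for k in self.rp_dims:
            if int(k) < 1:
                raise ValueError(f"rp dimension must be positive, got {k}")


def stratified_folds(y: LabelVector | np.ndarray, n_folds: int, seed: int):
    """Stratified k-fold split: list of (train_indices, test_indices).

    Folds are disjoint, cover all samples, and per-fold class counts are
    within 1 of proportional. Deterministic for a given seed. Raises if
    any class has fewer members than ``n_folds`` (which would create
    single-class test folds elsewhere).
    """
    labels = y.labels if isinstance(y, LabelVector) else np.asarray(y, dtype=int)
    _, counts = np.unique(labels, return_counts=True)
    if counts.size < 2:
        raise ValueError("stratified folds need two classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than "
            f"{n_folds} folds; reduce n_folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        (train.copy(), test.copy())
        for train, test in skf.split(np.zeros(labels.size), labels)
    ]


class _SkPredictor:
    """Adapter giving sklearn estimators the ``classify(X) -> {0,1}`` surface."""

    def __init__(self, estimator):
        self._est = estimator

    def classify(self, X) -> np.ndarray:
        return np.asarray(self._est.predict(X), dtype=int)


class GPPredictor:
    """A trained GP program exposed as a predictor, with its provenance."""

    def __init__(self, result):
        self.result = result
        self.tree = result.best_tree

    def classify(self, X) -> np.ndarray:
        return np.asarray(classify(self.tree, np.asarray(X)), dtype=int)

    @property
    def sexpr(self) -> str:
        return to_sexpr(self.tree)


def fit_baseline(name: str, train_X, train_y, seed: int, knn_k: int = 3):
    """Train one of the comparison classifiers on (samples x features) data.

    Library defaults throughout, except KNN where ``k = knn_k`` (3 by
    default). Returns an object with ``classify(X) -> {0,1}``.
    """
    if name == "DT":
        est = DecisionTreeClassifier(random_state=seed)
    elif name == "NB":
        est = GaussianNB()
    elif name == "KNN":
        est = KNeighborsClassifier(n_neighbors=knn_k)
    elif name == "SVM":
        est = SVC(random_state=seed)
    elif name == "RF":
        est = RandomForestClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown baseline classifier {name!r}")
    est.fit(np.asarray(train_X), np.asarray(train_y, dtype=int))
    return _SkPredictor(est)


def _derived_seed(*parts) -> int:
    """Deterministic sub-seed below 2**31 from hierarchical components."""
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunSummary:
    """Raw per-(classifier, rp_dim, repeat, fold) records plus config echo.

    ``records`` columns: classifier, rp_dim, repeat, fold, train_accuracy
    (MCC x 100), train_percent_correct, test_accuracy (balanced x 100),
    program (GP S-expression, NA otherwise).
    """

    records: pd.DataFrame
    config: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        return summarize(self.records)

    def to_tsv(self, records_path, summary_path) -> None:
        self.records.to_csv(records_path, sep="\t", index=False)
        self.aggregate().to_csv(summary_path, sep="\t", index=False)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample standard deviation per (classifier, rp_dim) cell.

    Pools all (repeat, fold) records of a cell, as the "mean over folds
    and repeats" presentation requires. Single-record cells report std 0
    with ``single_record=True``. Order of records does not matter.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    rows = []
    for (clf, dim), grp in records.groupby(["classifier", "rp_dim"], sort=True):
        n = len(grp)
        row = {
            "classifier": clf,
            "rp_dim": dim,
            "n_records": n,
            "single_record": n == 1,
        }
        for col in ("train_accuracy", "test_accuracy"):
            vals = grp[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_std"] = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _train_predictor(name, Xtr, ytr, seed, cfg: ExperimentConfig):
    if name == "GP":
        result = evolve(Xtr, ytr, replace(cfg.gp, seed=seed))
        return GPPredictor(result)
    return fit_baseline(name, Xtr, ytr, seed, knn_k=cfg.knn_k)


def run_experiment(
    m: ExpressionMatrix, y: LabelVector, cfg: ExperimentConfig
) -> RunSummary:
    """Run the full benchmark design and return all records.

    For each repeat and each entry of ``cfg.rp_dims`` (plus a full-feature
    pass if ``rp_dims`` is empty or ``include_full_features`` is set), all
    configured classifiers are trained per stratified fold and scored.
    Deterministic for a fixed ``base_seed``.
    """
    y.check_aligned(m)
    dims: list = list(cfg.rp_dims)
    if not dims or cfg.include_full_features:
        dims = [None] + dims
    for k in dims:
        if k is not None and int(k) >= m.n_features:
            raise ValueError(
                f"rp dimension {k} must be below the feature count "
                f"{m.n_features}"
            )

    rows = []
    X_full = m.values.T  # samples x features
    labels = y.labels
    for r in range(cfg.n_repeats):
        rep_seed = cfg.base_seed + r
        folds = stratified_folds(y, cfg.n_folds, rep_seed)
        for dim_idx, k in enumerate(dims):
            if k is not None and not cfg.projection_per_fold:
                p = build_projection(
                    m.n_features, int(k), rep_seed, cfg.projection_scheme
                )
                X_dim = project(m, p).values.T
            for fold_idx, (train_idx, test_idx) in enumerate(folds):
                if k is None:
                    X = X_full
                elif cfg.projection_per_fold:
                    p = build_projection(
                        m.n_features,
                        int(k),
                        _derived_seed(rep_seed, fold_idx),
                        cfg.projection_scheme,
                    )
                    X = project(m, p).values.T
                else:
                    X = X_dim
                Xtr, ytr = X[train_idx], labels[train_idx]
                Xte, yte = X[test_idx], labels[test_idx]
                for clf_idx, name in enumerate(cfg.classifiers):
                    seed = _derived_seed(
                        cfg.base_seed, r, dim_idx, fold_idx, clf_idx
                    )
                    try:
                        predictor = _train_predictor(name, Xtr, ytr, seed, cfg)
                        c_tr = confusion(predictor.classify(Xtr), ytr)
                        c_te = confusion(predictor.classify(Xte), yte)
                    except Exception as exc:
                        raise RuntimeError(
                            f"classifier {name} failed at repeat {r}, "
                            f"fold {fold_idx}, rp_dim {k}: {exc}"
                        ) from exc
                    rows.append(
                        {
                            "classifier": name,
                            "rp_dim": FULL_FEATURES if k is None else int(k),
                            "repeat": r,
                            "fold": fold_idx,
                            "train_accuracy": training_accuracy(c_tr),
                            "train_percent_correct": percent_correct(c_tr),
                            "test_accuracy": test_accuracy(c_te),
                            "program": predictor.sexpr
                            if isinstance(predictor, GPPredictor)
                            else pd.NA,
                        }
                    )
    records = pd.DataFrame(rows)
    config_echo = {
        "n_folds": cfg.n_folds,
        "n_repeats": cfg.n_repeats,
        "rp_dims": list(cfg.rp_dims),
        "classifiers": list(cfg.classifiers),
        "knn_k": cfg.knn_k,
        "base_seed": cfg.base_seed,
        "projection_per_fold": cfg.projection_per_fold,
        "projection_scheme": cfg.projection_scheme,
        "gp": cfg.gp.__dict__.copy(),
    }
    return RunSummary(records=records, config=config_echo)
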