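"""Classifier training and repeated stratified cross-validation.

The evaluation protocol: 30 repeats of stratified 5-fold cross-validation
(150 training-validation cycles).  Inside every cycle the full selection
pipeline (Z-score, LASSO, correlation pruning) is re-fit on the four
training folds only, the three classifier families (SVM, random forest,
LDA) are trained with hyperparameters chosen by inner cross-validated
misclassification loss, and the operating threshold is set by the Youden
index on the validation predictions.  The model with the highest validation
accuracy across cycles is exported per family for independent testing.

All splitting is at the subject level, and train/validation disjointness is
asserted for every cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .evaluation import auroc
from .selection import SelectionState, select_features

__all__ = [
    "CVConfig",
    "TrainedModel",
    "CycleResult",
    "RepeatedCVResult",
    "stratified_kfold",
    "cv_cycle_plan",
    "train_classifier",
    "youden_threshold",
    "repeated_cv",
    "apply_model",
]

CLASSIFIER_KINDS = ("svm", "rf", "lda")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol and hyperparameter grids.

    Defaults follow the published protocol: 5 stratified folds, 30 repeats
    (150 cycles), SVM box constraints spanning 0.1-10 over linear/RBF/cubic
    polynomial kernels, random forests of 100-1000 trees with minimum leaf
    sizes 1-20, inner 5-fold model selection by misclassification loss.
    """

    n_folds: int = 5
    n_repeats: int = 30
    svm_kernels: tuple[str, ...] = ("linear", "rbf", "poly")
    svm_c: tuple[float, ...] = (0.1, 0.31622776601683794, 1.0, 3.1622776601683795, 10.0)
    rf_trees: tuple[int, ...] = (100, 250, 500, 1000)
    rf_min_leaf: tuple[int, ...] = (1, 5, 10, 20)
    inner_folds: int = 5
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    lasso_lambdas: tuple[float, ...] | None = None
    correlation_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")
        if not self.svm_kernels or not self.svm_c or not self.rf_trees or not self.rf_min_leaf:
            raise ValueError("hyperparameter grids must be non-empty")
        unknown = set(self.classifiers) - set(CLASSIFIER_KINDS)
        if unknown:
            raise ValueError(f"unknown classifier kinds: {sorted(unknown)}")

    @property
    def n_cycles(self) -> int:
        return self.n_folds * self.n_repeats


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its selection state and threshold."""

    kind: str
    estimator: object
    hyperparameters: dict
    selection: SelectionState
    threshold: float | None = None

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        x = self.selection.zscore.transform(features)[self.selection.final_features]
        return self.estimator.predict_proba(x.values)[:, 1]


class YoudenResult(NamedTuple):
    threshold: float
    j: float
    degenerate: bool


@dataclass
class CycleResult:
    repeat: int
    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    final_features: list[str]
    metrics: dict  # per classifier kind: auroc, accuracy, threshold, hyperparameters
    val_probabilities: dict  # per kind: out-of-fold probabilities
    val_labels: np.ndarray


@dataclass
class RepeatedCVResult:
    cycles: list[CycleResult]
    retention_counts: pd.Series
    n_cycles: int
    best_models: dict  # kind -> TrainedModel
    best_cycle: dict  # kind -> (repeat, fold, accuracy)
    config: CVConfig
    seed: int

    def cycle_aurocs(self, kind: str) -> np.ndarray:
        return np.array([c.metrics[kind]["auroc"] for c in self.cycles])

    def out_of_fold(self, kind: str, repeat: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Pooled out-of-fold probabilities and labels for one repeat."""
        probs, labels = [], []
        for c in self.cycles:
            if c.repeat == repeat:
                probs.append(c.val_probabilities[kind])
                labels.append(c.val_labels)
        return np.concatenate(probs), np.concatenate(labels)


def stratified_kfold(labels, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-level stratified fold assignment, deterministic per seed."""
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels are single-class")
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members; need >= {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    return [(tr.copy(), va.copy()) for tr, va in skf.split(np.zeros_like(y), y)]


def cv_cycle_plan(
    labels, config: CVConfig, seed: int
) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """All (repeat, fold, train_idx, val_idx) cycles of the full protocol."""
    repeat_seeds = _repeat_seeds(seed, config.n_repeats)
    plan = []
    for r in range(config.n_repeats):
        for f, (tr, va) in enumerate(stratified_kfold(labels, config.n_folds, repeat_seeds[r])):
            plan.append((r, f, tr, va))
    return plan


def _repeat_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _inner_cv(y: np.ndarray, folds: int, seed: int) -> StratifiedKFold:
    _, counts = np.unique(y, return_counts=True)
    return StratifiedKFold(
        n_splits=int(min(folds, counts.min())), shuffle=True, random_state=seed % 2**31
    )


def train_classifier(kind: str, X, y, config: CVConfig, seed: int) -> TrainedModel:
    """Fit one classifier family with inner-CV hyperparameter selection.

    Model selection minimizes inner cross-validated misclassification loss.
    All three families emit class probabilities: the SVM through a monotone
    logistic (Platt) link fitted on inner-CV decision scores, the forest via
    vote fractions, LDA via its posterior.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 subjects in each class")
    rs = seed % 2**31
    if kind == "svm":
        grid = {"kernel": list(config.svm_kernels), "C": list(config.svm_c)}
        base = SVC(degree=3, gamma="scale", random_state=rs)
    elif kind == "rf":
        grid = {
            "n_estimators": list(config.rf_trees),
            "min_samples_leaf": list(config.rf_min_leaf),
        }
        base = RandomForestClassifier(random_state=rs, n_jobs=1)
    elif kind == "lda":
        grid = None
        base = LinearDiscriminantAnalysis()
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")

    if grid:
        search = GridSearchCV(
            base, grid, scoring="accuracy", cv=_inner_cv(y, config.inner_folds, seed),
            refit=True, n_jobs=1,
        )
        search.fit(X, y)
        est = search.best_estimator_
        hyper = dict(search.best_params_)
        if kind == "svm":
            # monotone logistic (Platt) link fitted on inner-CV decision scores
            est = CalibratedClassifierCV(
                est, method="sigmoid", cv=_inner_cv(y, config.inner_folds, seed),
                ensemble=False,
            )
            est.fit(X, y)
    else:
        est = base.fit(X, y)
        hyper = {}
    return TrainedModel(kind=kind, estimator=est, hyperparameters=hyper, selection=None)


def youden_threshold(scores, labels) -> YoudenResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidate cutpoints are midpoints between sorted unique scores; ties in
    J resolve to the lowest threshold.  A constant score vector is flagged
    degenerate with J = 0.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class")
    uniq = np.unique(s)
    if uniq.size < 2:
        return YoudenResult(threshold=float(uniq[0]), j=0.0, degenerate=True)
    cuts = 0.5 * (uniq[:-1] + uniq[1:])
    n1 = np.sum(y == 1)
    n0 = np.sum(y == 0)
    best = YoudenResult(float(cuts[0]), -np.inf, False)
    for c in cuts:
        pred = s >= c
        sens = np.sum(pred & (y == 1)) / n1
        spec = np.sum(~pred & (y == 0)) / n0
        j = sens + spec - 1
        if j > best.j:  # strict: ties keep the lowest threshold
            best = YoudenResult(float(c), float(j), False)
    return best


def repeated_cv(table: pd.DataFrame, config: CVConfig, seed: int) -> RepeatedCVResult:
    """Run the full repeated stratified cross-validation protocol.

    ``table`` is a feature table with ``subject_id``, ``label`` and feature
    columns.  Feature selection is re-fit independently inside every
    training fold; the validation fold never touches selection or training.
    Deterministic: a fixed seed reproduces every cycle bit-identically.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 subjects")
    y = table["label"].to_numpy(dtype=int)
    feature_cols = [c for c in table.columns if c not in ("subject_id", "label")]
    features = table[feature_cols]
    lambdas = np.asarray(config.lasso_lambdas) if config.lasso_lambdas else None

    cycles: list[CycleResult] = []
    retention = pd.Series(0.0, index=feature_cols)
    best_models: dict[str, TrainedModel] = {}
    best_key: dict[str, tuple] = {}
    plan = cv_cycle_plan(y, config, seed)
    cycle_seeds = np.random.SeedSequence(seed + 1).generate_state(len(plan)) % (2**31)

    for (r, f, tr, va), cseed in zip(plan, cycle_seeds):
        assert np.intersect1d(tr, va).size == 0, "train/validation overlap"
        try:
            sel = select_features(
                features.iloc[tr], y[tr], seed=int(cseed), lambdas=lambdas,
                correlation_threshold=config.correlation_threshold,
            )
            x_train = sel.zscore.transform(features.iloc[tr])[sel.final_features]
            x_val = sel.zscore.transform(features.iloc[va])[sel.final_features]
            metrics: dict[str, dict] = {}
            val_probs: dict[str, np.ndarray] = {}
            for kind in config.classifiers:
                model = train_classifier(kind, x_train.values, y[tr], config, int(cseed))
                model.selection = sel
                probs = model.estimator.predict_proba(x_val.values)[:, 1]
                yj = youden_threshold(probs, y[va])
                model.threshold = yj.threshold
                pred = (probs >= yj.threshold).astype(int)
                acc = float(np.mean(pred == y[va]))
                roc = auroc(probs, y[va])
                metrics[kind] = {
                    "auroc": roc.value,
                    "accuracy": acc,
                    "threshold": yj.threshold,
                    "youden_j": yj.j,
                    "degenerate_threshold": yj.degenerate,
                    "hyperparameters": model.hyperparameters,
                }
                val_probs[kind] = probs
                key = (acc, roc.value)
                if kind not in best_key or key > best_key[kind]:
                    # strict >: ties keep the earlier cycle
                    best_key[kind] = key
                    best_models[kind] = model
        except Exception as exc:  # noqa: BLE001 - annotate with cycle context
            raise RuntimeError(f"cycle failed (repeat {r}, fold {f}): {exc}") from exc
        for name in sel.final_features:
            retention[name] += 1
        cycles.append(
            CycleResult(
                repeat=r,
                fold=f,
                train_idx=tr,
                val_idx=va,
                final_features=list(sel.final_features),
                metrics=metrics,
                val_probabilities=val_probs,
                val_labels=y[va],
            )
        )

    return RepeatedCVResult(
        cycles=cycles,
        retention_counts=retention,
        n_cycles=len(cycles),
        best_models=best_models,
        best_cycle={k: {"accuracy": best_key[k][0], "auroc": best_key[k][1]} for k in best_key},
        config=config,
        seed=seed,
    )


def apply_model(model: TrainedModel, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and thresholded classes on an independent table.

    Normalization and feature subsetting come from the model's stored
    selection state; nothing is re-fit.
    """
    missing = [c for c in model.selection.final_features if c not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    probs = model.predict_proba(table)
    if model.threshold is None:
        raise ValueError("model has no decision threshold")
    return probs, (probs >= model.threshold).astype(int)
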