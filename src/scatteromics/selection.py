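"""Feature normalization and selection: Z-score, LASSO, correlation pruning.

The selection pipeline applied inside every training fold:

1. Z-score normalization (constant features are flagged and excluded; test
   tables are transformed with the training-fold parameters — no leakage).
2. L1-penalized logistic regression over a log-spaced lambda grid; lambda is
   chosen by internal stratified cross-validated deviance and features with
   nonzero coefficients are retained.
3. Spearman correlation pruning: among retained pairs with |rho| > 0.8
   (processed in descending |rho| order) the member with the smaller raw
   dynamic range (max - min over the training rows, pre-normalization) is
   removed.

Retention bookkeeping across repeated cross-validation cycles yields the
per-feature retention probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ZScoreState",
    "SelectionState",
    "RetentionRecord",
    "default_lambda_grid",
    "zscore_fit_apply",
    "lasso_select",
    "spearman_matrix",
    "correlation_prune",
    "select_features",
    "retention_probabilities",
]


def default_lambda_grid() -> np.ndarray:
    """50 log-spaced L1 penalties spanning [1e-4, 1e1]."""
    return np.logspace(-4, 1, 50)


@dataclass
class ZScoreState:
    means: pd.Series
    stds: pd.Series
    constant_features: list[str]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        # non-finite entries (flagged-invalid statistics, e.g. the skewness
        # of a zero-variance map) are mean-imputed after standardization
        cols = self.means.index
        z = (table[cols] - self.means) / self.stds
        return z.mask(~np.isfinite(z), 0.0)


@dataclass
class SelectionState:
    """Everything a trained model needs to reapply its feature selection."""

    zscore: ZScoreState
    lasso_lambda: float = float("nan")
    lasso_coefficients: pd.Series = field(default_factory=pd.Series)
    retained_after_lasso: list[str] = field(default_factory=list)
    pruned: list[tuple[str, str, float]] = field(default_factory=list)  # (removed, kept, rho)
    final_features: list[str] = field(default_factory=list)


@dataclass
class RetentionRecord:
    counts: pd.Series  # per-feature retained-cycle counts
    n_cycles: int


def zscore_fit_apply(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[pd.DataFrame, list[pd.DataFrame], ZScoreState]:
    """Fit Z-score parameters on the training table and apply everywhere.

    Constant training columns (std == 0) are excluded from the transformed
    output and recorded in ``state.constant_features``.  Columns must be
    numeric features only.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    means = train.mean()
    stds = train.std(ddof=0)
    constant = [c for c in train.columns if stds[c] == 0 or not np.isfinite(stds[c])]
    keep = [c for c in train.columns if c not in constant]
    state = ZScoreState(means=means[keep], stds=stds[keep], constant_features=constant)
    return state.transform(train), [state.transform(o) for o in others], state


def lasso_select(
    X: pd.DataFrame,
    y,
    seed: int,
    lambdas: np.ndarray | None = None,
    n_folds: int = 5,
) -> tuple[list[str], float, pd.Series]:
    """L1 logistic regression with lambda chosen by inner-CV deviance.

    Returns ``(retained feature names, chosen lambda, coefficients)``.  If
    the deviance-optimal lambda shrinks every coefficient to zero, the
    penalty is relaxed along the grid until at least one feature survives
    (an empty model would abort the downstream classifiers).
    """
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels are single-class")
    if counts.min() < 2:
        raise ValueError("need >= 2 subjects per class")
    lambdas = default_lambda_grid() if lambdas is None else np.asarray(lambdas, dtype=float)
    n = len(y)
    cs = 1.0 / (n * lambdas)  # sklearn C; objective (1/n) logloss + lambda ||w||_1
    order = np.argsort(cs)
    cs_sorted = cs[order]
    folds = min(n_folds, counts.min())
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = LogisticRegressionCV(
            Cs=cs_sorted,
            cv=cv,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            refit=True,
            max_iter=2000,
            random_state=seed % 2**31,
        )
        model.fit(X.values, y)
    best_c = float(model.C_[0])
    coef = model.coef_[0].copy()
    if not np.any(np.abs(coef) > 1e-12):
        # relax the penalty until something survives
        for c in cs_sorted[np.searchsorted(cs_sorted, best_c, side="right"):]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                warnings.simplefilter("ignore", UserWarning)
                lr = LogisticRegression(
                    C=c, penalty="l1", solver="liblinear", max_iter=2000,
                    random_state=seed % 2**31,
                )
                lr.fit(X.values, y)
            if np.any(np.abs(lr.coef_[0]) > 1e-12):
                best_c, coef = float(c), lr.coef_[0].copy()
                break
    coefficients = pd.Series(coef, index=X.columns)
    retained = [c for c in X.columns if abs(coefficients[c]) > 1e-12]
    lam = 1.0 / (n * best_c)
    return retained, lam, coefficients


def spearman_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank-correlation matrix of the feature columns.

    Constant columns produce NaN entries (flagged-undefined); the diagonal
    is unit by convention.
    """
    if len(X) < 3:
        raise ValueError("need at least 3 rows")
    arr = np.asarray(X, dtype=float)
    if arr.shape[1] == 1:
        rho = np.ones((1, 1))
    elif arr.shape[1] == 2:
        r = float(spearmanr(arr[:, 0], arr[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = spearmanr(arr, axis=0).statistic
    rho = np.array(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=X.columns, columns=X.columns)


def correlation_prune(
    retained: list[str],
    matrix: pd.DataFrame,
    X_raw: pd.DataFrame,
    threshold: float = 0.8,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Remove the lesser-dynamic-range member of highly correlated pairs.

    Pairs with |rho| strictly above ``threshold`` are processed in
    descending |rho| order; when both members are still alive the one with
    the smaller raw dynamic range (max - min over the training rows, before
    normalization) is dropped.  Deterministic: ties in |rho| break on the
    pair's column order and ties in range drop the later column.

    Returns ``(surviving names, pruned records)`` where each record is
    ``(removed, kept, rho)``.
    """
    alive = dict.fromkeys(retained, True)
    ranges = {c: float(X_raw[c].max() - X_raw[c].min()) for c in retained}
    pairs = []
    for i, a in enumerate(retained):
        for b in retained[i + 1 :]:
            rho = float(matrix.loc[a, b])
            if np.isfinite(rho) and abs(rho) > threshold:
                pairs.append((abs(rho), i, a, b, rho))
    pairs.sort(key=lambda t: (-t[0], t[1]))
    removed: list[tuple[str, str, float]] = []
    for _, _, a, b, rho in pairs:
        if alive[a] and alive[b]:
            drop, keep = (b, a) if ranges[a] >= ranges[b] else (a, b)
            alive[drop] = False
            removed.append((drop, keep, rho))
    return [c for c in retained if alive[c]], removed


def select_features(
    train_features: pd.DataFrame,
    y,
    seed: int,
    lambdas: np.ndarray | None = None,
    correlation_threshold: float = 0.8,
) -> SelectionState:
    """The full per-fold pipeline: Z-score -> LASSO -> correlation pruning.

    ``train_features`` holds raw (unnormalized) feature columns for the
    training rows only; the returned state carries everything needed to
    transform and subset any other table identically.
    """
    train_norm, _, zstate = zscore_fit_apply(train_features)
    retained, lam, coefs = lasso_select(train_norm, y, seed, lambdas=lambdas)
    if len(retained) > 1:
        matrix = spearman_matrix(train_norm[retained])
        final, pruned = correlation_prune(
            retained, matrix, train_features, threshold=correlation_threshold
        )
    else:
        final, pruned = list(retained), []
    return SelectionState(
        zscore=zstate,
        lasso_lambda=lam,
        lasso_coefficients=coefs,
        retained_after_lasso=retained,
        pruned=pruned,
        final_features=final,
    )


def retention_probabilities(
    records: list[list[str]],
    all_features: list[str],
    n_cycles: int | None = None,
) -> pd.Series:
    """Per-feature fraction of cycles in which the feature was retained.

    Sorted descending by probability (name order breaks ties for
    determinism).
    """
    if len(records) < 1:
        raise ValueError("need at least one cycle")
    n = n_cycles if n_cycles is not None else len(records)
    counts = pd.Series(0, index=list(all_features), dtype=float)
    for cycle_features in records:
        for f in cycle_features:
            counts[f] += 1
    probs = counts / n
    return probs.sort_index().sort_values(ascending=False, kind="stable")
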