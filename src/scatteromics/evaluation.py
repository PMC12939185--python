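"""Classifier performance evaluation: ROC, confusion panel, calibration.

AUROC is the pairwise concordance probability (ties count one half), with a
Hanley–McNeil asymptotic 95% confidence interval.  The confusion-derived
panel covers sensitivity, specificity, accuracy, F1, diagnostic likelihood
ratios (LR+ = sens/(1-spec), LR- = (1-sens)/spec), predictive values and
balanced accuracy.  Calibration groups out-of-fold predicted probabilities
into ten equally spaced bins and compares mean predicted probability with
the observed positive fraction; the Brier score is the mean squared
probability error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, norm
from scipy.stats import rankdata

if TYPE_CHECKING:  # pragma: no cover
    from .modeling import TrainedModel

__all__ = [
    "AUROCResult",
    "auroc",
    "confusion_metrics",
    "metrics_from_rates",
    "brier_score",
    "calibration_curve",
    "anova_oneway",
    "report",
]


@dataclass(frozen=True)
class AUROCResult:
    value: float
    ci_low: float
    ci_high: float
    n_positive: int
    n_negative: int


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def auroc(scores, labels) -> AUROCResult:
    """AUROC by pairwise concordance with a Hanley–McNeil 95% CI.

    Equivalent to the normalized Mann–Whitney U statistic: ranks of the
    pooled scores, ties counted one half.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    ranks = rankdata(s)
    a = (np.sum(ranks[y == 1]) - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    se = np.sqrt(max(var, 0.0))
    z = norm.ppf(0.975)
    return AUROCResult(
        value=float(a),
        ci_low=float(max(0.0, a - z * se)),
        ci_high=float(min(1.0, a + z * se)),
        n_positive=n1,
        n_negative=n0,
    )


def confusion_metrics(predicted, labels) -> dict:
    """Confusion counts and the derived metric panel.

    Zero-denominator metrics are returned as ``inf`` (LR+ at perfect
    specificity) or NaN and listed under ``flags`` rather than raising.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if y.size == 0 or y.shape != p.shape:
        raise ValueError("predicted and labels must be non-empty and aligned")
    tp = int(np.sum((p == 1) & (y == 1)))
    tn = int(np.sum((p == 0) & (y == 0)))
    fp = int(np.sum((p == 1) & (y == 0)))
    fn = int(np.sum((p == 0) & (y == 1)))
    flags: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    acc = (tp + tn) / y.size
    if np.isfinite(sens) and np.isfinite(spec):
        lr_plus = sens / (1 - spec) if spec < 1 else float("inf")
        if spec == 1:
            flags.append("lr_plus_infinite")
        lr_minus = (1 - sens) / spec if spec > 0 else float("nan")
        bal = (sens + spec) / 2
    else:
        lr_plus = lr_minus = bal = float("nan")
    f1 = (
        2 * ppv * sens / (ppv + sens)
        if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
        else float("nan")
    )
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
        "lr_plus": lr_plus,
        "lr_minus": lr_minus,
        "ppv": ppv,
        "npv": npv,
        "balanced_accuracy": bal,
        "flags": flags,
    }


def metrics_from_rates(
    sensitivity: float, specificity: float, ppv: float | None = None
) -> dict:
    """Derived panel metrics from given sensitivity/specificity (fractions).

    Mirrors the arithmetic used when a published table reports the primary
    rates and the likelihood ratios / balanced accuracy / F1 are derived
    from them.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must be fractions in [0, 1]")
    out = {
        "lr_plus": sensitivity / (1 - specificity) if specificity < 1 else float("inf"),
        "lr_minus": (1 - sensitivity) / specificity if specificity > 0 else float("nan"),
        "balanced_accuracy": (sensitivity + specificity) / 2,
    }
    if ppv is not None:
        out["f1"] = 2 * ppv * sensitivity / (ppv + sensitivity)
    return out


def brier_score(probabilities, labels) -> float:
    """Mean squared difference between probabilities and binary outcomes."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if p.shape != y.shape or p.size == 0:
        raise ValueError("probabilities and labels must be non-empty and aligned")
    return float(np.mean((p - y) ** 2))


def calibration_curve(probabilities, labels, bins: int = 10) -> pd.DataFrame:
    """Equal-width probability bins on [0, 1] with observed positive rates.

    Empty bins are kept in the table with NaN summaries and count 0 (flagged
    by the ``empty`` column, never silently dropped).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        sel = idx == b
        n = int(np.sum(sel))
        rows.append(
            {
                "bin": b,
                "lower": edges[b],
                "upper": edges[b + 1],
                "mean_predicted": float(np.mean(p[sel])) if n else float("nan"),
                "observed_fraction": float(np.mean(y[sel])) if n else float("nan"),
                "count": n,
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows)


def anova_oneway(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    Degenerate all-identical input returns (0.0, 1.0).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    f, p = f_oneway(*arrs)
    return float(f), float(p)


def _evaluate_one(model: "TrainedModel", test_table: pd.DataFrame) -> dict:
    from .modeling import apply_model

    probs, classes = apply_model(model, test_table)
    y = test_table["label"].to_numpy(dtype=int)
    roc = auroc(probs, y)
    panel = confusion_metrics(classes, y)
    calib = calibration_curve(probs, y, bins=10)
    return {
        "kind": model.kind,
        "threshold": model.threshold,
        "auroc": roc.value,
        "auroc_ci": [roc.ci_low, roc.ci_high],
        "auroc_ci_method": "hanley-mcneil",
        "brier": brier_score(probs, y),
        "panel": {k: v for k, v in panel.items() if k != "flags"},
        "panel_flags": panel["flags"],
        "calibration": calib.to_dict(orient="records"),
        "n_test": int(len(y)),
        "features": list(model.selection.final_features),
    }


def report(
    models: Mapping[str, "TrainedModel"], test_table: pd.DataFrame, out: str | Path
) -> dict:
    """Evaluate each model on an independent test table and serialize.

    Writes ``report.json`` plus per-model calibration and confusion CSVs
    under ``out``.  Re-running with identical inputs is byte-identical (no
    timestamps, sorted keys).
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    results = {kind: _evaluate_one(m, test_table) for kind, m in sorted(models.items())}
    payload = {"schema_version": 1, "models": results}
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    for kind, res in results.items():
        pd.DataFrame(res["calibration"]).to_csv(out / f"calibration_{kind}.csv", index=False)
        pd.DataFrame([res["panel"]]).to_csv(out / f"confusion_{kind}.csv", index=False)
    return payload
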