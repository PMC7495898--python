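"""Classification metrics, the E_c selection criterion, F-score feature
ranking, and the repeated stratified k-fold cross-validation engine.

The six confusion-matrix metrics are the standard closed forms

    SEN = TP/(TP+FN)            SPE = TN/(TN+FP)
    PRE = TP/(TP+FP)            ACC = (TP+TN)/(TP+TN+FP+FN)
    F1  = 2*SEN*PRE/(SEN+PRE)   MCC = (TP*TN - FP*FN)/sqrt(prod of margins)

with a zero-denominator sentinel of 0 (flagged, never an exception).  AUC is
the Mann-Whitney statistic.  The feature-selection criterion E_c averages,
over cross-validation repeats and folds, the sum ACC + SEN + SPE + MCC +
AUC, so a perfect classifier scores 5 and the criterion is bounded in
[-1, 5].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "confusion_metrics",
    "auc_score",
    "ec_score",
    "fscore_ranking",
    "repeated_kfold_cv",
    "cv_summary_table",
    "EC_METRICS",
]

EC_METRICS = ("ACC", "SEN", "SPE", "MCC", "AUC")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must total at least 1")


def _safe_div(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_metrics(counts: ConfusionCounts) -> Dict[str, float]:
    """The six confusion-matrix metrics; zero denominators yield 0 and are
    recorded in the returned ``zero_denominator`` list."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    flags: list = []
    sen = _safe_div(tp, tp + fn, flags, "SEN")
    spe = _safe_div(tn, tn + fp, flags, "SPE")
    pre = _safe_div(tp, tp + fp, flags, "PRE")
    acc = (tp + tn) / (tp + tn + fp + fn)
    f1 = _safe_div(2 * sen * pre, sen + pre, flags, "F1")
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, flags, "MCC")
    return {
        "ACC": acc, "SEN": sen, "SPE": spe, "PRE": pre,
        "F1": f1, "MCC": mcc, "zero_denominator": flags,
    }


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve as the Mann-Whitney statistic:
    (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def ec_score(per_repeat_folds: Sequence[Sequence[Dict[str, float]]]) -> float:
    """Selection criterion E_c.

    ``per_repeat_folds[r][f]`` holds the fold-f metrics of repeat r (must
    contain ACC, SEN, SPE, MCC, AUC).  E_c = mean over repeats of the mean
    over folds of the five-metric sum; bounded in [-1, 5].
    """
    if not per_repeat_folds:
        raise ValueError("no cross-validation results supplied")
    repeat_means = []
    for folds in per_repeat_folds:
        if not folds:
            raise ValueError("a repeat contains no folds")
        sums = [sum(f[m] for m in EC_METRICS) for f in folds]
        repeat_means.append(float(np.mean(sums)))
    return float(np.mean(repeat_means))


def fscore_ranking(
    table: pd.DataFrame,
    label_col: str = "label",
) -> pd.DataFrame:
    """Discrimination F-score per feature, ranked descending.

    F = ((mu_pos - mu)^2 + (mu_neg - mu)^2) / (var_pos + var_neg) with
    class sample variances (ddof=1); features with zero variance in both
    classes score 0 and are flagged.  Ties break by column name.
    """
    if label_col not in table.columns:
        raise ValueError(f"label column {label_col!r} missing")
    y = table[label_col].to_numpy()
    feats = [c for c in table.columns if c != label_col]
    if not feats:
        raise ValueError("table has no feature columns")
    rows = []
    for c in feats:
        x = table[c].to_numpy(dtype=float)
        xp, xn = x[y == 1], x[y == 0]
        mu, mup, mun = x.mean(), xp.mean(), xn.mean()
        den = (xp.var(ddof=1) if len(xp) > 1 else 0.0) + (
            xn.var(ddof=1) if len(xn) > 1 else 0.0)
        if den == 0.0:
            rows.append((c, 0.0, True))
        else:
            rows.append((c, ((mup - mu) ** 2 + (mun - mu) ** 2) / den, False))
    out = pd.DataFrame(rows, columns=["feature", "fscore", "zero_variance"])
    out = out.sort_values(["fscore", "feature"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    out.index += 1
    out.index.name = "rank"
    return out


@dataclass
class CVResult:
    repeat: int
    fold: int
    metrics: Dict[str, float]
    test_index: np.ndarray
    seed: int


def _metrics_from_predictions(
    y_true: np.ndarray, proba: np.ndarray, threshold: float = 0.5
) -> Dict[str, float]:
    pred = (proba >= threshold).astype(int)
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (y_true == 1)).sum()),
        fp=int(((pred == 1) & (y_true == 0)).sum()),
        tn=int(((pred == 0) & (y_true == 0)).sum()),
        fn=int(((pred == 0) & (y_true == 1)).sum()),
    )
    m = confusion_metrics(counts)
    m.pop("zero_denominator")
    m["AUC"] = auc_score(proba, y_true) if len(set(y_true)) == 2 else 0.0
    return m


def repeated_kfold_cv(
    table: pd.DataFrame,
    model_factory: Callable[[], object],
    *,
    label_col: str = "label",
    feature_cols: Optional[Sequence[str]] = None,
    k: int = 10,
    repeats: int = 1,
    seed: int = 0,
    external_table: Optional[pd.DataFrame] = None,
) -> List[CVResult]:
    """Repeated stratified k-fold cross-validation.

    Each repeat reshuffles with ``seed + repeat``; within a fold the model
    from ``model_factory()`` is fit on the training rows and scored on the
    held-out fold.  When ``external_table`` is given, its rows are appended
    to every fold's test set (the combined-test selection protocol).
    Returns one :class:`CVResult` per (repeat, fold).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    feats = list(feature_cols) if feature_cols is not None else [
        c for c in table.columns if c != label_col]
    X = table[feats].to_numpy(dtype=float)
    y = table[label_col].to_numpy(dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} samples < k={k}; "
            "use a smaller k"
        )
    X_ext = y_ext = None
    if external_table is not None:
        X_ext = external_table[feats].to_numpy(dtype=float)
        y_ext = external_table[label_col].to_numpy(dtype=int)

    results: List[CVResult] = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            model = model_factory()
            model.fit(X[tr], y[tr])
            X_test, y_test = X[te], y[te]
            if X_ext is not None:
                X_test = np.vstack([X_test, X_ext])
                y_test = np.concatenate([y_test, y_ext])
            proba = _predict_proba1(model, X_test)
            m = _metrics_from_predictions(y_test, proba)
            results.append(CVResult(repeat=rep, fold=fold, metrics=m,
                                    test_index=te, seed=seed + rep))
    return results


def _predict_proba1(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1]
    if hasattr(model, "decision_function"):
        z = np.asarray(model.decision_function(X), dtype=float)
        return 1.0 / (1.0 + np.exp(-z))
    return np.asarray(model.predict(X), dtype=float)


def cv_summary_table(results: List[CVResult]) -> pd.DataFrame:
    """Per-fold rows plus an 'aggregate' mean row, as a DataFrame ready for
    delimited-text serialization."""
    rows = []
    for r in results:
        row = {"repeat": r.repeat, "fold": r.fold, **r.metrics}
        rows.append(row)
    df = pd.DataFrame(rows)
    agg = df.drop(columns=["repeat", "fold"]).mean().to_dict()
    agg.update({"repeat": -1, "fold": -1})
    return pd.concat([df, pd.DataFrame([agg])], ignore_index=True)


def results_to_ec(results: List[CVResult]) -> float:
    """Group per-(repeat, fold) CV results and evaluate E_c."""
    by_rep: Dict[int, List[Dict[str, float]]] = {}
    for r in results:
        by_rep.setdefault(r.repeat, []).append(r.metrics)
    return ec_score([by_rep[rep] for rep in sorted(by_rep)])


__all__.append("results_to_ec")
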