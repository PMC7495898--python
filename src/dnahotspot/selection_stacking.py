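"""The ensemble stacking classifier (ESC), the ensemble vote classifier
(EVC), and sequential backward selection (SBS) driven by the E_c criterion.

The ESC is a two-level super learner: three gradient-boosting base
classifiers produce class-1 probabilities that feed a logistic-regression
meta-model.  Meta-features are out-of-fold probabilities from an internal
stratified 5-fold scheme (naive in-sample stacking overfits badly at the
~180-sample scale this is designed for); the base learners are refit on all
data afterwards.  The reference base-learner trio is XGBoost, LightGBM and
sklearn gradient tree boosting; a lightweight sklearn trio
(``fast_base_specs``) backs quick runs and the test suite.

SBS removes one feature per round: every leave-one-out subset of the
current set is scored by E_c under identical fold seeds (paired
comparison), and the best subset is adopted only if its E_c strictly
exceeds the current one.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .metrics_cv import repeated_kfold_cv, results_to_ec

__all__ = [
    "StackingClassifier",
    "VoteClassifier",
    "SelectionTrace",
    "SelectionRound",
    "reference_base_specs",
    "fast_base_specs",
    "fit_stacking",
    "predict_stacking",
    "fit_vote",
    "make_ec_evaluator",
    "sbs_select",
    "save_model",
    "load_model",
    "ARCHIVE_VERSION",
]

ARCHIVE_VERSION = 1


def reference_base_specs(seed: int = 0) -> List[Tuple[str, BaseEstimator]]:
    """Three distinct gradient-boosting variants (XGBoost, LightGBM, sklearn
    gradient tree boosting), defaults untouched apart from determinism."""
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    return [
        ("xgboost", XGBClassifier(
            n_estimators=100, random_state=seed, eval_metric="logloss",
            verbosity=0, use_label_encoder=False)),
        ("lightgbm", LGBMClassifier(
            n_estimators=100, random_state=seed, verbose=-1)),
        ("gtb", GradientBoostingClassifier(random_state=seed)),
    ]


def fast_base_specs(seed: int = 0) -> List[Tuple[str, BaseEstimator]]:
    """Lightweight test-double trio (boosted stumps, logistic regression,
    naive Bayes) honoring the same fit/probability contract."""
    return [
        ("ada_stumps", AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=20, random_state=seed)),
        ("logreg", LogisticRegression(max_iter=500)),
        ("gnb", GaussianNB()),
    ]


def _proba1(model, X) -> np.ndarray:
    return np.asarray(model.predict_proba(X))[:, 1]


class StackingClassifier(BaseEstimator, ClassifierMixin):
    """Two-level stacking ensemble with out-of-fold meta-features.

    Parameters
    ----------
    base_specs
        (name, estimator) pairs; each must implement fit / predict_proba.
    meta
        The level-two classifier (logistic regression by default).
    n_oof_splits
        Internal stratified folds used to generate leak-free meta-features.
    seed
        Controls the internal fold scheme and is forwarded to clones that
        expose a random_state parameter.
    """

    def __init__(self, base_specs=None, meta=None, n_oof_splits: int = 5,
                 seed: int = 0):
        self.base_specs = base_specs
        self.meta = meta
        self.n_oof_splits = n_oof_splits
        self.seed = seed

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        specs = self.base_specs or fast_base_specs(self.seed)
        self.feature_names_ = list(feature_names) if feature_names is not None else None
        skf = StratifiedKFold(n_splits=self.n_oof_splits, shuffle=True,
                              random_state=self.seed)
        oof = np.zeros((len(y), len(specs)))
        for j, (name, est) in enumerate(specs):
            for tr, te in skf.split(X, y):
                m = clone(est)
                try:
                    m.fit(X[tr], y[tr])
                except Exception as exc:
                    raise RuntimeError(f"base learner {name!r} failed to fit: {exc}")
                oof[te, j] = _proba1(m, X[te])
        self.meta_ = clone(self.meta) if self.meta is not None else LogisticRegression(max_iter=500)
        self.meta_.fit(oof, y)
        self.base_models_ = []
        for name, est in specs:
            m = clone(est)
            try:
                m.fit(X, y)
            except Exception as exc:
                raise RuntimeError(f"base learner {name!r} failed to fit: {exc}")
            self.base_models_.append((name, m))
        self.oof_meta_features_ = oof
        self.classes_ = np.array([0, 1])
        return self

    def _meta_features(self, X) -> np.ndarray:
        return np.column_stack([_proba1(m, X) for _, m in self.base_models_])

    def predict_proba(self, X) -> np.ndarray:
        X = self._bind_columns(X)
        return self.meta_.predict_proba(self._meta_features(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def _bind_columns(self, X):
        """Name-based column binding for DataFrame input: reorder to the
        training feature order, error on missing, warn on extras."""
        if isinstance(X, pd.DataFrame) and self.feature_names_ is not None:
            missing = [c for c in self.feature_names_ if c not in X.columns]
            if missing:
                raise KeyError(f"missing feature columns: {missing}")
            extra = [c for c in X.columns if c not in self.feature_names_]
            if extra:
                warnings.warn(f"ignoring extra feature columns: {extra}")
            return X[self.feature_names_].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)


class VoteClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble vote classifier: unweighted mean of the member class-1
    probabilities."""

    def __init__(self, specs=None, seed: int = 0):
        self.specs = specs
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        specs = self.specs or fast_base_specs(self.seed)
        if len(specs) < 1:
            raise ValueError("at least one member learner required")
        self.models_ = []
        for name, est in specs:
            m = clone(est)
            try:
                m.fit(X, y)
            except Exception as exc:
                raise RuntimeError(f"member learner {name!r} failed to fit: {exc}")
            self.models_.append((name, m))
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p1 = np.mean([_proba1(m, X) for _, m in self.models_], axis=0)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_stacking(
    table: pd.DataFrame,
    base_specs=None,
    meta=None,
    seed: int = 0,
    label_col: str = "label",
) -> StackingClassifier:
    """Fit the ESC on a labeled feature table (columns bound by name)."""
    feats = [c for c in table.columns if c != label_col]
    model = StackingClassifier(base_specs=base_specs, meta=meta, seed=seed)
    model.fit(table[feats].to_numpy(dtype=float),
              table[label_col].to_numpy(dtype=int), feature_names=feats)
    return model


def predict_stacking(model: StackingClassifier, rows: pd.DataFrame) -> pd.DataFrame:
    """Per-row class-1 probability and the 0.5-threshold label."""
    proba = model.predict_proba(rows)[:, 1]
    return pd.DataFrame(
        {"probability": proba, "label": (proba >= 0.5).astype(int)},
        index=rows.index)


def fit_vote(
    table: pd.DataFrame,
    specs=None,
    seed: int = 0,
    label_col: str = "label",
) -> VoteClassifier:
    feats = [c for c in table.columns if c != label_col]
    model = VoteClassifier(specs=specs, seed=seed)
    model.fit(table[feats].to_numpy(dtype=float),
              table[label_col].to_numpy(dtype=int))
    return model


@dataclass
class SelectionRound:
    round: int
    current_ec: float
    candidates: List[Tuple[str, float]]  # (removed feature, E_c)
    removed: Optional[str]
    adopted_ec: Optional[float]


@dataclass
class SelectionTrace:
    rounds: List[SelectionRound] = field(default_factory=list)
    stop_reason: str = ""
    initial_features: List[str] = field(default_factory=list)
    final_features: List[str] = field(default_factory=list)

    def to_text(self, sep: str = "\t") -> str:
        lines = [f"round{sep}removed_feature{sep}ec"]
        for r in self.rounds:
            lines.append(f"{r.round}{sep}{r.removed or '-'}{sep}"
                         f"{r.adopted_ec if r.adopted_ec is not None else r.current_ec:.6f}")
        return "\n".join(lines) + "\n"


def make_ec_evaluator(
    table: pd.DataFrame,
    model_factory: Callable[[], object],
    *,
    label_col: str = "label",
    k: int = 10,
    repeats: int = 3,
    external_table: Optional[pd.DataFrame] = None,
) -> Callable[[Sequence[str], int], float]:
    """E_c evaluator over feature subsets: repeated stratified k-fold CV of
    ``model_factory()`` restricted to the subset, optionally scoring the
    combined (fold + external) test set each fold."""

    def evaluate(subset: Sequence[str], seed: int) -> float:
        results = repeated_kfold_cv(
            table, model_factory, label_col=label_col,
            feature_cols=list(subset), k=k, repeats=repeats, seed=seed,
            external_table=external_table)
        return results_to_ec(results)

    return evaluate


def sbs_select(
    features: Sequence[str],
    evaluator: Callable[[Sequence[str], int], float],
    seed: int = 0,
    min_features: int = 1,
) -> Tuple[List[str], SelectionTrace]:
    """Sequential backward selection driven by E_c.

    Per round all leave-one-out subsets of the current set are evaluated
    with the same fold seed (paired comparison); the best is adopted only on
    strict E_c improvement, otherwise selection stops.  An evaluator failure
    on one subset skips that subset; if every subset of a round fails the
    selection aborts.
    """
    current = list(features)
    if len(current) < 2:
        raise ValueError("need at least 2 features to select from")
    trace = SelectionTrace(initial_features=list(current))
    current_ec = evaluator(current, seed)
    round_no = 0
    while len(current) > min_features:
        round_no += 1
        round_seed = seed + 1000 * round_no
        candidates: List[Tuple[str, float]] = []
        failures = 0
        for f in current:
            subset = [c for c in current if c != f]
            try:
                ec = evaluator(subset, round_seed)
            except Exception as exc:
                warnings.warn(f"evaluator failed for subset without {f!r}: {exc}")
                failures += 1
                continue
            candidates.append((f, ec))
        if not candidates:
            if failures:
                raise RuntimeError("all candidate subsets failed evaluation")
            break
        best_feature, best_ec = max(candidates, key=lambda t: (t[1], t[0]))
        if best_ec > current_ec:
            current = [c for c in current if c != best_feature]
            trace.rounds.append(SelectionRound(
                round=round_no, current_ec=current_ec, candidates=candidates,
                removed=best_feature, adopted_ec=best_ec))
            current_ec = best_ec
        else:
            trace.rounds.append(SelectionRound(
                round=round_no, current_ec=current_ec, candidates=candidates,
                removed=None, adopted_ec=None))
            trace.stop_reason = "no strict E_c improvement"
            break
    else:
        trace.stop_reason = f"reached minimum feature count {min_features}"
    if not trace.stop_reason:
        trace.stop_reason = "no candidates"
    trace.final_features = list(current)
    return current, trace


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(repr(sorted(payload.items())).encode()).hexdigest()[:16]


def save_model(model, path: str, *, seed: int = 0, config: Optional[dict] = None) -> None:
    """Persist a fitted model with version, feature names, seed and a config
    hash; loading refuses incompatible archive versions."""
    payload = {
        "version": ARCHIVE_VERSION,
        "model": model,
        "feature_names": getattr(model, "feature_names_", None),
        "seed": seed,
        "config_hash": _config_hash(config or {}),
    }
    joblib.dump(payload, path)


def load_model(path: str):
    payload = joblib.load(path)
    if payload.get("version") != ARCHIVE_VERSION:
        raise ValueError(
            f"model archive version {payload.get('version')} is not "
            f"compatible with this package (expected {ARCHIVE_VERSION})")
    return payload["model"]
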