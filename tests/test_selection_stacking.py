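import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression

from dnahotspot.metrics_cv import repeated_kfold_cv
from dnahotspot.selection_stacking import (
    StackingClassifier,
    VoteClassifier,
    fast_base_specs,
    fit_stacking,
    fit_vote,
    load_model,
    make_ec_evaluator,
    predict_stacking,
    save_model,
    sbs_select,
)


def _fit_table(table, seed=0):
    return fit_stacking(table, base_specs=fast_base_specs(seed), seed=seed)


# --------------------------------------------------------------------------
# stacking

def test_separable_table_high_cv_auc(separable_table):
    res = repeated_kfold_cv(
        separable_table,
        lambda: StackingClassifier(base_specs=fast_base_specs(0), seed=0),
        k=10, repeats=1, seed=0)
    auc = np.mean([r.metrics["AUC"] for r in res])
    assert auc >= 0.95


def test_meta_feature_matrix_shape(separable_table):
    model = _fit_table(separable_table)
    assert model.oof_meta_features_.shape == (len(separable_table), 3)


def test_same_seed_identical_predictions(separable_table):
    feats = separable_table.drop(columns=["label"])
    p1 = _fit_table(separable_table, seed=3).predict_proba(feats)[:, 1]
    p2 = _fit_table(separable_table, seed=3).predict_proba(feats)[:, 1]
    np.testing.assert_array_equal(p1, p2)


def test_training_rows_mostly_recovered(separable_table):
    model = _fit_table(separable_table)
    pred = predict_stacking(model, separable_table.drop(columns=["label"]))
    agree = (pred["label"].to_numpy()
             == separable_table["label"].to_numpy()).mean()
    assert agree >= 0.95


def test_probability_bounds_on_random_inputs(separable_table):
    model = _fit_table(separable_table)
    rng = np.random.default_rng(0)
    X = rng.normal(scale=10, size=(10_000, separable_table.shape[1] - 1))
    p = model.predict_proba(X)[:, 1]
    assert ((p >= 0) & (p <= 1)).all()


def test_column_permutation_does_not_change_predictions(separable_table):
    model = _fit_table(separable_table)
    feats = separable_table.drop(columns=["label"])
    shuffled = feats[list(reversed(feats.columns))]
    p1 = model.predict_proba(feats)[:, 1]
    p2 = model.predict_proba(shuffled)[:, 1]
    np.testing.assert_array_equal(p1, p2)


def test_missing_feature_column_named(separable_table):
    model = _fit_table(separable_table)
    feats = separable_table.drop(columns=["label", "inf_0"])
    with pytest.raises(KeyError, match="inf_0"):
        model.predict_proba(feats)


def test_extra_columns_ignored_with_warning(separable_table):
    model = _fit_table(separable_table)
    feats = separable_table.drop(columns=["label"]).copy()
    feats["bogus"] = 1.0
    with pytest.warns(UserWarning, match="bogus"):
        model.predict_proba(feats)


def test_single_class_rejected(separable_table):
    df = separable_table.copy()
    df["label"] = 1
    with pytest.raises(ValueError, match="class"):
        fit_stacking(df, base_specs=fast_base_specs(0))


def test_failing_base_learner_named(separable_table):
    class Broken:
        def get_params(self, deep=True):
            return {}

        def set_params(self, **kw):
            return self

        def fit(self, X, y):
            raise RuntimeError("boom")

    specs = [("broken", Broken())] + fast_base_specs(0)[:2]
    with pytest.raises(RuntimeError, match="broken"):
        fit_stacking(separable_table, base_specs=specs)


def test_stacking_three_identical_bases_tracks_single_learner(separable_table):
    """Three copies of one base learner through the meta-model should stay
    rank-consistent with that learner used alone."""
    single = LogisticRegression(max_iter=500)
    feats = separable_table.drop(columns=["label"])
    y = separable_table["label"].to_numpy()
    single.fit(feats.to_numpy(), y)
    p_single = single.predict_proba(feats.to_numpy())[:, 1]

    specs = [(f"lr{i}", LogisticRegression(max_iter=500)) for i in range(3)]
    stacked = fit_stacking(separable_table, base_specs=specs, seed=0)
    p_stack = stacked.predict_proba(feats)[:, 1]
    rho, _ = spearmanr(p_single, p_stack)
    assert rho >= 0.99


# --------------------------------------------------------------------------
# voting

def test_vote_is_mean_probability():
    class Fixed:
        def __init__(self, p):
            self.p = p

        def get_params(self, deep=True):
            return {"p": self.p}

        def set_params(self, **kw):
            return self

        def fit(self, X, y):
            return self

        def predict_proba(self, X):
            out = np.full(len(X), self.p)
            return np.column_stack([1 - out, out])

    df = pd.DataFrame({"x": [0.0, 1.0], "label": [0, 1]})
    model = fit_vote(df, specs=[("a", Fixed(0.8)), ("b", Fixed(0.4))])
    np.testing.assert_allclose(model.predict_proba([[0.0]])[:, 1], 0.6)

    solo = fit_vote(df, specs=[("a", Fixed(0.8))])
    np.testing.assert_allclose(solo.predict_proba([[0.0]])[:, 1], 0.8)


def test_vote_separable_cv_auc(separable_table):
    res = repeated_kfold_cv(
        separable_table,
        lambda: VoteClassifier(specs=fast_base_specs(0), seed=0),
        k=10, repeats=1, seed=0)
    assert np.mean([r.metrics["AUC"] for r in res]) >= 0.95


# --------------------------------------------------------------------------
# SBS

def test_first_round_evaluates_all_leave_one_out_subsets():
    seen = []

    def evaluator(subset, seed):
        seen.append(tuple(subset))
        return 1.0  # flat landscape -> stop after round 1

    feats = [f"f{i}" for i in range(7)]
    final, trace = sbs_select(feats, evaluator, seed=0)
    round1 = [s for s in seen if len(s) == 6]
    assert len(round1) == 7
    assert final == feats
    assert trace.stop_reason == "no strict E_c improvement"


def test_stop_when_removal_always_hurts():
    def evaluator(subset, seed):
        return float(len(subset))  # every removal lowers E_c

    final, trace = sbs_select(["a", "b"], evaluator, seed=0)
    assert final == ["a", "b"]
    assert len(trace.rounds) == 1
    assert len(trace.rounds[0].candidates) == 2


def test_adopted_ec_sequence_strictly_increases():
    def evaluator(subset, seed):
        # noise features hurt: E_c rises as they are removed
        return 5.0 - 0.5 * sum(1 for f in subset if f.startswith("noise"))

    feats = ["inf_0", "noise_0", "noise_1", "noise_2"]
    final, trace = sbs_select(feats, evaluator, seed=0)
    assert final == ["inf_0"] or set(final) == {"inf_0"}
    adopted = [r.adopted_ec for r in trace.rounds if r.adopted_ec is not None]
    assert all(b > a for a, b in zip(adopted, adopted[1:]))
    assert adopted[-1] >= evaluator(feats, 0)


def test_failed_subsets_skipped():
    def evaluator(subset, seed):
        if "poison" not in subset:
            raise RuntimeError("cannot evaluate without poison")
        return 1.0

    with pytest.warns(UserWarning, match="failed"):
        final, trace = sbs_select(["poison", "a", "b"], evaluator, seed=0)
    assert "poison" in final


def test_sbs_requires_two_features():
    with pytest.raises(ValueError):
        sbs_select(["only"], lambda s, r: 1.0)


def test_evaluator_pairs_folds_within_round(separable_table):
    """Candidates within one round see identical fold seeds."""
    seeds_seen = []

    ev = make_ec_evaluator(separable_table, LogisticRegression, repeats=1, k=5)

    def spy(subset, seed):
        seeds_seen.append(seed)
        return ev(subset, seed)

    sbs_select([c for c in separable_table.columns if c != "label"][:3],
               spy, seed=42)
    by_round = {}
    # initial eval uses seed 42; each round r uses 42 + 1000 r for all cands
    assert seeds_seen[0] == 42
    assert len(set(seeds_seen[1:4])) == 1


# --------------------------------------------------------------------------
# persistence

def test_model_archive_round_trip(tmp_path, separable_table):
    model = _fit_table(separable_table)
    path = tmp_path / "model.joblib"
    save_model(model, path, seed=0, config={"k": 10})
    again = load_model(path)
    feats = separable_table.drop(columns=["label"])
    np.testing.assert_array_equal(model.predict_proba(feats),
                                  again.predict_proba(feats))


def test_incompatible_archive_version_refused(tmp_path, separable_table):
    import joblib

    model = _fit_table(separable_table)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    payload = joblib.load(path)
    payload["version"] = 999
    joblib.dump(payload, path)
    with pytest.raises(ValueError, match="version"):
        load_model(path)
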