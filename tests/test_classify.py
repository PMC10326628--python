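import warnings

import numpy as np
import pandas as pd
import pytest

from ramanomics.classify import (
    ClassifierSpec, SpecificationError, StratificationError, aggregate_by_sample,
    encode_labels, grid_points, grid_search_cv, group_folds, make_split, predict,
)
from ramanomics.cnn import Conv1DClassifier
from conftest import separable_scores

warnings.filterwarnings("ignore", category=FutureWarning)  # SVC probability deprecation


def toy_manifest(n_samples=100, reps=5):
    rows = []
    for i in range(n_samples):
        label = "pregnancy" if i % 2 == 0 else "non_pregnancy"
        for r in range(1, reps + 1):
            rows.append({"spectrum_file": f"S{i}_r{r}.csv", "sample_id": f"S{i}",
                         "replicate": r, "platform": "p532", "label": label})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- splitting

def test_balanced_hundred_samples_split_80_20():
    plan = make_split(toy_manifest(100), ratio=0.8, seed=3)
    assert len(plan.train_samples) == 80
    assert len(plan.test_samples) == 20


def test_split_deterministic_given_seed():
    a = make_split(toy_manifest(40), seed=11)
    b = make_split(toy_manifest(40), seed=11)
    assert a == b
    c = make_split(toy_manifest(40), seed=12)
    assert c != a


def test_split_stratified_within_one_sample():
    for seed in range(5):
        plan = make_split(toy_manifest(30), ratio=0.8, seed=seed)
        man = toy_manifest(30).drop_duplicates("sample_id").set_index("sample_id")
        for part in (plan.train_samples, plan.test_samples):
            labels = man.loc[list(part), "label"]
            assert abs((labels == "pregnancy").sum() - (labels == "non_pregnancy").sum()) <= 1


def test_no_replicate_straddles_partition():
    """Every replicate of a 10-sample toy manifest lands on one side only."""
    manifest = toy_manifest(10, reps=5)
    plan = make_split(manifest, ratio=0.8, seed=0)
    mask = plan.mask(manifest["sample_id"])
    for _, sub in pd.DataFrame({"sample_id": manifest["sample_id"], "train": mask}).groupby("sample_id"):
        assert sub["train"].nunique() == 1
    assert set(plan.train_samples) | set(plan.test_samples) == set(manifest["sample_id"])


def test_missing_label_raises_stratification_error():
    manifest = toy_manifest(10)
    manifest["label"] = "pregnancy"
    with pytest.raises(StratificationError):
        make_split(manifest)


# ---------------------------------------------------------------- CV folds

def test_group_folds_never_split_a_sample():
    X, y, groups = separable_scores(n_samples=20, replicates=3)
    folds = group_folds(encode_labels(y), groups, 4)
    assert len(folds) == 4
    for tr, va in folds:
        assert set(groups[tr]).isdisjoint(set(groups[va]))
    # every group validated exactly once
    seen = [g for _, va in folds for g in set(groups[va])]
    assert sorted(seen) == sorted(set(groups))


def test_degenerate_single_class_folds_rejected():
    y = np.array([0] * 6 + [1] * 2)
    groups = np.array(["a", "a", "b", "b", "c", "c", "d", "d"])
    with pytest.raises(SpecificationError):
        group_folds(y, groups, 4)  # one fold isolates all class-1 samples


# ---------------------------------------------------------------- grids

def test_grid_points_listed_order():
    pts = list(grid_points({"a": [1, 2], "b": ["x", "y"]}))
    assert pts[0] == {"a": 1, "b": "x"}
    assert pts[-1] == {"a": 2, "b": "y"}
    assert len(pts) == 4


def test_spec_validation():
    with pytest.raises(SpecificationError):
        ClassifierSpec(algorithm="nope")
    with pytest.raises(SpecificationError):
        ClassifierSpec(algorithm="svm", grid={"C": []})
    with pytest.raises(SpecificationError):
        ClassifierSpec(algorithm="svm", cv_folds=1)


def test_single_point_grid_equivalent_to_plain_fit():
    X, y, groups = separable_scores(seed=1)
    spec = ClassifierSpec(algorithm="svm", grid={"kernel": ["linear"], "C": [1.0]},
                          cv_folds=3, seed=0)
    model = grid_search_cv(spec, X, y, groups)
    assert model.best_params == {"kernel": "linear", "C": 1.0}
    assert 0.0 <= model.cv_accuracy <= 1.0


@pytest.mark.parametrize("algo,grid,fixed", [
    ("svm", {"kernel": ["linear"], "C": [1.0]}, {}),
    ("rf", {"n_estimators": [100]}, {}),
    ("xgboost", {"n_estimators": [100], "max_depth": [3]}, {}),
    ("cnn1d", {"n_conv_layers": [1], "n_kernels": [8]}, {"epochs": 40}),
])
def test_separable_scores_high_cv_accuracy(algo, grid, fixed):
    X, y, groups = separable_scores(seed=2)
    spec = ClassifierSpec(algorithm=algo, grid=grid, cv_folds=3, seed=0,
                          fixed_params=fixed)
    model = grid_search_cv(spec, X, y, groups)
    assert model.cv_accuracy >= 0.95


def test_permuted_labels_give_chance_cv_accuracy():
    """Label permutation destroys the signal: CV accuracy ~ 0.5."""
    accs = []
    for rep in range(10):
        X, y, groups = separable_scores(n_samples=40, replicates=2, seed=rep)
        rng = np.random.default_rng(1000 + rep)
        uniq = np.unique(groups)
        perm_labels = dict(zip(uniq, rng.permutation(
            [y[groups == g][0] for g in uniq])))
        y_perm = np.array([perm_labels[g] for g in groups], dtype=object)
        spec = ClassifierSpec(algorithm="svm", grid={"kernel": ["linear"], "C": [1.0]},
                              cv_folds=3, seed=0)
        accs.append(grid_search_cv(spec, X, y_perm, groups).cv_accuracy)
    mean_acc = np.mean(accs)
    # CV accuracy under a label permutation is chance-level at best; at
    # small n it is systematically a little BELOW 0.5 (each training
    # fold's majority class is the validation fold's minority), so the
    # one-sided check against spurious signal is the meaningful one.
    n_effective = 40 * len(accs)  # independent units are samples, not spectra
    assert mean_acc < 0.5 + 3 * np.sqrt(0.25 / n_effective)
    assert mean_acc > 0.3


# ---------------------------------------------------------------- predict

def test_predictions_are_probabilities_and_deterministic():
    X, y, groups = separable_scores(seed=4)
    spec = ClassifierSpec(algorithm="rf", grid={"n_estimators": [50]}, cv_folds=3, seed=0)
    model = grid_search_cv(spec, X, y, groups)
    preds = predict(model, X)
    np.testing.assert_allclose(preds["p_pregnancy"] + preds["p_non_pregnancy"], 1.0,
                               atol=1e-9)
    dup = predict(model, np.vstack([X[0], X[0]]))
    assert dup.iloc[0].equals(dup.iloc[1])
    assert np.mean(preds["predicted"].to_numpy() == y) >= 0.95


def test_tie_probability_resolves_to_non_pregnancy():
    class Half:
        def predict_proba(self, X):
            return np.full((len(X), 2), 0.5)
    from ramanomics.classify import TrainedModel
    model = TrainedModel(spec=None, estimator=Half(), best_params={}, cv_accuracy=0.5)
    preds = predict(model, np.zeros((3, 2)))
    assert (preds["predicted"] == "non_pregnancy").all()


def test_majority_vote_per_sample():
    preds = pd.DataFrame({"predicted": ["pregnancy", "pregnancy", "non_pregnancy",
                                        "non_pregnancy", "pregnancy",
                                        "non_pregnancy", "pregnancy"]})
    sample_ids = ["A", "A", "A", "B", "B", "B", "B"]
    voted = aggregate_by_sample(preds, sample_ids).set_index("sample_id")
    assert voted.loc["A", "predicted"] == "pregnancy"      # 2 of 3
    assert voted.loc["B", "predicted"] == "non_pregnancy"  # 2-2 tie -> non_pregnancy


# ---------------------------------------------------------------- CNN

def test_cnn_gradients_match_finite_differences():
    net = Conv1DClassifier(n_conv_layers=1, n_kernels=3, kernel_width=3,
                           dense_units=5, seed=1)
    rng = np.random.default_rng(2)
    X = rng.normal(size=(6, 12))
    y = np.array([0, 1, 0, 1, 1, 0])
    net.mu_, net.sd_ = np.zeros(12), np.ones(12)
    params = net._init_weights(12, rng)
    proba, cache = net._forward(X, params)
    grads = net._backward(X, np.eye(2)[y], proba, cache, params)

    def loss(p):
        out, _ = net._forward(X, p)
        return -np.mean(np.log(np.clip(out[np.arange(6), y], 1e-12, 1.0)))

    eps = 1e-6
    for key, arr in params.items():
        flat = arr.ravel()
        for idx in (0, flat.size // 2, flat.size - 1):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss(params)
            flat[idx] = orig - eps
            lm = loss(params)
            flat[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[key].ravel()[idx]
            assert analytic == pytest.approx(numeric, abs=1e-6, rel=1e-4), key


def test_cnn_deterministic_given_seed():
    X, y, _ = separable_scores(n_samples=20, replicates=2, seed=6)
    yc = encode_labels(y)
    a = Conv1DClassifier(n_conv_layers=1, n_kernels=4, epochs=10, seed=3).fit(X, yc)
    b = Conv1DClassifier(n_conv_layers=1, n_kernels=4, epochs=10, seed=3).fit(X, yc)
    np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))


def test_cnn_sklearn_protocol():
    net = Conv1DClassifier()
    params = net.get_params()
    assert params["n_kernels"] == 16
    net.set_params(n_kernels=8)
    assert net.n_kernels == 8
    with pytest.raises(ValueError):
        net.set_params(bogus=1)
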