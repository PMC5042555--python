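import math

import numpy as np
import pytest

from litclf import (
    FeatureVector,
    LinearClassifier,
    LinearClassifierResults,
    MultinomialNaiveBayes,
    OneVsRestClassifier,
    TrainConfig,
    generate_blobs,
    load_model,
    save_model,
    sigmoid,
)
from litclf.models import train_naive_bayes


def blob_problem(seed=5, n=50, means=((-2.0, 0.0), (2.0, 0.0)), sigma=0.3):
    X, y01 = generate_blobs(n, means, sigma, seed)
    y = np.where(y01 == 1, 1.0, -1.0)
    return X, y


# --- naive Bayes ----------------------------------------------------------

def toy_vectors():
    # 2 classes, 3 terms, TF-IDF-like non-negative values
    rows = [
        ("breast", {0: 2.0, 1: 0.5}),
        ("breast", {0: 1.0, 2: 0.2}),
        ("lung", {1: 3.0}),
        ("lung", {1: 1.5, 2: 1.0}),
    ]
    return [FeatureVector(3, e, label=lab) for lab, e in rows]


def brute_force_nb(vectors, probe, smoothing=1.0):
    """Independent enumeration of the smoothed joint log-likelihoods."""
    classes = sorted({v.label for v in vectors})
    d = vectors[0].dimension
    joint = {}
    for c in classes:
        members = [v for v in vectors if v.label == c]
        prior = math.log(len(members) / len(vectors))
        totals = [
            sum(v.entries.get(t, 0.0) for v in members) + smoothing
            for t in range(d)
        ]
        denom = sum(totals)
        ll = [math.log(tot) - math.log(denom) for tot in totals]
        joint[c] = prior + sum(
            probe.entries.get(t, 0.0) * ll[t] for t in range(d)
        )
    return joint


def test_nb_priors_from_class_proportions():
    res = train_naive_bayes(toy_vectors())
    assert res.log_priors["breast"] == pytest.approx(math.log(0.5))
    assert res.log_priors["lung"] == pytest.approx(math.log(0.5))


def test_nb_smoothed_likelihoods_positive():
    res = train_naive_bayes(toy_vectors())
    # term 0 never occurs in class lung, yet its likelihood is > 0
    assert np.all(np.isfinite(res.log_likelihood["lung"]))
    assert np.exp(res.log_likelihood["lung"]).sum() == pytest.approx(1.0)
    assert np.exp(res.log_likelihood["breast"]).sum() == pytest.approx(1.0)


@pytest.mark.parametrize(
    "probe",
    [
        FeatureVector(3, {0: 1.0}),
        FeatureVector(3, {1: 2.0, 2: 0.5}),
        FeatureVector(3, {2: 4.0}),
        FeatureVector(3, {}),
    ],
)
def test_nb_matches_enumeration_oracle(probe):
    vectors = toy_vectors()
    res = train_naive_bayes(vectors)
    expected = brute_force_nb(vectors, probe)
    got = res.joint_log_likelihood(probe)
    for c in expected:
        assert got[c] == pytest.approx(expected[c], abs=1e-12)
    assert res.predict(probe)[0] == max(expected, key=expected.get)


def test_nb_posteriors_normalized():
    res = train_naive_bayes(toy_vectors())
    _, post = res.predict(FeatureVector(3, {0: 1.0, 1: 1.0}))
    assert sum(math.exp(v) for v in post.values()) == pytest.approx(1.0, abs=1e-12)


def test_nb_all_zero_vector_falls_back_to_priors():
    vectors = toy_vectors() + [FeatureVector(3, {0: 0.5}, label="breast")]
    res = train_naive_bayes(vectors)  # priors now 3/5 vs 2/5
    label, _ = res.predict(FeatureVector(3, {}))
    assert label == "breast"


def test_nb_matches_sklearn_multinomial():
    sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
    rng = np.random.default_rng(0)
    X = rng.random((30, 8)) * rng.integers(0, 2, (30, 8))
    y = np.array(["a"] * 15 + ["b"] * 15)
    ours = MultinomialNaiveBayes(X, y).fit(smoothing=1.0)
    ref = sklearn_nb.MultinomialNB(alpha=1.0).fit(X, y)
    probe = rng.random((10, 8))
    got = [ours.predict(p)[0] for p in probe]
    assert got == list(ref.predict(probe))


def test_nb_dimension_mismatch():
    res = train_naive_bayes(toy_vectors())
    with pytest.raises(ValueError, match="dimension"):
        res.predict(FeatureVector(5, {0: 1.0}))


def test_nb_requires_labels():
    with pytest.raises(ValueError):
        MultinomialNaiveBayes([FeatureVector(2, {0: 1.0})], [None])


# --- linear models --------------------------------------------------------

def test_hinge_separates_blobs_perfectly():
    X, y = blob_problem()
    res = LinearClassifier(X, y, loss="hinge").fit(
        TrainConfig(reg_param=0.0, regularizer="none", seed=1)
    )
    assert res.training_accuracy() == 1.0


def test_l2_regularization_shrinks_weights():
    X, y = blob_problem()
    free = LinearClassifier(X, y, loss="hinge").fit(
        TrainConfig(reg_param=0.0, regularizer="l2", seed=1)
    )
    shrunk = LinearClassifier(X, y, loss="hinge").fit(
        TrainConfig(reg_param=10.0, regularizer="l2", seed=1)
    )
    assert np.linalg.norm(shrunk.weights) < np.linalg.norm(free.weights)


def test_logistic_objective_at_zero_is_log2():
    X, y = blob_problem()
    model = LinearClassifier(X, y, loss="logistic")
    cfg = TrainConfig(reg_param=0.0, regularizer="none")
    assert model.objective(np.zeros(2), cfg) == pytest.approx(math.log(2))


def test_objective_decreases_on_convex_toy_problem():
    X, y = blob_problem()
    res = LinearClassifier(X, y, loss="hinge").fit(
        TrainConfig(regularizer="l2", reg_param=0.01, seed=1)
    )
    path = res.objective_path
    assert path[-1] < path[0]
    # monitored monotonicity: decaying steps allow only tiny upticks
    assert all(b <= a + 0.05 for a, b in zip(path, path[1:]))


def test_seeded_training_is_bit_reproducible():
    X, y = blob_problem()
    cfg = TrainConfig(seed=42, minibatch_fraction=0.5)
    w1 = LinearClassifier(X, y, loss="logistic").fit(cfg).weights
    w2 = LinearClassifier(X, y, loss="logistic").fit(cfg).weights
    assert np.array_equal(w1, w2)


def test_single_class_rejected():
    X = np.ones((4, 2))
    with pytest.raises(ValueError, match="both classes"):
        LinearClassifier(X, [1, 1, 1, 1], loss="hinge")


def test_non_finite_features_rejected():
    X = np.array([[1.0, np.nan], [0.0, 1.0]])
    with pytest.raises(ValueError, match="non-finite"):
        LinearClassifier(X, [1, -1], loss="hinge")


def test_sigmoid_values_and_stability():
    assert sigmoid(0.0) == 0.5
    assert sigmoid(math.log(3)) == pytest.approx(0.75)
    assert sigmoid(1000.0) == pytest.approx(1.0)
    assert sigmoid(-1000.0) == pytest.approx(0.0)
    assert 0.0 <= sigmoid(-1e3) < sigmoid(1e3) <= 1.0


def _manual_results(w, loss="hinge", positive_class=1):
    X = np.array([[1.0, 0.0], [0.0, 1.0]])
    model = LinearClassifier(X, [1, -1], loss=loss, positive_class=None)
    model.positive_class = positive_class
    return LinearClassifierResults(model, np.asarray(w, float), TrainConfig(), [0.0])


def test_decision_score_inner_product():
    res = _manual_results([1.0, 2.0])
    assert res.decision_score(np.array([3.0, 0.5])) == pytest.approx(4.0)
    assert _manual_results([0.0, 0.0]).decision_score([5.0, 5.0]) == 0.0
    # orthogonal input
    assert res.decision_score([2.0, -1.0]) == pytest.approx(0.0)


def test_decision_score_dimension_mismatch():
    res = _manual_results([1.0, 2.0])
    with pytest.raises(ValueError, match="dimension"):
        res.decision_score([1.0, 2.0, 3.0])


def test_predict_binary_tie_goes_to_pivot():
    res = _manual_results([0.0, 0.0], positive_class="pos")
    label, z, prob = res.predict([1.0, 1.0])
    assert z == 0.0
    assert label != "pos"  # tie resolves to the negative/pivot class


def test_predict_binary_logistic_probability():
    res = _manual_results([2.0, 0.0], loss="logistic")
    label, z, prob = res.predict([1.0, 0.0])
    assert label == 1 and z == pytest.approx(2.0)
    assert prob == pytest.approx(sigmoid(2.0))


def test_predict_hinge_negative_side():
    res = _manual_results([1.0, 0.0])
    label, z, prob = res.predict([-0.1, 0.0])
    assert label == -1 and prob is None


def test_hinge_and_logistic_agree_given_same_weights():
    w = [0.7, -1.3]
    probes = [[1.0, 0.2], [-0.5, 0.1], [0.1, 0.9], [2.0, 1.0]]
    h = _manual_results(w, loss="hinge")
    l = _manual_results(w, loss="logistic")
    for x in probes:
        assert h.predict(x)[0] == l.predict(x)[0]


# --- one-vs-rest ----------------------------------------------------------

def test_ovr_two_class_agrees_with_binary():
    X, y01 = generate_blobs(40, ((-2.0, 0.0), (2.0, 0.0)), 0.3, seed=9)
    labels = np.where(y01 == 1, "right", "left")
    cfg = TrainConfig(seed=2)
    ovr = OneVsRestClassifier(X, labels, loss="hinge").fit(cfg)
    binary = LinearClassifier(X, labels, loss="hinge",
                              positive_class="right").fit(cfg)
    probes, _ = generate_blobs(10, ((-2.0, 0.0), (2.0, 0.0)), 0.3, seed=10)
    for x in probes:
        lab, _ = ovr.predict(x)
        blab = "right" if binary.decision_score(x) > 0 else "left"
        assert lab == blab


def test_ovr_three_separable_classes():
    X, y01 = generate_blobs(
        40, ((-4.0, 0.0), (4.0, 0.0), (0.0, 4.0)), 0.3, seed=11
    )
    labels = np.array(["a", "b", "c"])[y01]
    res = OneVsRestClassifier(X, labels, loss="hinge").fit(TrainConfig(seed=3))
    assert res.predict_many(X) == list(labels)


def test_ovr_tie_breaks_lexicographically():
    X = np.eye(2)
    res = OneVsRestClassifier(X, ["b", "a"], loss="hinge").fit(TrainConfig())
    for c in res.classes:
        res.submodels[c].weights = np.zeros(2)
    label, scores = res.predict([1.0, 1.0])
    assert set(scores.values()) == {0.0}
    assert label == "a"


def test_ovr_needs_two_classes():
    with pytest.raises(ValueError):
        OneVsRestClassifier(np.eye(2), ["a", "a"], loss="hinge")


def test_linear_agrees_with_sklearn_on_blobs():
    svm = pytest.importorskip("sklearn.svm")
    X, y = blob_problem(seed=21, sigma=0.6)
    ours = LinearClassifier(X, y, loss="hinge").fit(TrainConfig(seed=0))
    ref = svm.LinearSVC().fit(X, y)
    probes, _ = generate_blobs(25, ((-2.0, 0.0), (2.0, 0.0)), 0.6, seed=22)
    ours_pred = np.sign(ours.decision_scores(probes))
    assert (ours_pred == ref.predict(probes)).mean() >= 0.95


# --- serialization --------------------------------------------------------

def test_model_json_round_trip(tmp_path):
    X, y = blob_problem()
    res = LinearClassifier(X, y, loss="logistic").fit(TrainConfig(seed=7))
    path = tmp_path / "model.json"
    save_model(res, path, vocab_hash="abc123")
    back = load_model(path)
    assert np.array_equal(back.weights, res.weights)
    assert back.predict([1.5, 0.0])[0] == res.predict([1.5, 0.0])[0]

    nb = train_naive_bayes(toy_vectors())
    nb_path = tmp_path / "nb.json"
    save_model(nb, nb_path)
    nb_back = load_model(nb_path)
    probe = FeatureVector(3, {1: 2.0})
    assert nb_back.predict(probe)[0] == nb.predict(probe)[0]

    labels = np.where(y == 1, "b", "a")
    ovr = OneVsRestClassifier(X, labels, loss="hinge").fit(TrainConfig(seed=7))
    ovr_path = tmp_path / "ovr.json"
    save_model(ovr, ovr_path)
    ovr_back = load_model(ovr_path)
    assert ovr_back.predict([1.5, 0.0])[0] == ovr.predict([1.5, 0.0])[0]
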