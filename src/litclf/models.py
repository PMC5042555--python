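"""Linear and probabilistic text classifiers.

Three classifiers operate on the same TF-IDF feature vectors:

* a linear SVM, trained by minimizing the regularized empirical hinge loss

      f(w) = a * R(w) + (1/n) * sum_i max(0, 1 - y_i w^T x_i)

* binary logistic regression with loss log(1 + exp(-y w^T x)) and the
  logistic link f(z) = 1 / (1 + e^{-z}), z = w^T x;
* multinomial naive Bayes with Laplace smoothing, taking the TF-IDF
  values as pseudo-counts.

R(w) is none, ||w||_1 or (1/2)||w||_2^2 with trade-off parameter a >= 0.
The linear models are fitted by full-batch (optionally mini-batch)
subgradient descent with step size decaying as step_size / sqrt(t),
with the long-standing defaults of large-scale linear-classifier
tooling: 100 iterations, step size 1.0, a = 0.01, L2, batch fraction 1.0.  Multiclass problems are
reduced one-vs-rest for the linear models; naive Bayes is natively
multiclass.

The API follows the statsmodels convention: a model object is built from
data, ``fit()`` returns a results object carrying the estimates and a
``summary()`` table, and prediction hangs off the results.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp
from scipy.special import expit, logsumexp

from .features import FeatureVector, vectors_to_csr

__all__ = [
    "TrainConfig",
    "LinearClassifier",
    "LinearClassifierResults",
    "MultinomialNaiveBayes",
    "NaiveBayesResults",
    "OneVsRestClassifier",
    "OneVsRestResults",
    "sigmoid",
    "train_linear_sgd",
    "decision_score",
    "predict_binary",
    "train_naive_bayes",
    "nb_predict",
    "ovr_train",
    "ovr_predict",
    "save_model",
    "load_model",
]

_LOSSES = ("hinge", "logistic")
_REGULARIZERS = ("none", "l1", "l2")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings for the linear models (and NB smoothing).

    Defaults are the classic large-scale-linear-classifier defaults:
    100 full-batch subgradient iterations, step size 1.0 with 1/sqrt(t)
    decay, regularization parameter 0.01, Laplace smoothing 1.0.
    """

    iterations: int = 100
    step_size: float = 1.0
    reg_param: float = 0.01
    regularizer: str = "l2"
    seed: int = 0
    minibatch_fraction: float = 1.0
    smoothing: float = 1.0
    add_bias: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.reg_param < 0:
            raise ValueError("reg_param must be >= 0")
        if self.regularizer not in _REGULARIZERS:
            raise ValueError(f"regularizer must be one of {_REGULARIZERS}")
        if not (0 < self.minibatch_fraction <= 1):
            raise ValueError("minibatch_fraction must be in (0, 1]")
        if self.smoothing <= 0:
            raise ValueError("smoothing must be > 0")


def sigmoid(z: float) -> float:
    """Logistic function 1/(1+e^-z), stable for large |z|."""
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def _as_matrix(X) -> sp.csr_matrix:
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], FeatureVector):
        return vectors_to_csr(X)
    if sp.issparse(X):
        return X.tocsr()
    return sp.csr_matrix(np.atleast_2d(np.asarray(X, dtype=float)))


def _encode_binary(labels: Sequence, positive_class) -> np.ndarray:
    y = np.asarray([1.0 if lab == positive_class else -1.0 for lab in labels])
    return y


def _regularizer_value(w: np.ndarray, kind: str) -> float:
    if kind == "l1":
        return float(np.abs(w).sum())
    if kind == "l2":
        return 0.5 * float(w @ w)
    return 0.0


def _regularizer_subgradient(w: np.ndarray, kind: str) -> np.ndarray:
    if kind == "l1":
        return np.sign(w)
    if kind == "l2":
        return w
    return np.zeros_like(w)


class LinearClassifier:
    """Binary linear model (hinge or logistic loss) built from data.

    Parameters
    ----------
    X : sparse matrix, array or list of FeatureVector
        Training instances, one row per document.
    y : sequence
        Labels; either already +1/-1, or arbitrary labels together with
        ``positive_class``.
    loss : {"hinge", "logistic"}
    positive_class : label treated as +1 (required for non-numeric labels).
    """

    def __init__(self, X, y, loss: str = "hinge", positive_class=None):
        if loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}")
        self.loss = loss
        if (
            isinstance(X, (list, tuple))
            and X
            and isinstance(X[0], FeatureVector)
            and y is None
        ):
            y = [v.label for v in X]
        self.X = _as_matrix(X)
        if not np.all(np.isfinite(self.X.data)):
            raise ValueError("non-finite feature values in training data")
        labels = list(y)
        if len(labels) != self.X.shape[0]:
            raise ValueError("X and y disagree on the number of instances")
        if positive_class is None:
            uniq = set(labels)
            if uniq <= {1, -1, 1.0, -1.0}:
                self.y = np.asarray(labels, dtype=float)
                self.positive_class = 1
            else:
                raise ValueError(
                    "labels are not +1/-1; supply positive_class explicitly"
                )
        else:
            self.positive_class = positive_class
            self.y = _encode_binary(labels, positive_class)
        if len(set(self.y.tolist())) < 2:
            raise ValueError("training data must contain both classes")
        self.n, self.d = self.X.shape

    def objective(self, w: np.ndarray, config: TrainConfig) -> float:
        """f(w) = a R(w) + mean loss; exposed for convergence monitoring."""
        z = self.X @ w
        m = self.y * z
        if self.loss == "hinge":
            loss = np.maximum(0.0, 1.0 - m).mean()
        else:
            loss = np.logaddexp(0.0, -m).mean()
        return config.reg_param * _regularizer_value(w, config.regularizer) + loss

    def _loss_subgradient(self, w, X, y) -> np.ndarray:
        z = X @ w
        m = y * z
        if self.loss == "hinge":
            active = m < 1.0
            coef = np.where(active, -y, 0.0)
        else:
            coef = -y * expit(-m)
        return np.asarray(X.T @ coef).ravel() / X.shape[0]

    def fit(self, config: Optional[TrainConfig] = None) -> "LinearClassifierResults":
        """Seeded (stochastic) subgradient descent on the convex objective."""
        config = config or TrainConfig()
        X, y = self.X, self.y
        if config.add_bias:
            X = sp.hstack([X, np.ones((self.n, 1))]).tocsr()
        d = X.shape[1]
        rng = np.random.default_rng(config.seed)
        w = np.zeros(d)
        objective_path = []
        batch = max(1, int(round(config.minibatch_fraction * self.n)))
        for t in range(1, config.iterations + 1):
            if batch < self.n:
                idx = rng.choice(self.n, size=batch, replace=False)
                Xb, yb = X[idx], y[idx]
            else:
                Xb, yb = X, y
            g = self._loss_subgradient(w, Xb, yb)
            g = g + config.reg_param * _regularizer_subgradient(w, config.regularizer)
            w = w - (config.step_size / math.sqrt(t)) * g
            objective_path.append(self._objective_with_bias(w, X, config))
        return LinearClassifierResults(self, w, config, objective_path)

    def _objective_with_bias(self, w, X, config) -> float:
        z = X @ w
        m = self.y * z
        if self.loss == "hinge":
            loss = np.maximum(0.0, 1.0 - m).mean()
        else:
            loss = np.logaddexp(0.0, -m).mean()
        return config.reg_param * _regularizer_value(w, config.regularizer) + loss


class LinearClassifierResults:
    """Fitted weights plus diagnostics for a binary linear model."""

    def __init__(self, model, w, config, objective_path):
        self.model = model
        self.weights = np.asarray(w)
        self.config = config
        self.objective_path = list(objective_path)
        self.loss = model.loss
        self.positive_class = model.positive_class

    @property
    def final_objective(self) -> float:
        return self.objective_path[-1]

    def decision_score(self, x) -> float:
        """z = w^T x for a single feature vector."""
        xv = x.toarray() if isinstance(x, FeatureVector) else np.asarray(x).ravel()
        w = self.weights
        d = len(w) - (1 if self.config.add_bias else 0)
        if len(xv) != d:
            raise ValueError(f"dimension mismatch: model {d}, input {len(xv)}")
        z = float(w[:d] @ xv)
        if self.config.add_bias:
            z += float(w[-1])
        return z

    def decision_scores(self, X) -> np.ndarray:
        M = _as_matrix(X)
        w = self.weights
        d = len(w) - (1 if self.config.add_bias else 0)
        if M.shape[1] != d:
            raise ValueError(f"dimension mismatch: model {d}, input {M.shape[1]}")
        z = np.asarray(M @ w[:d]).ravel()
        if self.config.add_bias:
            z = z + w[-1]
        return z

    def predict(self, x):
        """(label, z, probability) — probability only for the logistic loss.

        Positive iff z > 0 (for logistic this is sigmoid(z) > 0.5); a tie
        z = 0 resolves to the negative/pivot class.
        """
        z = self.decision_score(x)
        prob = sigmoid(z) if self.loss == "logistic" else None
        label = self.positive_class if z > 0 else _negative_label(self.positive_class)
        return label, z, prob

    def training_accuracy(self) -> float:
        z = self.decision_scores(self.model.X)
        pred = np.where(z > 0, 1.0, -1.0)
        return float((pred == self.model.y).mean())

    def summary(self) -> str:
        c = self.config
        lines = [
            f"{'Linear SVM' if self.loss == 'hinge' else 'Logistic regression'} results",
            "=" * 44,
            f"loss:              {self.loss}",
            f"regularizer:       {c.regularizer} (a = {c.reg_param})",
            f"iterations:        {c.iterations}  (step {c.step_size}/sqrt(t))",
            f"n instances:       {self.model.n}",
            f"n features:        {self.model.d}",
            f"positive class:    {self.positive_class}",
            f"final objective:   {self.final_objective:.6f}",
            f"||w||_1:           {np.abs(self.weights).sum():.6f}",
            f"||w||_2:           {np.linalg.norm(self.weights):.6f}",
            f"training accuracy: {self.training_accuracy():.4f}",
        ]
        return "\n".join(lines)


def _negative_label(positive_class):
    if positive_class in (1, 1.0):
        return -1
    return f"not-{positive_class}"


class MultinomialNaiveBayes:
    """Multinomial naive Bayes over TF-IDF values used as pseudo-counts.

    The single modelling assumption is class-conditional independence of
    the features.  ``fit`` estimates log-priors from class proportions and
    per-class term log-likelihoods with Laplace smoothing lambda.
    """

    def __init__(self, X, y: Sequence[str]):
        self.X = _as_matrix(X)
        self.labels = list(y)
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("X and y disagree on the number of instances")
        if any(lab is None for lab in self.labels):
            raise ValueError("all training documents must be labeled")
        self.classes = sorted(set(self.labels))
        for c in self.classes:
            if self.labels.count(c) == 0:  # pragma: no cover - defensive
                raise ValueError(f"class {c!r} has zero examples")

    def fit(self, smoothing: float = 1.0) -> "NaiveBayesResults":
        if smoothing <= 0:
            raise ValueError("smoothing must be > 0")
        n, d = self.X.shape
        y = np.asarray(self.labels)
        log_priors = {}
        log_likelihood = {}
        for c in self.classes:
            mask = y == c
            log_priors[c] = math.log(mask.sum() / n)
            totals = np.asarray(self.X[mask].sum(axis=0)).ravel() + smoothing
            log_likelihood[c] = np.log(totals) - math.log(totals.sum())
        return NaiveBayesResults(self, log_priors, log_likelihood, smoothing)


class NaiveBayesResults:
    """Fitted class log-priors and term log-likelihood tables."""

    def __init__(self, model, log_priors, log_likelihood, smoothing):
        self.model = model
        self.classes = model.classes
        self.log_priors = log_priors
        self.log_likelihood = log_likelihood
        self.smoothing = smoothing
        self.dimension = model.X.shape[1]

    def joint_log_likelihood(self, x) -> dict[str, float]:
        xv = x.toarray() if isinstance(x, FeatureVector) else np.asarray(x).ravel()
        if len(xv) != self.dimension:
            raise ValueError(
                f"dimension mismatch: model {self.dimension}, input {len(xv)}"
            )
        return {
            c: self.log_priors[c] + float(xv @ self.log_likelihood[c])
            for c in self.classes
        }

    def predict(self, x):
        """(label, normalized per-class log-posteriors).

        The label is the argmax of log-prior + sum_t x_t log p(t|c);
        exact ties resolve to the lexicographically smallest class.
        """
        joint = self.joint_log_likelihood(x)
        vals = np.asarray([joint[c] for c in self.classes])
        log_post = vals - logsumexp(vals)
        top = max(joint.values())
        best = min(c for c in self.classes if joint[c] == top)
        return best, dict(zip(self.classes, log_post.tolist()))

    def posterior_margin(self, x) -> float:
        """top1 - top2 log-posterior gap, a ranking score for ROC curves."""
        joint = sorted(self.joint_log_likelihood(x).values(), reverse=True)
        if len(joint) == 1:
            return joint[0]
        return joint[0] - joint[1]

    def summary(self) -> str:
        lines = [
            "Multinomial naive Bayes results",
            "=" * 44,
            f"classes:        {self.classes}",
            f"n instances:    {self.model.X.shape[0]}",
            f"n features:     {self.dimension}",
            f"smoothing:      {self.smoothing}",
            "log-priors:     "
            + ", ".join(f"{c}={self.log_priors[c]:.4f}" for c in self.classes),
        ]
        return "\n".join(lines)


class OneVsRestClassifier:
    """Multiclass reduction: one binary linear model per class."""

    def __init__(self, X, y: Sequence[str], loss: str = "hinge"):
        self.X = _as_matrix(X)
        self.labels = list(y)
        self.loss = loss
        self.classes = sorted(set(self.labels))
        if len(self.classes) < 2:
            raise ValueError("one-vs-rest needs at least 2 classes")

    def fit(self, config: Optional[TrainConfig] = None) -> "OneVsRestResults":
        config = config or TrainConfig()
        submodels = {}
        for c in self.classes:
            model = LinearClassifier(
                self.X, self.labels, loss=self.loss, positive_class=c
            )
            submodels[c] = model.fit(config)
        return OneVsRestResults(self, submodels, config)


class OneVsRestResults:
    def __init__(self, model, submodels, config):
        self.model = model
        self.classes = model.classes
        self.submodels = submodels
        self.config = config

    def decision_scores(self, x) -> dict[str, float]:
        return {c: self.submodels[c].decision_score(x) for c in self.classes}

    def predict(self, x):
        """(label, per-class scores); score ties resolve to the
        lexicographically smallest class label."""
        scores = self.decision_scores(x)
        top = max(scores.values())
        label = min(c for c in self.classes if scores[c] == top)
        return label, scores

    def predict_many(self, X) -> list[str]:
        M = _as_matrix(X)
        S = np.column_stack(
            [self.submodels[c].decision_scores(M) for c in self.classes]
        )
        out = []
        for row in S:
            top = row.max()
            out.append(min(c for c, s in zip(self.classes, row) if s == top))
        return out

    def summary(self) -> str:
        lines = [
            f"One-vs-rest {'SVM' if self.model.loss == 'hinge' else 'logistic'} results",
            "=" * 44,
            f"classes: {self.classes}",
        ]
        for c in self.classes:
            r = self.submodels[c]
            lines.append(
                f"  {c}: objective {r.final_objective:.6f}, "
                f"||w||_2 {np.linalg.norm(r.weights):.4f}"
            )
        return "\n".join(lines)


# --- functional wrappers -------------------------------------------------

def train_linear_sgd(
    vectors: Sequence[FeatureVector],
    config: TrainConfig,
    loss: str,
    positive_class=None,
) -> LinearClassifierResults:
    labels = [v.label for v in vectors]
    if positive_class is None and set(labels) <= {1, -1}:
        positive_class = 1
    model = LinearClassifier(vectors, labels, loss=loss, positive_class=positive_class)
    return model.fit(config)


def decision_score(results: LinearClassifierResults, x) -> float:
    return results.decision_score(x)


def predict_binary(results: LinearClassifierResults, x):
    return results.predict(x)


def train_naive_bayes(
    vectors: Sequence[FeatureVector], smoothing: float = 1.0
) -> NaiveBayesResults:
    model = MultinomialNaiveBayes(vectors, [v.label for v in vectors])
    return model.fit(smoothing)


def nb_predict(results: NaiveBayesResults, x):
    return results.predict(x)


def ovr_train(
    vectors: Sequence[FeatureVector], config: TrainConfig, loss: str
) -> OneVsRestResults:
    model = OneVsRestClassifier(vectors, [v.label for v in vectors], loss=loss)
    return model.fit(config)


def ovr_predict(results: OneVsRestResults, x):
    return results.predict(x)


# --- JSON serialization ---------------------------------------------------

_SCHEMA = 1


def save_model(results, path: str | Path, vocab_hash: Optional[str] = None) -> None:
    """Serialize a fitted results object to a documented JSON container.

    ``vocab_hash`` optionally records a digest of the vocabulary sidecar
    the model was trained against, for provenance checks at load time.
    """
    if isinstance(results, LinearClassifierResults):
        payload = {
            "schema": _SCHEMA,
            "kind": "linear",
            "loss": results.loss,
            "positive_class": results.positive_class,
            "weights": results.weights.tolist(),
            "config": asdict(results.config),
            "objective_path": results.objective_path,
        }
    elif isinstance(results, NaiveBayesResults):
        payload = {
            "schema": _SCHEMA,
            "kind": "naive_bayes",
            "classes": results.classes,
            "log_priors": results.log_priors,
            "log_likelihood": {
                c: results.log_likelihood[c].tolist() for c in results.classes
            },
            "smoothing": results.smoothing,
            "dimension": results.dimension,
        }
    elif isinstance(results, OneVsRestResults):
        payload = {
            "schema": _SCHEMA,
            "kind": "one_vs_rest",
            "loss": results.model.loss,
            "classes": results.classes,
            "config": asdict(results.config),
            "weights": {
                c: results.submodels[c].weights.tolist() for c in results.classes
            },
            "objectives": {
                c: results.submodels[c].objective_path for c in results.classes
            },
        }
    else:
        raise TypeError(f"cannot serialize {type(results).__name__}")
    payload["vocab_hash"] = vocab_hash
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle)


class _LoadedLinear(LinearClassifierResults):
    """Results object reconstructed from JSON (no training data attached)."""

    def __init__(self, payload):
        class _Stub:
            pass

        stub = _Stub()
        stub.loss = payload["loss"]
        stub.positive_class = payload["positive_class"]
        config = TrainConfig(**payload["config"])
        super().__init__(stub, np.asarray(payload["weights"]), config,
                         payload["objective_path"])

    def training_accuracy(self):  # pragma: no cover
        raise AttributeError("training data not available on a loaded model")


def load_model(path: str | Path):
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    if payload.get("schema") != _SCHEMA:
        raise ValueError(f"unsupported model schema {payload.get('schema')}")
    kind = payload["kind"]
    if kind == "linear":
        return _LoadedLinear(payload)
    if kind == "naive_bayes":
        class _Stub:
            pass

        stub = _Stub()
        stub.classes = payload["classes"]
        stub.X = sp.csr_matrix((0, payload["dimension"]))
        res = NaiveBayesResults.__new__(NaiveBayesResults)
        res.model = stub
        res.classes = payload["classes"]
        res.log_priors = payload["log_priors"]
        res.log_likelihood = {
            c: np.asarray(v) for c, v in payload["log_likelihood"].items()
        }
        res.smoothing = payload["smoothing"]
        res.dimension = payload["dimension"]
        return res
    if kind == "one_vs_rest":
        class _Stub:
            pass

        stub = _Stub()
        stub.loss = payload["loss"]
        stub.classes = payload["classes"]
        config = TrainConfig(**payload["config"])
        submodels = {}
        for c in payload["classes"]:
            sub = {
                "loss": payload["loss"],
                "positive_class": c,
                "weights": payload["weights"][c],
                "config": payload["config"],
                "objective_path": payload["objectives"][c],
            }
            submodels[c] = _LoadedLinear(sub)
        res = OneVsRestResults.__new__(OneVsRestResults)
        res.model = stub
        res.classes = payload["classes"]
        res.submodels = submodels
        res.config = config
        return res
    raise ValueError(f"unknown model kind {kind!r}")
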