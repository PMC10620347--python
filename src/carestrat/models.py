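"""The four classifier families used by the study harness.

* majority baseline — always predicts the modal training label;
* multinomial naive Bayes over token counts with add-one (Laplace)
  smoothing, deleting test tokens outside the training vocabulary;
* softmax (multinomial logistic) regression trained by mini-batch SGD on the
  L2-regularized cross-entropy, at most ``max_epochs`` passes;
* linear-kernel SVM minimizing the primal hinge objective
  ``(1/2)||w||^2 + C * sum hinge``, one-vs-rest for multiclass (liblinear
  behind this surface).

Every argmax tie breaks toward the lexicographically smallest label, so all
predictions are deterministic given seed and configuration.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

Label = Hashable


def _check_finite(X: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")


# ---------------------------------------------------------------------------
# Majority baseline


@dataclass(frozen=True)
class MajorityModel:
    stored_label: Label

    def predict(self, inputs: Sequence) -> list[Label]:
        return [self.stored_label] * len(inputs)


def train_majority(labels: Sequence[Label]) -> MajorityModel:
    """Store the modal training label; ties go to the smallest label."""
    if not labels:
        raise ValueError("cannot train a majority model on an empty label list")
    counts = Counter(labels)
    best = min(counts, key=lambda lab: (-counts[lab], str(lab)))
    return MajorityModel(stored_label=best)


# ---------------------------------------------------------------------------
# Multinomial naive Bayes


@dataclass
class NaiveBayesModel:
    classes: list[Label]
    vocabulary: dict[str, int]
    log_priors: np.ndarray  # (K,)
    log_likelihoods: np.ndarray  # (K, V); rows of exp sum to 1

    def predict(self, token_sequences: Sequence[Iterable[str]]) -> list[Label]:
        return [nb_predict(self, toks) for toks in token_sequences]


def train_naive_bayes(
    token_sequences: Sequence[Iterable[str]], labels: Sequence[Label]
) -> NaiveBayesModel:
    """Fit priors and Laplace-smoothed token likelihoods per class."""
    if len(token_sequences) != len(labels):
        raise ValueError("token_sequences and labels differ in length")
    classes = sorted(set(labels), key=str)
    if len(classes) < 2:
        raise ValueError("naive Bayes requires at least two classes in training")
    docs = [list(t) for t in token_sequences]
    vocab = {w: i for i, w in enumerate(sorted({t for doc in docs for t in doc}))}
    K, V = len(classes), len(vocab)
    class_index = {c: k for k, c in enumerate(classes)}
    counts = np.zeros((K, V))
    doc_counts = np.zeros(K)
    for doc, label in zip(docs, labels):
        k = class_index[label]
        doc_counts[k] += 1
        for tok in doc:
            counts[k, vocab[tok]] += 1
    log_priors = np.log(doc_counts / doc_counts.sum())
    log_likelihoods = np.log((counts + 1.0) / (counts.sum(axis=1, keepdims=True) + V))
    return NaiveBayesModel(
        classes=classes, vocabulary=vocab,
        log_priors=log_priors, log_likelihoods=log_likelihoods,
    )


def nb_log_joint(model: NaiveBayesModel, tokens: Iterable[str]) -> np.ndarray:
    """Per-class log P(c) + sum log P(token|c); unknown tokens removed."""
    scores = model.log_priors.copy()
    for tok in tokens:
        i = model.vocabulary.get(tok)
        if i is not None:
            scores += model.log_likelihoods[:, i]
    return scores


def nb_predict(model: NaiveBayesModel, tokens: Iterable[str]) -> Label:
    scores = nb_log_joint(model, tokens)
    return model.classes[int(np.argmax(scores))]  # classes sorted -> ties lexicographic


# ---------------------------------------------------------------------------
# Softmax regression via mini-batch SGD


@dataclass(frozen=True)
class LogisticConfig:
    l2_strength: float = 1.0
    max_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.1  # decays as lr / sqrt(t) over updates
    tol: float = 1e-4
    seed: int = 0


@dataclass
class LogisticModel:
    classes: list[Label]
    weights: np.ndarray  # (K, D)
    bias: np.ndarray  # (K,)
    config: LogisticConfig
    n_epochs_run: int = 0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights.T + self.bias

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.decision_function(np.asarray(X, dtype=float))
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> list[Label]:
        proba = self.predict_proba(X)
        return [self.classes[i] for i in np.argmax(proba, axis=1)]


def _softmax_loss(W, b, X, Y, l2):
    z = X @ W.T + b
    z -= z.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    ce = -np.mean((Y * log_probs).sum(axis=1))
    return ce + 0.5 * l2 * float((W * W).sum()) / X.shape[0]


def train_logistic(
    feature_vectors: np.ndarray,
    labels: Sequence[Label],
    config: LogisticConfig = LogisticConfig(),
) -> LogisticModel:
    """Minimize L2-regularized cross-entropy with mini-batch SGD.

    Runs at most ``max_epochs`` passes; stops early once the full-data loss
    improves by less than ``tol`` between epochs. The binary case is the
    two-class softmax, equivalent to a sigmoid on the score difference.
    """
    X = np.asarray(feature_vectors, dtype=float)
    _check_finite(X)
    classes = sorted(set(labels), key=str)
    if len(classes) < 2:
        raise ValueError("logistic regression requires at least two classes")
    class_index = {c: k for k, c in enumerate(classes)}
    y = np.array([class_index[lab] for lab in labels])
    n, d = X.shape
    K = len(classes)
    Y = np.eye(K)[y]
    W = np.zeros((K, d))
    b = np.zeros(K)
    rng = np.random.default_rng(config.seed)
    t = 0
    prev_loss = _softmax_loss(W, b, X, Y, config.l2_strength)
    epochs_run = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            t += 1
            lr = config.learning_rate / math.sqrt(t)
            z = X[idx] @ W.T + b
            z -= z.max(axis=1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=1, keepdims=True)
            grad = p - Y[idx]
            W -= lr * (grad.T @ X[idx] / len(idx) + config.l2_strength * W / n)
            b -= lr * grad.mean(axis=0)
        epochs_run = epoch + 1
        loss = _softmax_loss(W, b, X, Y, config.l2_strength)
        if abs(prev_loss - loss) < config.tol:
            break
        prev_loss = loss
    return LogisticModel(classes=classes, weights=W, bias=b, config=config,
                         n_epochs_run=epochs_run)


# ---------------------------------------------------------------------------
# Linear SVM (primal hinge, one-vs-rest)


@dataclass
class LinearSvmModel:
    classes: list[Label]
    weights: np.ndarray  # (K, D) or (1, D) for binary
    bias: np.ndarray
    C: float
    multiclass_scheme: str = "one-vs-rest"

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights.T + self.bias

    def predict(self, X: np.ndarray) -> list[Label]:
        scores = self.decision_function(X)
        if len(self.classes) == 2:
            idx = (scores[:, 0] > 0).astype(int)
            return [self.classes[i] for i in idx]
        return [self.classes[i] for i in np.argmax(scores, axis=1)]

    def objective(self, X: np.ndarray, labels: Sequence[Label]) -> float:
        """Primal binary objective (1/2)||w||^2 + C * sum hinge (binary only)."""
        if len(self.classes) != 2:
            raise ValueError("primal objective helper is binary-only")
        y = np.array([1.0 if lab == self.classes[1] else -1.0 for lab in labels])
        margins = y * self.decision_function(X)[:, 0]
        hinge = np.maximum(0.0, 1.0 - margins).sum()
        return 0.5 * float(self.weights @ self.weights.T) + self.C * hinge


def train_linear_svm(
    feature_vectors: np.ndarray,
    labels: Sequence[Label],
    C: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100000,
) -> LinearSvmModel:
    """Linear-kernel SVM; one-vs-rest with lexicographic argmax tie-break."""
    X = np.asarray(feature_vectors, dtype=float)
    _check_finite(X)
    classes = sorted(set(labels), key=str)
    if len(classes) < 2:
        raise ValueError("SVM requires at least two classes")
    y = [str(lab) for lab in labels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LinearSVC(C=C, loss="hinge", tol=tol, max_iter=max_iter, random_state=0)
        clf.fit(X, y)
    # liblinear orders classes by the sorted string labels, matching `classes`
    return LinearSvmModel(
        classes=classes,
        weights=np.atleast_2d(clf.coef_),
        bias=np.atleast_1d(clf.intercept_),
        C=C,
    )
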