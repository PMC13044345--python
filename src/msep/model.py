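"""Class-weighted training objective and extractor backends.

Class imbalance is severe in this task (``unknown`` dominates; ``absent`` is
typically much rarer than ``present``), so training uses a weighted
cross-entropy objective

    L = - sum_i w_i log p(y_i | x_i),      w_i = N / (C * N_{y_i})

where N is the number of training samples, C the number of classes and
N_{y_i} the count of sample i's class.  The weights equalize the aggregate
mass of every class: N_c * w_c = N / C exactly.

Four interchangeable extractor backends satisfy one predict contract:

* ``rules`` — delegates to the rule classifier;
* ``linear`` — a self-contained multinomial logistic model over hashed
  word-unigram and character 3–5-gram counts, trained by deterministic
  full-batch gradient descent on the weighted objective plus L2;
* ``external-finetune-stub`` / ``external-prompt-stub`` — predictions
  produced elsewhere (a fine-tuned encoder, a prompted LLM) and loaded from
  file, so backend comparison works without those systems.

The trainer minimizes the weight-normalized objective (divide by sum of
weights); scaling all weights by a constant therefore leaves the fitted
decision function bitwise identical.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import Sentence, normalized_key
from .rules import RuleSet, classify_with_rules

__all__ = [
    "LabeledDataset",
    "LossSpec",
    "ModelError",
    "compute_class_weights",
    "weighted_cross_entropy",
    "hash_features",
    "train_linear",
    "predict",
    "RulesExtractor",
    "LinearExtractor",
    "ExternalExtractor",
    "load_external_predictions",
    "save_linear",
    "load_linear",
]

PROB_FLOOR = 1e-12


class ModelError(ValueError):
    """Raised for invalid training inputs or unfitted extractors."""


@dataclass
class LabeledDataset:
    """Gold-labeled sentences for one condition.

    ``label_set`` is the set of statuses with at least ``min_per_class``
    samples; items outside it are flagged excluded (too few samples for
    cross-validation) but retained for bookkeeping.
    """

    items: list[tuple[Sentence, str]]
    condition: str
    min_per_class: int = 3

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, lab in self.items:
            out[lab] = out.get(lab, 0) + 1
        return out

    @property
    def label_set(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, n in self.counts.items() if n >= self.min_per_class))

    @property
    def included(self) -> list[tuple[Sentence, str]]:
        ls = set(self.label_set)
        return [(s, lab) for s, lab in self.items if lab in ls]

    @property
    def excluded(self) -> list[tuple[Sentence, str]]:
        ls = set(self.label_set)
        return [(s, lab) for s, lab in self.items if lab not in ls]

    def deduplicated(self) -> "LabeledDataset":
        """Drop items with a previously seen normalized text, keeping first."""
        seen: set[str] = set()
        kept = []
        for s, lab in self.items:
            key = normalized_key(s.text)
            if key not in seen:
                seen.add(key)
                kept.append((s, lab))
        return LabeledDataset(kept, self.condition, self.min_per_class)


@dataclass
class LossSpec:
    """Hyperparameters of the weighted cross-entropy objective and optimizer."""

    l2: float = 1e-4
    max_iter: int = 500
    learning_rate: float = 2.0
    tol: float = 1e-7
    seed: int = 0
    hash_dim: int = 2**18


def compute_class_weights(dataset: LabeledDataset) -> dict[str, float]:
    """Per-class weight N / (C * N_c) over the dataset's included items."""
    counts: dict[str, int] = {}
    for _, lab in dataset.included:
        counts[lab] = counts.get(lab, 0) + 1
    for lab in dataset.label_set:
        if counts.get(lab, 0) == 0:
            raise ModelError(f"class {lab!r} has no samples")
    n = sum(counts.values())
    c = len(counts)
    return {lab: n / (c * nc) for lab, nc in counts.items()}


def weighted_cross_entropy(
    probs: np.ndarray,
    labels: Sequence[int],
    weights: Sequence[float],
) -> float:
    """L = -sum_i w_i log p(y_i | x_i), natural log.

    ``probs`` is (n, C) with rows summing to 1 within 1e-9; ``labels`` holds
    true-class column indices; ``weights`` gives w_i per sample.  True-class
    probabilities of zero are clamped at 1e-12 with a warning.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    weights = np.asarray(weights, dtype=float)
    if probs.ndim != 2 or len(labels) != probs.shape[0] or len(weights) != len(labels):
        raise ModelError("probs, labels and weights have inconsistent shapes")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
        raise ModelError("probability rows must sum to 1 within 1e-9")
    p_true = probs[np.arange(len(labels)), labels]
    if np.any(p_true <= 0):
        warnings.warn(
            f"zero true-class probability clamped at {PROB_FLOOR}", stacklevel=2
        )
        p_true = np.maximum(p_true, PROB_FLOOR)
    return float(-(weights * np.log(p_true)).sum())


# ---------------------------------------------------------------------------
# Hashed text features
# ---------------------------------------------------------------------------


def _token_hashes(text: str, dim: int) -> list[int]:
    key = normalized_key(text)
    idx = [zlib.crc32(f"w|{tok}".encode()) % dim for tok in key.split()]
    padded = f" {key} "
    for n in (3, 4, 5):
        idx.extend(
            zlib.crc32(f"c{n}|{padded[i : i + n]}".encode()) % dim
            for i in range(len(padded) - n + 1)
        )
    return idx


def hash_features(texts: Sequence[str], dim: int = 2**18) -> sp.csr_matrix:
    """Hashed word-unigram + character 3–5-gram count matrix, L2-normalized rows.

    Hash collisions are accepted; the dimension bounds the model size
    without any vocabulary fitting.
    """
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for text in texts:
        counts: dict[int, int] = {}
        for h in _token_hashes(text, dim):
            counts[h] = counts.get(h, 0) + 1
        for k in sorted(counts):
            indices.append(k)
            data.append(float(counts[k]))
        indptr.append(len(indices))
    X = sp.csr_matrix(
        (np.array(data), np.array(indices, dtype=np.int64), np.array(indptr, dtype=np.int64)),
        shape=(len(texts), dim),
    )
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    norms[norms == 0] = 1.0
    return sp.diags(1.0 / norms) @ X


# ---------------------------------------------------------------------------
# Extractor backends
# ---------------------------------------------------------------------------


class Extractor:
    """Predict contract shared by all backends."""

    backend_kind: str = "abstract"
    label_set: tuple[str, ...] = ()

    def predict(self, sentences: Sequence[Sentence]) -> dict[str, str]:
        raise NotImplementedError


@dataclass
class RulesExtractor(Extractor):
    rules: RuleSet
    backend_kind: str = "rules"

    @property
    def label_set(self) -> tuple[str, ...]:  # type: ignore[override]
        return self.rules.label_set

    def predict(self, sentences: Sequence[Sentence]) -> dict[str, str]:
        return {s.sent_id: classify_with_rules(s, self.rules).label for s in sentences}


@dataclass
class LinearExtractor(Extractor):
    weights: np.ndarray  # (dim, C)
    bias: np.ndarray  # (C,)
    labels: tuple[str, ...]
    hash_dim: int
    backend_kind: str = "linear"
    fitted: bool = False

    @property
    def label_set(self) -> tuple[str, ...]:  # type: ignore[override]
        return self.labels

    def decision_scores(self, sentences: Sequence[Sentence]) -> np.ndarray:
        X = hash_features([s.text for s in sentences], self.hash_dim)
        return X @ self.weights + self.bias

    def predict(self, sentences: Sequence[Sentence]) -> dict[str, str]:
        if not self.fitted:
            raise ModelError("linear extractor is not fitted")
        if not sentences:
            return {}
        scores = self.decision_scores(sentences)
        picks = np.argmax(scores, axis=1)
        return {s.sent_id: self.labels[k] for s, k in zip(sentences, picks)}


@dataclass
class ExternalExtractor(Extractor):
    """Stub backend serving predictions produced by an external system."""

    predictions: Mapping[str, str]
    labels: tuple[str, ...] = ()
    backend_kind: str = "external-finetune-stub"
    fallback: str = "unknown"

    @property
    def label_set(self) -> tuple[str, ...]:  # type: ignore[override]
        return self.labels or tuple(sorted(set(self.predictions.values())))

    def predict(self, sentences: Sequence[Sentence]) -> dict[str, str]:
        return {s.sent_id: self.predictions.get(s.sent_id, self.fallback) for s in sentences}


def load_external_predictions(path: str | Path) -> dict[str, str]:
    """JSON-lines (sent_id, label) file written by an external extractor."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                out[rec["sent_id"]] = rec["label"]
            except (json.JSONDecodeError, KeyError) as exc:
                raise ModelError(f"line {lineno}: invalid prediction record ({exc})") from exc
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_linear(
    dataset: LabeledDataset,
    spec: LossSpec | None = None,
    weights: Mapping[str, float] | None = None,
) -> LinearExtractor:
    """Fit the multinomial linear backend on the weighted objective.

    Full-batch gradient descent with a fixed step that halves whenever a
    step would increase the (weight-normalized, L2-regularized) loss, so
    training loss is non-increasing and the run is deterministic for a
    given seed and data order.
    """
    spec = spec or LossSpec()
    items = dataset.included
    labels = dataset.label_set
    if len(labels) < 2:
        raise ModelError(
            f"training needs >= 2 classes, got {labels!r} "
            f"(min_per_class={dataset.min_per_class})"
        )
    if weights is None:
        weights = compute_class_weights(dataset)
    lab_index = {lab: j for j, lab in enumerate(labels)}
    y = np.array([lab_index[lab] for _, lab in items], dtype=int)
    w = np.array([weights[lab] for _, lab in items], dtype=float)
    w_norm = w / w.sum()
    X = hash_features([s.text for s, _ in items], spec.hash_dim)
    n, dim = X.shape
    C = len(labels)
    Y = np.zeros((n, C))
    Y[np.arange(n), y] = 1.0

    W = np.zeros((dim, C))
    b = np.zeros(C)

    def loss_and_grad(W, b):
        P = _softmax(X @ W + b)
        p_true = np.maximum(P[np.arange(n), y], PROB_FLOOR)
        loss = float(-(w_norm * np.log(p_true)).sum()) + 0.5 * spec.l2 * float((W * W).sum())
        R = (P - Y) * w_norm[:, None]
        gW = (X.T @ R) + spec.l2 * W
        gb = R.sum(axis=0)
        return loss, gW, gb

    lr = spec.learning_rate
    loss, gW, gb = loss_and_grad(W, b)
    for _ in range(spec.max_iter):
        W_new = W - lr * gW
        b_new = b - lr * gb
        loss_new, gW_new, gb_new = loss_and_grad(W_new, b_new)
        if loss_new > loss:
            lr *= 0.5
            if lr < 1e-8:
                break
            continue
        if loss - loss_new < spec.tol:
            W, b, loss = W_new, b_new, loss_new
            break
        W, b, loss = W_new, b_new, loss_new
        gW, gb = gW_new, gb_new
    return LinearExtractor(
        weights=W, bias=b, labels=labels, hash_dim=spec.hash_dim, fitted=True
    )


def predict(extractor: Extractor, sentences: Sequence[Sentence]) -> dict[str, str]:
    """Total, deterministic sentence->label mapping for any backend."""
    if isinstance(extractor, LinearExtractor) and not extractor.fitted:
        raise ModelError("linear extractor is not fitted")
    return extractor.predict(list(sentences))


# ---------------------------------------------------------------------------
# Model files: JSON header + flat weight array
# ---------------------------------------------------------------------------


def save_linear(extractor: LinearExtractor, path: str | Path) -> None:
    rec = {
        "backend_kind": "linear",
        "labels": list(extractor.labels),
        "hash_dim": extractor.hash_dim,
        "bias": extractor.bias.tolist(),
        "weights_nonzero": {
            str(i): extractor.weights[i].tolist()
            for i in np.nonzero(np.any(extractor.weights != 0, axis=1))[0]
        },
    }
    Path(path).write_text(json.dumps(rec), encoding="utf-8")


def load_linear(path: str | Path) -> LinearExtractor:
    rec = json.loads(Path(path).read_text(encoding="utf-8"))
    W = np.zeros((rec["hash_dim"], len(rec["labels"])))
    for i, row in rec["weights_nonzero"].items():
        W[int(i)] = row
    return LinearExtractor(
        weights=W,
        bias=np.array(rec["bias"], dtype=float),
        labels=tuple(rec["labels"]),
        hash_dim=rec["hash_dim"],
        fitted=True,
    )
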