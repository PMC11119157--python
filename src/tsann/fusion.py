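"""Per-variant classification heads and the fused two-stage classifier.

Each variant's pair of graph outputs (C x SK/4 per class branch) is
concatenated and flattened to a vector of length C*SK/2, passed through a
small MLP to two class scores, and softmaxed — the first stage weights each
variant's own class evidence. The softmaxed pairs of all variants are
concatenated and a second MLP maps them to the final two logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MLPParams", "FusionParams", "fuse_and_classify", "softmax", "loss"]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - np.max(x, axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class MLPParams:
    """One hidden layer, rectifier activation: y = W2 relu(W1 x + b1) + b2."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.maximum(x @ self.W1 + self.b1, 0.0)
        return h @ self.W2 + self.b2


@dataclass
class FusionParams:
    """Per-variant first-stage MLPs plus the shared fusion MLP."""

    mlp1: dict  # variant name -> MLPParams (input C*SK/2 -> h1 -> 2)
    mlp2: MLPParams  # input 2*|variants| -> h2 -> 2


def fuse_and_classify(branch_outputs: dict, params: FusionParams) -> np.ndarray:
    """Final two-class logits for one segment.

    ``branch_outputs`` maps variant name -> (Zbar_l1, Zbar_l2), each
    C x SK/4. Variant order follows the dict order (insertion order is the
    configured variant order).
    """
    if not branch_outputs:
        raise ValueError("variant set is empty")
    stage1 = []
    for v, (zb1, zb2) in branch_outputs.items():
        fv = np.concatenate([zb1, zb2], axis=1).ravel()
        stage1.append(softmax(params.mlp1[v].forward(fv)))
    return params.mlp2.forward(np.concatenate(stage1))


def loss(true_labels: np.ndarray, logits: np.ndarray, lam: float = 0.0, theta=()) -> float:
    """Mean cross-entropy of softmaxed logits plus squared-L2 regularization.

    ``true_labels`` are 0/1 class indices, ``logits`` is (n, 2); ``theta``
    iterates over the arrays entering the penalty (weights, not biases).
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    y = np.asarray(true_labels, dtype=int).ravel()
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_probs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    data_term = -log_probs[np.arange(y.size), y].mean()
    reg = sum(float(np.sum(np.asarray(w) ** 2)) for w in theta)
    return float(data_term + lam * reg)
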