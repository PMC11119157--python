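"""Two-stage graph aggregation over the task-specific adjacency pair.

For each connectivity variant the segment's node features Z (C x SK) are
propagated through a class-specific first GCN layer per class graph,
``Z_l = relu(A~_l Z W_l)``. An *adjacency attention* gate is then computed
from pairwise concatenations of first-layer node features: per class, each
ordered pair (a, b) is scored by a logistic of the concatenated feature
rows projected on a trainable vector P_l, and the two class score matrices
are summed, giving a C x C gate in (0, 2). The gate multiplies each
normalized adjacency elementwise and a shared second GCN layer (weights
W_as) reduces both branches to C x SK/4.

Plain numpy reference implementations; the trainable batched path lives in
:mod:`tsann.network`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import TaskAdjacency

__all__ = [
    "BranchParams",
    "gcn_layer",
    "pairwise_concat",
    "adjacency_attention",
    "branch_forward",
]


@dataclass
class BranchParams:
    """Trainable tensors of one variant's graph branch.

    W_l1, W_l2 : (SK, SK/2) first-layer weights, one per class graph
    W_as       : (SK/2, SK/4) second-layer weights, shared by both branches
    P_l1, P_l2 : (SK,) attention projection vectors (act on concatenated
                 pairs of SK/2-dimensional first-layer rows)
    """

    W_l1: np.ndarray
    W_l2: np.ndarray
    W_as: np.ndarray
    P_l1: np.ndarray
    P_l2: np.ndarray


def gcn_layer(a: np.ndarray, z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """One graph-convolution layer: ``relu(A Z W)``."""
    a, z, w = (np.asarray(m, dtype=np.float64) for m in (a, z, w))
    if a.shape[0] != a.shape[1] or a.shape[1] != z.shape[0] or z.shape[1] != w.shape[0]:
        raise ValueError(
            f"shape mismatch: A {a.shape}, Z {z.shape}, W {w.shape}"
        )
    return np.maximum(a @ z @ w, 0.0)


def pairwise_concat(z: np.ndarray) -> np.ndarray:
    """C x C x 2F tensor whose (a, b) entry is [z_a ; z_b]."""
    z = np.asarray(z)
    c, f = z.shape
    left = np.broadcast_to(z[:, None, :], (c, c, f))
    right = np.broadcast_to(z[None, :, :], (c, c, f))
    return np.concatenate([left, right], axis=2)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def adjacency_attention(
    z_l1: np.ndarray, z_l2: np.ndarray, p_l1: np.ndarray, p_l2: np.ndarray
) -> np.ndarray:
    """Summed logistic pair scores of the two class branches, in (0, 2)."""
    score1 = _sigmoid(pairwise_concat(z_l1) @ p_l1)
    score2 = _sigmoid(pairwise_concat(z_l2) @ p_l2)
    return score1 + score2


def branch_forward(
    z_j: np.ndarray,
    ta: TaskAdjacency,
    params: BranchParams,
    use_attention: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Full two-stage aggregation for one variant; returns (Zbar_l1, Zbar_l2)."""
    l1, l2 = ta.labels
    a1, a2 = ta.norm[l1], ta.norm[l2]
    z1 = gcn_layer(a1, z_j, params.W_l1)
    z2 = gcn_layer(a2, z_j, params.W_l2)
    if use_attention:
        gate = adjacency_attention(z1, z2, params.P_l1, params.P_l2)
        a1, a2 = gate * a1, gate * a2
    zb1 = gcn_layer(a1, z1, params.W_as)
    zb2 = gcn_layer(a2, z2, params.W_as)
    return zb1, zb2
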