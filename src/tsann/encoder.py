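"""Node-feature encoding: multi-scale temporal convolution power features.

Each channel is passed through three parallel banks of K learned 1-D
convolution kernels. Kernel length halves per scale, tied to the sampling
rate: ``S_r = round(0.5^r * fs)`` samples for scales r = 1, 2, 3, so the
banks act as digital filters probing progressively finer temporal scales.
Each filtered series is squared, average-pooled and log-compressed (the
standard log band-power feature), giving a K x F_r block per scale. A
*kernel attention* step scores each of the K kernels by the normalized
projection of its feature row onto a trainable direction ``q_r``, softmaxes
the K scores, and scales the rows by their weights. The three scales'
weighted blocks are flattened and concatenated into one row of length
``SK = sum_r K * F_r`` per channel; kernels and ``q_r`` are shared across
channels, so a segment encodes to a C x SK node-feature matrix.

These are the reference (plain numpy) forward functions; the trainable
autodiff path in :mod:`tsann.network` computes the same quantities batched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EncoderConfig",
    "EncoderParams",
    "kernel_lengths",
    "feature_length",
    "pooling_matrix",
    "encode_channel",
    "kernel_attention",
    "encode_segment",
]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class EncoderConfig:
    """Encoder hyperparameters.

    pool_len / pool_stride default to round(fs/4) samples (non-overlapping
    quarter-second power bins). ``log_floor`` keeps the log finite on silent
    input.
    """

    fs: float
    n_scales: int = 3
    kernels_per_scale: int = 9
    pool_len: int | None = None
    pool_stride: int | None = None
    log_floor: float = 1e-6

    def __post_init__(self):
        if self.fs <= 8:
            raise ValueError("fs must exceed 8 Hz for three halving scales")
        if self.pool_len is None:
            self.pool_len = max(1, _round_half_away(self.fs / 4))
        if self.pool_stride is None:
            self.pool_stride = self.pool_len
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        if min(self.kernel_lengths()) < 1:
            raise ValueError("smallest kernel length rounds below 1 sample")

    def kernel_lengths(self) -> tuple[int, ...]:
        return kernel_lengths(self.fs, self.n_scales)

    def feature_lengths(self, t: int) -> tuple[int, ...]:
        return tuple(
            feature_length(t, s, self.pool_len, self.pool_stride)
            for s in self.kernel_lengths()
        )

    def sk(self, t: int) -> int:
        return self.kernels_per_scale * sum(self.feature_lengths(t))


@dataclass
class EncoderParams:
    """Trainable encoder tensors as plain arrays: conv kernels and q_r."""

    kernels: list  # per scale: (S_r, K) array
    q: list  # per scale: (F_r,) projection vector


def kernel_lengths(fs: float, n_scales: int = 3) -> tuple[int, ...]:
    """Per-scale kernel lengths ``S_r = round(0.5^r * fs)``, halving per scale."""
    lengths = tuple(_round_half_away(0.5**r * fs) for r in range(1, n_scales + 1))
    if lengths[-1] < 1:
        raise ValueError(f"fs={fs}: scale {n_scales} kernel rounds below 1 sample")
    return lengths


def feature_length(t: int, s: int, pool_len: int, pool_stride: int) -> int:
    """Output length of valid conv (length s) + pooling on a length-t series."""
    conv_len = t - s + 1
    f = (conv_len - pool_len) // pool_stride + 1
    if f < 1:
        raise ValueError(
            f"input too short: need T >= {s + pool_len - 1}, got {t}"
        )
    return f


def pooling_matrix(conv_len: int, pool_len: int, pool_stride: int) -> np.ndarray:
    """(conv_len, F) averaging matrix so pooling is a matrix product."""
    f = (conv_len - pool_len) // pool_stride + 1
    p = np.zeros((conv_len, f))
    for j in range(f):
        p[j * pool_stride : j * pool_stride + pool_len, j] = 1.0 / pool_len
    return p


def encode_channel(x: np.ndarray, cfg: EncoderConfig, params: EncoderParams) -> list[np.ndarray]:
    """Per-scale pre-attention feature blocks Z_r (K x F_r) for one channel.

    Valid (no-padding) convolution, elementwise square, average pooling,
    then log(. + log_floor).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    out = []
    for s, kern in zip(cfg.kernel_lengths(), params.kernels):
        conv_len = x.size - s + 1
        if conv_len < cfg.pool_len:
            raise ValueError(
                f"input too short: need T >= {s + cfg.pool_len - 1}, got {x.size}"
            )
        windows = np.lib.stride_tricks.sliding_window_view(x, s)  # (conv_len, s)
        conv = windows @ kern  # (conv_len, K)
        pooled = pooling_matrix(conv_len, cfg.pool_len, cfg.pool_stride).T @ (conv**2)
        out.append(np.log(pooled + cfg.log_floor).T)  # (K, F_r)
    return out


def kernel_attention(z_r: np.ndarray, q_r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Softmax-weight the K kernel rows by their scalar projection on q_r.

    Returns ``(weighted rows, attention scores Q_r)``.
    """
    z_r = np.asarray(z_r, dtype=np.float64)
    q_r = np.asarray(q_r, dtype=np.float64)
    norm = np.linalg.norm(q_r)
    if norm == 0:
        raise ValueError("projection vector q_r is zero")
    scores = z_r @ q_r / norm  # (K,)
    e = np.exp(scores - scores.max())
    weights = e / e.sum()
    return z_r * weights[:, None], scores


def encode_segment(
    x: np.ndarray,
    cfg: EncoderConfig,
    params: EncoderParams,
    use_attention: bool = True,
) -> np.ndarray:
    """Encode a C x T segment into the C x SK node-feature matrix.

    Kernels and projection vectors are shared across channels; per channel
    the three scales' (weighted) blocks are flattened row-major and
    concatenated.
    """
    x = np.asarray(x, dtype=np.float64)
    rows = []
    for c in range(x.shape[0]):
        blocks = encode_channel(x[c], cfg, params)
        if use_attention:
            blocks = [kernel_attention(z, q)[0] for z, q in zip(blocks, params.q)]
        rows.append(np.concatenate([b.ravel() for b in blocks]))
    return np.stack(rows)
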