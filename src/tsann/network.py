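"""The trainable temporal-spatial attention network (batched autodiff path).

Assembles the three blocks — multi-scale conv encoder with kernel
attention, per-variant two-stage GCN with adjacency attention over the
task-specific graph pair, and the fused two-stage MLP classifier — as one
differentiable forward pass over a batch of segments, with structural
ablation toggles:

``use_cnn=False``
    raw segment samples become the node features (SK = T);
``use_gcn=False``
    encoder output is flattened straight into the fusion MLP;
``use_kernel_attention=False`` / ``use_adjacency_attention=False``
    drop the respective attention parameters, backbone unchanged.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Adam, Tensor, concat
from .encoder import EncoderConfig, pooling_matrix

__all__ = ["TSANNNetwork"]


class TSANNNetwork:
    """All trainable tensors plus the batched forward pass.

    Parameters are created once from a seeded generator; adjacency matrices
    are set per training context via :meth:`set_adjacency` (they are data,
    not parameters).
    """

    def __init__(
        self,
        n_channels: int,
        n_times: int,
        fs: float,
        variants: tuple[str, ...],
        *,
        n_scales: int = 3,
        kernels_per_scale: int = 9,
        pool_len: int | None = None,
        pool_stride: int | None = None,
        log_floor: float = 1e-6,
        hidden1: int = 64,
        hidden2: int = 16,
        use_kernel_attention: bool = True,
        use_adjacency_attention: bool = True,
        use_cnn: bool = True,
        use_gcn: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        self.C, self.T, self.fs = int(n_channels), int(n_times), float(fs)
        self.variants = tuple(variants)
        self.use_kernel_attention = use_kernel_attention
        self.use_adjacency_attention = use_adjacency_attention
        self.use_cnn = use_cnn
        self.use_gcn = use_gcn
        self.hidden1, self.hidden2 = int(hidden1), int(hidden2)
        self.dtype = dtype
        if use_gcn and not self.variants:
            raise ValueError("variant set must be non-empty when the GCN block is enabled")
        rng = rng if rng is not None else np.random.default_rng(0)

        if use_cnn:
            self.enc_cfg = EncoderConfig(
                fs=fs,
                n_scales=n_scales,
                kernels_per_scale=kernels_per_scale,
                pool_len=pool_len,
                pool_stride=pool_stride,
                log_floor=log_floor,
            )
            self.kernel_sizes = self.enc_cfg.kernel_lengths()
            self.feature_sizes = self.enc_cfg.feature_lengths(self.T)
            self.SK = self.enc_cfg.sk(self.T)
        else:
            self.enc_cfg = None
            self.kernel_sizes = ()
            self.feature_sizes = ()
            self.SK = self.T
        if use_gcn and self.SK % 4 != 0:
            raise ValueError(
                f"node-feature width SK={self.SK} must be divisible by 4 for the "
                "SK -> SK/2 -> SK/4 graph stages; adjust pooling or window length"
            )

        self.params: dict[str, Tensor] = {}
        self._bias_names: set[str] = set()
        self._adjacency: dict[str, tuple[Tensor, Tensor]] = {}
        self._pool_mats: list[np.ndarray] = []
        self._init_params(rng)

    # -- construction ---------------------------------------------------------
    def _add(self, name: str, arr: np.ndarray, bias: bool = False):
        self.params[name] = Tensor(arr.astype(self.dtype), requires_grad=True)
        if bias:
            self._bias_names.add(name)

    def _glorot(self, rng, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    def _init_params(self, rng):
        K = self.enc_cfg.kernels_per_scale if self.use_cnn else 0
        if self.use_cnn:
            for r, (s, f) in enumerate(zip(self.kernel_sizes, self.feature_sizes), start=1):
                self._add(f"conv{r}", rng.normal(0.0, 1.0 / np.sqrt(s), size=(s, K)))
                if self.use_kernel_attention:
                    self._add(f"q{r}", rng.normal(0.0, 1.0, size=(f,)))
                self._pool_mats.append(
                    pooling_matrix(self.T - s + 1, self.enc_cfg.pool_len, self.enc_cfg.pool_stride).astype(self.dtype)
                )
        sk = self.SK
        if self.use_gcn:
            for v in self.variants:
                self._add(f"{v}.W_l1", self._glorot(rng, sk, sk // 2))
                self._add(f"{v}.W_l2", self._glorot(rng, sk, sk // 2))
                self._add(f"{v}.W_as", self._glorot(rng, sk // 2, sk // 4))
                if self.use_adjacency_attention:
                    self._add(f"{v}.P_l1", rng.normal(0.0, 1.0 / np.sqrt(sk), size=(sk,)))
                    self._add(f"{v}.P_l2", rng.normal(0.0, 1.0 / np.sqrt(sk), size=(sk,)))
        self._init_heads(rng)

    def _init_heads(self, rng):
        sk = self.SK
        if self.use_gcn:
            fin = self.C * (sk // 2)
            for v in self.variants:
                self._add(f"{v}.mlp1.W1", self._glorot(rng, fin, self.hidden1))
                self._add(f"{v}.mlp1.b1", np.zeros(self.hidden1), bias=True)
                # zero-init the head's output layer: every branch starts at the
                # softmax's maximal-gradient point (0.5, 0.5) with no coherent
                # sample-independent offset, which otherwise gets amplified
                # into saturation before class structure is picked up
                self._add(f"{v}.mlp1.W2", np.zeros((self.hidden1, 2)))
                self._add(f"{v}.mlp1.b2", np.zeros(2), bias=True)
            fusion_in = 2 * len(self.variants)
        else:
            fusion_in = self.C * sk
        self._add("mlp2.W1", self._glorot(rng, fusion_in, self.hidden2))
        self._add("mlp2.b1", np.zeros(self.hidden2), bias=True)
        self._add("mlp2.W2", self._glorot(rng, self.hidden2, 2))
        self._add("mlp2.b2", np.zeros(2), bias=True)

    # -- adjacency ------------------------------------------------------------
    def set_adjacency(self, adjacency: dict):
        """Install the normalized class-graph pair per variant.

        ``adjacency[variant] = (A_l1_norm, A_l2_norm)``, each C x C.
        """
        if self.use_gcn:
            missing = [v for v in self.variants if v not in adjacency]
            if missing:
                raise ValueError(f"missing adjacency for variant(s) {missing}")
            self._adjacency = {
                v: (
                    Tensor(np.asarray(adjacency[v][0], dtype=self.dtype)),
                    Tensor(np.asarray(adjacency[v][1], dtype=self.dtype)),
                )
                for v in self.variants
            }

    # -- forward --------------------------------------------------------------
    def _encode(self, x: np.ndarray) -> Tensor:
        """Batch of segments (B, C, T) -> node features (B, C, SK)."""
        b = x.shape[0]
        if not self.use_cnn:
            return Tensor(x.astype(self.dtype))
        flat = x.reshape(b * self.C, self.T).astype(self.dtype)
        blocks = []
        K = self.enc_cfg.kernels_per_scale
        for r, (s, f) in enumerate(zip(self.kernel_sizes, self.feature_sizes), start=1):
            l = self.T - s + 1
            # contiguous im2col + one 2-D GEMM beats batched strided matmul
            windows = np.ascontiguousarray(
                np.lib.stride_tricks.sliding_window_view(flat, s, axis=1)
            ).reshape(b * self.C * l, s)
            conv = (Tensor(windows) @ self.params[f"conv{r}"]).reshape(b * self.C, l, K)
            pooled = conv.square().transpose(0, 2, 1) @ Tensor(self._pool_mats[r - 1])  # (B*C, K, F)
            z = (pooled + np.float32(self.enc_cfg.log_floor)).log()
            if self.use_kernel_attention:
                q = self.params[f"q{r}"]
                norm = q.square().sum().sqrt()
                if norm.data == 0:
                    raise ValueError(f"projection vector q{r} is zero")
                scores = (z @ q) / norm  # (B*C, K)
                w = scores.softmax(axis=1).expand_dims(2)
                z = z * w
            blocks.append(z.reshape(b * self.C, K * f))
        return concat(blocks, axis=1).reshape(b, self.C, self.SK)

    def _branch(self, v: str, zj: Tensor) -> Tensor:
        """One variant's graph stages + first-stage head -> (B, 2) softmax."""
        a1, a2 = self._adjacency[v]
        z1 = (a1 @ (zj @ self.params[f"{v}.W_l1"])).relu()  # (B, C, SK/2)
        z2 = (a2 @ (zj @ self.params[f"{v}.W_l2"])).relu()
        if self.use_adjacency_attention:
            h = self.SK // 2
            gate = None
            for z, pname in ((z1, f"{v}.P_l1"), (z2, f"{v}.P_l2")):
                p = self.params[pname]
                u = z @ p[:h]  # (B, C)
                w = z @ p[h:]
                s = (u.expand_dims(2) + w.expand_dims(1)).sigmoid()  # (B, C, C)
                gate = s if gate is None else gate + s
            a1m, a2m = gate * a1, gate * a2  # broadcast over batch
        else:
            a1m, a2m = a1, a2
        zb1 = (a1m @ (z1 @ self.params[f"{v}.W_as"])).relu()  # (B, C, SK/4)
        zb2 = (a2m @ (z2 @ self.params[f"{v}.W_as"])).relu()
        b = zb1.shape[0]
        f = concat([zb1, zb2], axis=2).reshape(b, self.C * (self.SK // 2))
        h1 = (f @ self.params[f"{v}.mlp1.W1"] + self.params[f"{v}.mlp1.b1"]).relu()
        pair = h1 @ self.params[f"{v}.mlp1.W2"] + self.params[f"{v}.mlp1.b2"]
        return pair.softmax(axis=1)

    def forward(self, x: np.ndarray) -> Tensor:
        """Batch (B, C, T) -> final logits (B, 2)."""
        if x.ndim != 3 or x.shape[1] != self.C or x.shape[2] != self.T:
            raise ValueError(f"expected (B, {self.C}, {self.T}), got {x.shape}")
        zj = self._encode(x)
        if self.use_gcn:
            if not self._adjacency:
                raise RuntimeError("adjacency not set; call set_adjacency() first")
            fused = concat([self._branch(v, zj) for v in self.variants], axis=1)
        else:
            fused = zj.reshape(x.shape[0], self.C * self.SK)
        h = (fused @ self.params["mlp2.W1"] + self.params["mlp2.b1"]).relu()
        return h @ self.params["mlp2.W2"] + self.params["mlp2.b2"]

    def loss(self, x: np.ndarray, y: np.ndarray, lam: float = 0.0) -> Tensor:
        """Mean cross-entropy + lam * squared L2 of non-bias parameters."""
        logits = self.forward(x)
        onehot = np.eye(2, dtype=self.dtype)[np.asarray(y, dtype=int)]
        data = -(logits.log_softmax(axis=1) * Tensor(onehot)).sum() * (1.0 / len(y))
        if lam > 0:
            reg = None
            for name, p in self.params.items():
                if name in self._bias_names:
                    continue
                term = p.square().sum()
                reg = term if reg is None else reg + term
            return data + lam * reg
        return data

    # -- bookkeeping -----------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def weight_arrays(self) -> list[np.ndarray]:
        return [p.data for n, p in self.params.items() if n not in self._bias_names]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> dict:
        return {n: p.data.copy() for n, p in self.params.items()}

    def load_state_dict(self, state: dict):
        for n, p in self.params.items():
            p.data = state[n].copy()

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.parameters(), lr=lr)
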