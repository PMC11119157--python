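"""scikit-learn estimator wrapping the temporal-spatial attention network.

:class:`TSANNClassifier` consumes segments as an array ``(n_segments, C, T)``
with binary labels. ``fit`` builds the task-specific adjacency pair per
connectivity variant from the *training* segments (or accepts precomputed
ones), then trains with adaptive-moment gradient descent and, when a
validation split is supplied, early stopping on validation loss with the
best epoch's parameters restored.

The estimator composes with sklearn model selection (``get_params`` /
``set_params`` / ``clone``); nested cross-validation over trials lives in
:mod:`tsann.crossval`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .connectivity import ConnectivityConfig, TaskAdjacency, build_task_adjacency
from .data import Segment
from .network import TSANNNetwork

__all__ = ["TSANNClassifier"]


class TSANNClassifier(ClassifierMixin, BaseEstimator):
    """Trial-wise EEG classifier over task-specific connectivity graphs.

    Parameters
    ----------
    fs : sampling rate of the input segments (Hz).
    variants : connectivity methods whose graph branches are fused; any
        non-empty subset of ``("cor", "coh", "plv", "pli")``.
    band : analysis band (Hz) for the spectral/phase connectivity measures.
    lam : squared-L2 regularization weight on non-bias parameters.
    patience : epochs without validation-loss improvement before stopping
        (only active when a validation split is passed to ``fit``).
    use_* : structural ablation toggles (see :class:`tsann.network.TSANNNetwork`).
    """

    def __init__(
        self,
        fs: float = 128.0,
        variants: tuple = ("cor", "coh", "plv", "pli"),
        band: tuple = (4.0, 45.0),
        welch_seg_s: float = 1.0,
        welch_overlap: float = 0.5,
        n_scales: int = 3,
        kernels_per_scale: int = 9,
        pool_len: int | None = None,
        pool_stride: int | None = None,
        log_floor: float = 1e-6,
        hidden1: int = 64,
        hidden2: int = 16,
        lam: float = 1e-4,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 12,
        patience: int = 5,
        tol: float = 1e-3,
        use_kernel_attention: bool = True,
        use_adjacency_attention: bool = True,
        use_cnn: bool = True,
        use_gcn: bool = True,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.fs = fs
        self.variants = variants
        self.band = band
        self.welch_seg_s = welch_seg_s
        self.welch_overlap = welch_overlap
        self.n_scales = n_scales
        self.kernels_per_scale = kernels_per_scale
        self.pool_len = pool_len
        self.pool_stride = pool_stride
        self.log_floor = log_floor
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.lam = lam
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.use_kernel_attention = use_kernel_attention
        self.use_adjacency_attention = use_adjacency_attention
        self.use_cnn = use_cnn
        self.use_gcn = use_gcn
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ---------------------------------------------------------------
    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_segments, C, T), got shape {X.shape}")
        return X

    def _conn_cfg(self, method: str) -> ConnectivityConfig:
        return ConnectivityConfig(
            method=method,
            band=tuple(self.band),
            welch_seg_s=self.welch_seg_s,
            welch_overlap=self.welch_overlap,
        )

    def _segments_from_arrays(self, X, labels) -> list[Segment]:
        chans = [f"ch{i}" for i in range(X.shape[1])]
        return [
            Segment(
                data=X[i], fs=self.fs, channels=list(chans), label=str(labels[i]),
                trial_id=f"seg{i}", parent_trial_id=f"seg{i}", start=0,
            )
            for i in range(len(X))
        ]

    def build_adjacency(self, X, y) -> dict[str, TaskAdjacency]:
        """Task-specific adjacency per variant from labelled segments."""
        X = self._validate_X(X)
        segs = self._segments_from_arrays(X, y)
        labels = tuple(str(c) for c in np.unique(np.asarray(y).astype(str)))
        return {
            v: build_task_adjacency(segs, self._conn_cfg(v), labels=labels)
            for v in self.variants
        }

    def _adjacency_pairs(self, adjacency: dict) -> dict:
        l1, l2 = [str(c) for c in self.classes_]
        return {v: (ta.norm[l1], ta.norm[l2]) for v, ta in adjacency.items()}

    # -- estimator API ---------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None, adjacency=None):
        """Train on segments; optional validation split drives early stopping.

        ``adjacency`` may carry precomputed :class:`TaskAdjacency` per
        variant (e.g. averaged from cached per-segment matrices by the
        cross-validation driver); otherwise it is built here from (X, y).
        """
        X = self._validate_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"binary classifier: got classes {self.classes_}")
        y_idx = np.searchsorted(self.classes_, y)
        if self.use_gcn:
            if adjacency is None:
                adjacency = self.build_adjacency(X, y)
            self.adjacency_ = adjacency
        else:
            self.adjacency_ = {}

        rng = np.random.default_rng(self.random_state)
        self.network_ = TSANNNetwork(
            X.shape[1], X.shape[2], self.fs, tuple(self.variants),
            n_scales=self.n_scales, kernels_per_scale=self.kernels_per_scale,
            pool_len=self.pool_len, pool_stride=self.pool_stride,
            log_floor=self.log_floor, hidden1=self.hidden1, hidden2=self.hidden2,
            use_kernel_attention=self.use_kernel_attention,
            use_adjacency_attention=self.use_adjacency_attention,
            use_cnn=self.use_cnn, use_gcn=self.use_gcn, rng=rng,
        )
        if self.use_gcn:
            self.network_.set_adjacency(self._adjacency_pairs(self.adjacency_))
        self._optimizer = self.network_.make_optimizer(self.learning_rate)
        self.history_ = []
        self.n_epochs_ = 0

        has_val = X_val is not None
        if has_val:
            X_val = self._validate_X(X_val)
            yv_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        best_loss, best_state, since_best = np.inf, None, 0
        for epoch in range(self.max_epochs):
            train_loss = self._run_epoch(X, y_idx, rng)
            rec = {"epoch": epoch, "train_loss": train_loss}
            if has_val:
                val_loss, val_acc = self._evaluate(X_val, yv_idx)
                rec.update(val_loss=val_loss, val_acc=val_acc)
                monitored = val_loss
            else:
                monitored = train_loss
            if not np.isfinite(monitored):
                raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
            self.history_.append(rec)
            self.n_epochs_ = epoch + 1
            if self.verbose:
                print(f"epoch {epoch}: {rec}")
            if monitored < best_loss - self.tol:
                best_loss, since_best = monitored, 0
                best_state = self.network_.state_dict()
            else:
                since_best += 1
                if since_best > self.patience:
                    break
        if best_state is not None:
            self.network_.load_state_dict(best_state)
        if has_val:
            vl, va = self._evaluate(X_val, yv_idx)
            self.validation_loss_, self.validation_accuracy_ = vl, va
        return self

    def finetune(self, X, y, epochs: int, adjacency=None):
        """Continue training the fitted network (no early stopping).

        Used after inner-loop model selection: adjacency is typically
        rebuilt from the enlarged training set and training resumes for a
        fixed number of epochs.
        """
        check_is_fitted(self, "network_")
        X = self._validate_X(X)
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        if adjacency is not None and self.use_gcn:
            self.adjacency_ = adjacency
            self.network_.set_adjacency(self._adjacency_pairs(adjacency))
        rng = np.random.default_rng(self.random_state + 1)
        self._optimizer = self.network_.make_optimizer(self.learning_rate)
        for epoch in range(epochs):
            tl = self._run_epoch(X, y_idx, rng)
            if not np.isfinite(tl):
                raise FloatingPointError(f"fine-tuning diverged at epoch {epoch}")
            self.history_.append({"finetune_epoch": epoch, "train_loss": tl})
        return self

    def _run_epoch(self, X, y_idx, rng) -> float:
        order = rng.permutation(len(X))
        total, nb = 0.0, 0
        for start in range(0, len(X), self.batch_size):
            sel = order[start : start + self.batch_size]
            loss = self.network_.loss(X[sel], y_idx[sel], lam=self.lam)
            self._optimizer.zero_grad()
            loss.backward()
            self._optimizer.step()
            total += float(loss.data)
            nb += 1
        return total / max(nb, 1)

    def _evaluate(self, X, y_idx, batch: int = 256) -> tuple[float, float]:
        losses, correct = [], 0
        for start in range(0, len(X), batch):
            xb, yb = X[start : start + batch], y_idx[start : start + batch]
            logits = self.network_.forward(xb).data
            losses.append(_xent(logits, yb) * len(xb))
            correct += int((logits.argmax(axis=1) == yb).sum())
        return float(sum(losses) / len(X)), correct / len(X)

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._validate_X(X)
        out = []
        for start in range(0, len(X), 256):
            out.append(self.network_.forward(X[start : start + 256]).data)
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_scores(X)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.decision_scores(X).argmax(axis=1)]

    @property
    def n_parameters_(self) -> int:
        check_is_fitted(self, "network_")
        return self.network_.parameter_count()


def _xent(logits: np.ndarray, y_idx: np.ndarray) -> float:
    shifted = logits - logits.max(axis=1, keepdims=True)
    lp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return float(-lp[np.arange(len(y_idx)), y_idx].mean())
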