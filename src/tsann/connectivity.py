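"""Functional connectivity and task-specific (class-conditioned) adjacency.

Four pairwise measures over the C channels of one segment:

* **Cor** — Pearson correlation over time samples, in [-1, 1];
* **Coh** — magnitude-squared coherence |S_ab|^2 / (S_aa S_bb) from Welch
  cross-spectra, averaged over the frequency bins inside the analysis band,
  in [0, 1];
* **PLV** — phase-locking value |E[exp(i dphi(t))]| of the instantaneous
  phase difference (band-passed analytic signal), in [0, 1];
* **PLI** — phase-lag index |E[sign(sin dphi(t))]|, in [0, 1], blind to
  zero-lag coupling.

A *task-specific adjacency* is one matrix per class label, the element-wise
mean of the per-segment connectivity matrices of that class's **training**
segments only (correlation enters through its absolute value so all weights
are nonnegative), with the diagonal then fixed to 1 (self-loops) and the
result symmetrically normalized ``D^(-1/2) A D^(-1/2)`` for graph
convolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .data import EEGTrial, Segment, bandpass

__all__ = [
    "ConnectivityConfig",
    "TaskAdjacency",
    "pearson_matrix",
    "coherence_matrix",
    "plv_matrix",
    "pli_matrix",
    "phase_difference",
    "plv_from_phase_difference",
    "pli_from_phase_difference",
    "select_by_label",
    "connectivity_matrix",
    "build_task_adjacency",
    "normalize_adjacency",
]

METHODS = ("cor", "coh", "plv", "pli")

#: seconds of analytic-signal phase discarded at each segment edge to
#: suppress filter / Hilbert-transform transients
EDGE_DISCARD_S = 1.0


@dataclass
class ConnectivityConfig:
    """Parameters shared by the spectral/phase measures.

    band
        (lo, hi) in Hz; used by Coh for bin selection and by PLV/PLI for the
        band-pass before phase extraction.
    welch_seg_s, welch_overlap
        Welch segment length (seconds) and overlap fraction (Hann window).
    """

    method: str = "plv"
    band: tuple[float, float] = (4.0, 45.0)
    welch_seg_s: float = 1.0
    welch_overlap: float = 0.5

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError(f"invalid band {self.band}")
        if not (0 <= self.welch_overlap < 1):
            raise ValueError("welch_overlap must be in [0, 1)")
        if self.welch_seg_s <= 0:
            raise ValueError("welch_seg_s must be positive")


@dataclass
class TaskAdjacency:
    """A pair of class-conditioned C x C adjacencies and their normalized forms."""

    method: str
    labels: tuple[str, str]
    adj: dict  # label -> raw nonnegative symmetric C x C with unit diagonal
    norm: dict = field(default_factory=dict)  # label -> D^(-1/2) A D^(-1/2)

    def __post_init__(self):
        if not self.norm:
            self.norm = {l: normalize_adjacency(a) for l, a in self.adj.items()}


def pearson_matrix(segment: EEGTrial) -> np.ndarray:
    """Pearson correlation between every channel pair, over time samples.

    Zero-variance channels get zero off-diagonal entries (with a warning)
    rather than NaN; the diagonal is always 1.
    """
    x = segment.data
    sd = x.std(axis=1)
    dead = sd == 0
    if dead.any():
        names = [segment.channels[i] for i in np.flatnonzero(dead)]
        warnings.warn(f"zero-variance channel(s) {names}: correlation entries set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip((r + r.T) / 2.0, -1.0, 1.0)


def _welch_params(segment: EEGTrial, cfg: ConnectivityConfig):
    nperseg = int(round(cfg.welch_seg_s * segment.fs))
    nperseg = min(nperseg, segment.n_samples)
    noverlap = int(round(cfg.welch_overlap * nperseg))
    return nperseg, noverlap


def coherence_matrix(segment: EEGTrial, cfg: ConnectivityConfig) -> np.ndarray:
    """Band-averaged magnitude-squared coherence between every channel pair.

    Welch cross-spectra with a Hann window; the coherence spectrum is
    collapsed to a scalar per pair by the unweighted mean over the bins
    inside ``cfg.band``. Note that with a single Welch segment coherence is
    identically 1 for any pair.
    """
    nperseg, noverlap = _welch_params(segment, cfg)
    x = segment.data
    f, sxx = sps.csd(
        x[:, None, :], x[None, :, :], fs=segment.fs, window="hann",
        nperseg=nperseg, noverlap=noverlap, axis=-1,
    )
    lo, hi = cfg.band
    keep = (f >= lo) & (f <= hi)
    if not keep.any():
        raise ValueError(f"band {cfg.band} Hz contains no frequency bins (df={f[1]-f[0]:g} Hz)")
    auto = np.einsum("iif->if", sxx).real  # S_aa(f)
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxx) ** 2 / denom
    coh = np.nan_to_num(coh, nan=0.0)
    m = coh[:, :, keep].mean(axis=-1)
    m = np.clip((m + m.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return m


def _analytic_phase(segment: EEGTrial, cfg: ConnectivityConfig) -> np.ndarray:
    """Instantaneous phase per channel: band-pass, Hilbert, discard 1 s edges."""
    edge = int(round(EDGE_DISCARD_S * segment.fs))
    if segment.n_samples <= 2 * edge + int(round(segment.fs)):
        raise ValueError(
            f"segment {segment.trial_id!r} too short for phase analysis: "
            f"need > {3 * EDGE_DISCARD_S:g} s, got {segment.duration:g} s"
        )
    filtered = bandpass(segment, *cfg.band)
    analytic = sps.hilbert(filtered.data, axis=1)
    return np.angle(analytic[:, edge:-edge])


def phase_difference(phi_a: np.ndarray, phi_b: np.ndarray) -> np.ndarray:
    """Phase-difference series wrapped to (-pi, pi]."""
    d = phi_a - phi_b
    return np.angle(np.exp(1j * d))


def plv_from_phase_difference(dphi: np.ndarray) -> float:
    """|E[exp(i dphi)]| — the phase-locking value of a difference series."""
    return float(np.abs(np.exp(1j * np.asarray(dphi)).mean()))


def pli_from_phase_difference(dphi: np.ndarray) -> float:
    """|E[sign(sin dphi)]| — the phase-lag index of a difference series."""
    return float(np.abs(np.sign(np.sin(np.asarray(dphi))).mean()))


def plv_matrix(segment: EEGTrial, cfg: ConnectivityConfig) -> np.ndarray:
    """Phase-locking value |E[exp(i dphi(t))]| for every channel pair."""
    phi = _analytic_phase(segment, cfg)
    z = np.exp(1j * phi)
    n = z.shape[1]
    plv = np.abs(z @ z.conj().T) / n
    plv = np.clip((plv + plv.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(plv, 1.0)
    return plv


def pli_matrix(segment: EEGTrial, cfg: ConnectivityConfig) -> np.ndarray:
    """Phase-lag index |E[sign(sin dphi(t))]| for every channel pair.

    The raw diagonal is 0 (a channel has no lag against itself); exact
    zero-lag samples contribute sign(0) = 0.
    """
    phi = _analytic_phase(segment, cfg)
    # sin of the raw difference equals sin of the wrapped difference, and
    # identical phases subtract to exactly 0; C x C x t is small for EEG C
    dphi = phi[:, None, :] - phi[None, :, :]
    pli = np.abs(np.sign(np.sin(dphi)).mean(axis=-1))
    pli = np.clip((pli + pli.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(pli, 0.0)
    return pli


_MATRIX_FN = {
    "cor": lambda seg, cfg: pearson_matrix(seg),
    "coh": coherence_matrix,
    "plv": plv_matrix,
    "pli": pli_matrix,
}


def connectivity_matrix(segment: EEGTrial, cfg: ConnectivityConfig) -> np.ndarray:
    """Dispatch to the measure named by ``cfg.method``."""
    return _MATRIX_FN[cfg.method](segment, cfg)


def select_by_label(items: Sequence, label: str):
    """All trials/segments with the given label, in original order."""
    out = [it for it in items if it.label == label]
    if not out:
        raise ValueError(f"class {label!r} has no data")
    return out


def build_task_adjacency(
    training_segments: Sequence[Segment],
    cfg: ConnectivityConfig,
    labels: tuple[str, str] | None = None,
    matrices: np.ndarray | None = None,
) -> TaskAdjacency:
    """Average per-segment connectivity within each class and normalize.

    ``matrices`` may carry precomputed per-segment connectivity (aligned
    with ``training_segments``) so that repeated fold-wise averaging does
    not recompute spectra; otherwise matrices are computed here.
    """
    if labels is None:
        labels = tuple(sorted({s.label for s in training_segments}))
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {labels}")
    if matrices is None:
        matrices = np.stack([connectivity_matrix(s, cfg) for s in training_segments])
    seg_labels = np.array([s.label for s in training_segments])
    adj = {}
    for lab in labels:
        mask = seg_labels == lab
        if not mask.any():
            raise ValueError(f"class {lab!r} has no training data")
        mats = matrices[mask]
        if cfg.method == "cor":
            mats = np.abs(mats)
        a = mats.mean(axis=0)
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
        adj[lab] = a
    return TaskAdjacency(method=cfg.method, labels=labels, adj=adj)


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric normalization ``A~ = D^(-1/2) A D^(-1/2)``, D_aa = sum_b A_ab."""
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any():
        raise ValueError("adjacency must be nonnegative")
    deg = a.sum(axis=1)
    zero = deg <= 0
    if zero.any():
        raise ValueError(f"zero row sum at channel index(es) {np.flatnonzero(zero).tolist()}")
    inv_sqrt = 1.0 / np.sqrt(deg)
    return a * inv_sqrt[:, None] * inv_sqrt[None, :]
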