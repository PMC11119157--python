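"""Trial containers, band-pass filtering and overlapping-window segmentation.

An :class:`EEGTrial` is the atomic input: a channels x samples matrix in
microvolts with a sampling rate, ordered channel names and a binary class
label. Trials are band-pass filtered (zero-phase Butterworth) and cut into
overlapping windows (:class:`Segment`); the windows, not the trials, are the
unit the classifier consumes, but cross-validation assignments are always
keyed on the parent trial so that no window of a held-out trial leaks into
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "EEGTrial",
    "Segment",
    "SegmentationConfig",
    "segment_trial",
    "segment_trials",
    "bandpass",
]


@dataclass
class EEGTrial:
    """One recording epoch: C channels x T samples, with label and metadata."""

    data: np.ndarray
    fs: float
    channels: Sequence[str]
    label: str
    trial_id: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"trial {self.trial_id!r}: data must be 2-D (C x T)")
        c, t = self.data.shape
        if c < 2:
            raise ValueError(f"trial {self.trial_id!r}: need at least 2 channels, got {c}")
        if t < 1:
            raise ValueError(f"trial {self.trial_id!r}: empty trial")
        if self.fs <= 0:
            raise ValueError(f"trial {self.trial_id!r}: fs must be positive")
        self.channels = list(self.channels)
        if len(self.channels) != c:
            raise ValueError(
                f"trial {self.trial_id!r}: {len(self.channels)} channel names for {c} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"trial {self.trial_id!r}: duplicate channel names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment(EEGTrial):
    """A window cut from a trial; inherits the trial's label."""

    parent_trial_id: str = ""
    start: int = 0  # start index in samples, 0-based, within the parent trial


@dataclass
class SegmentationConfig:
    """Overlapping-window parameters, in seconds.

    ``step = window_s - overlap_s``: a 4 s window with 2 s overlap advances
    by 2 s per window.
    """

    window_s: float = 4.0
    overlap_s: float = 2.0

    def __post_init__(self):
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not (0 <= self.overlap_s < self.window_s):
            raise ValueError("overlap_s must satisfy 0 <= overlap_s < window_s")


def segment_trial(trial: EEGTrial, cfg: SegmentationConfig) -> list[Segment]:
    """Cut a trial into half-open windows ``[s, s+w)``; drop the incomplete tail.

    Window length and step are converted from seconds to samples by rounding;
    the number of windows is ``floor((T - w) / step) + 1``.
    """
    w = int(round(cfg.window_s * trial.fs))
    step = int(round((cfg.window_s - cfg.overlap_s) * trial.fs))
    if step < 1:
        raise ValueError("window/overlap too close: step rounds to 0 samples")
    t = trial.n_samples
    if w > t:
        raise ValueError(
            f"trial {trial.trial_id!r}: window of {w} samples exceeds trial length {t}"
        )
    n = (t - w) // step + 1
    out = []
    for i in range(n):
        s = i * step
        out.append(
            Segment(
                data=trial.data[:, s : s + w].copy(),
                fs=trial.fs,
                channels=list(trial.channels),
                label=trial.label,
                trial_id=f"{trial.trial_id}/seg{i}",
                parent_trial_id=trial.trial_id,
                start=s,
            )
        )
    return out


def segment_trials(trials: Sequence[EEGTrial], cfg: SegmentationConfig) -> list[Segment]:
    segs: list[Segment] = []
    for tr in trials:
        segs.extend(segment_trial(tr, cfg))
    return segs


def bandpass(trial: EEGTrial, lo_hz: float, hi_hz: float) -> EEGTrial:
    """Zero-phase band-pass (4th-order Butterworth, forward-backward).

    Applied channel-wise; shape is preserved. The band must sit strictly
    inside (0, fs/2).
    """
    nyq = trial.fs / 2.0
    if not (0 < lo_hz < hi_hz < nyq):
        raise ValueError(
            f"band ({lo_hz}, {hi_hz}) Hz outside (0, {nyq}) Hz for fs={trial.fs}"
        )
    sos = signal.butter(4, [lo_hz, hi_hz], btype="bandpass", fs=trial.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, trial.data, axis=1)
    return replace(trial, data=np.ascontiguousarray(filtered))
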