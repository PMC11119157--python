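"""Dataset I/O: the HDF5 trial container, EDF input, and the label manifest.

HDF5 layout (the package's on-disk contract)::

    /trials/<trial_id>/data   float32, C x T
    /trials/<trial_id>@fs     sampling rate (Hz)
    /trials/<trial_id>@label  class label (string)
    /trials/<trial_id>@channels  ordered channel names

EDF (European Data Format) files are read through :mod:`mne`, one trial per
file, with labels supplied by a CSV manifest (columns ``trial_id,label``;
``trial_id`` is the file stem). A minimal EDF writer is included for
round-trip tooling; EDF stores 16-bit samples, so writing quantizes to
~1/65535 of the per-channel amplitude range.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .data import EEGTrial

__all__ = [
    "save_dataset",
    "load_dataset",
    "load_edf_trial",
    "load_edf_dataset",
    "read_label_manifest",
    "write_edf",
]


def save_dataset(trials: Sequence[EEGTrial], path) -> None:
    """Write trials to the HDF5 container (32-bit float data)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("trials")
        for tr in trials:
            g = grp.create_group(tr.trial_id)
            g.create_dataset("data", data=tr.data.astype(np.float32))
            g.attrs["fs"] = float(tr.fs)
            g.attrs["label"] = tr.label
            g.attrs["channels"] = [str(c) for c in tr.channels]


def load_dataset(path) -> list[EEGTrial]:
    """Load trials from the HDF5 container; errors if sampling rates differ."""
    trials = []
    with h5py.File(path, "r") as f:
        if "trials" not in f:
            raise ValueError(f"{path}: not a trial container (missing /trials group)")
        for tid in f["trials"]:
            g = f["trials"][tid]
            trials.append(
                EEGTrial(
                    data=np.asarray(g["data"], dtype=np.float64),
                    fs=float(g.attrs["fs"]),
                    channels=[
                        c.decode() if isinstance(c, bytes) else str(c)
                        for c in g.attrs["channels"]
                    ],
                    label=str(g.attrs["label"]),
                    trial_id=tid,
                )
            )
    _check_uniform_fs(trials)
    return trials


def _check_uniform_fs(trials: Sequence[EEGTrial]) -> None:
    rates = {tr.fs for tr in trials}
    if len(rates) > 1:
        raise ValueError(f"sampling rate mismatch across trials: {sorted(rates)}")


def read_label_manifest(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    missing = {"trial_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"label manifest {path}: missing columns {sorted(missing)}")
    return dict(zip(df["trial_id"], df["label"]))


def load_edf_trial(path, label: str, trial_id: str | None = None) -> EEGTrial:
    """Read one EDF file as one trial (all channels, full duration)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6  # mne returns volts; container is microvolts
    return EEGTrial(
        data=data,
        fs=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        label=label,
        trial_id=trial_id if trial_id is not None else Path(path).stem,
    )


def load_edf_dataset(edf_dir, manifest_path) -> list[EEGTrial]:
    """Read every ``*.edf`` in a directory, labelled by the manifest.

    Every EDF file must have a manifest entry and vice versa; the error
    names the offending trial ids.
    """
    edf_dir = Path(edf_dir)
    labels = read_label_manifest(manifest_path)
    files = {p.stem: p for p in sorted(edf_dir.glob("*.edf"))}
    unlabelled = sorted(set(files) - set(labels))
    if unlabelled:
        raise ValueError(f"no label for trial(s): {unlabelled}")
    unknown = sorted(set(labels) - set(files))
    if unknown:
        raise ValueError(f"manifest names unknown trial(s): {unknown}")
    trials = [load_edf_trial(files[tid], labels[tid], tid) for tid in sorted(files)]
    _check_uniform_fs(trials)
    return trials


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(trial: EEGTrial, path) -> None:
    """Write a trial as a single-record EDF file (16-bit samples).

    One data record spanning the whole trial; physical range is the
    per-channel data range, digital range -32768..32767.
    """
    c, t = trial.data.shape
    with open(path, "wb") as f:
        header_bytes = 256 * (c + 1)
        f.write(_ascii("0", 8))
        f.write(_ascii("synthetic", 80))
        f.write(_ascii("tsann export", 80))
        f.write(_ascii("01.01.00", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(header_bytes, 8))
        f.write(_ascii("", 44))
        f.write(_ascii(1, 8))  # number of data records
        f.write(_ascii(f"{t / trial.fs:g}", 8))  # record duration (s)
        f.write(_ascii(c, 4))
        def fit8(v: float) -> str:
            # shortest representation that fits the 8-char EDF field
            for prec in range(6, 0, -1):
                s = f"{v:.{prec}g}"
                if len(s) <= 8:
                    return s
            return f"{v:.0e}"[:8]

        pmins, pmaxs, pmin_s, pmax_s = [], [], [], []
        for ch in range(c):
            lo, hi = float(trial.data[ch].min()), float(trial.data[ch].max())
            if hi <= lo:
                hi = lo + 1.0
            # pad the range by 1% so the 8-char rounded header values still bracket the data,
            # then quantize against the values the header actually carries
            margin = 0.01 * (hi - lo)
            pmin_s.append(fit8(lo - margin))
            pmax_s.append(fit8(hi + margin))
            pmins.append(float(pmin_s[-1]))
            pmaxs.append(float(pmax_s[-1]))
        for name in trial.channels:
            f.write(_ascii(name, 16))
        for _ in range(c):
            f.write(_ascii("", 80))  # transducer
        for _ in range(c):
            f.write(_ascii("uV", 8))
        for s in pmin_s:
            f.write(_ascii(s, 8))
        for s in pmax_s:
            f.write(_ascii(s, 8))
        for _ in range(c):
            f.write(_ascii(-32768, 8))
        for _ in range(c):
            f.write(_ascii(32767, 8))
        for _ in range(c):
            f.write(_ascii("", 80))  # prefiltering
        for _ in range(c):
            f.write(_ascii(t, 8))  # samples per record
        for _ in range(c):
            f.write(_ascii("", 32))
        for ch in range(c):
            lo, hi = pmins[ch], pmaxs[ch]
            scaled = (trial.data[ch] - lo) / (hi - lo) * 65535.0 - 32768.0
            dig = np.clip(np.round(scaled), -32768, 32767).astype("<i2")
            f.write(dig.tobytes())
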