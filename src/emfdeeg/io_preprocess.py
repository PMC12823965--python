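"""Reading, band-limiting and windowing of multichannel EEG.

Recordings enter either as EDF files or as delimited text (one column per
channel, with a small sidecar describing sampling rate, labels, condition
and subject).  Filtering is zero-phase Butterworth and slicing produces
fixed-length labeled windows ready for decomposition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Older 10-20 temporal/posterior labels accepted as synonyms of the
#: modified-combinatorial names.  Applied only on explicit request,
#: never silently.
LABEL_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}


@dataclass(frozen=True)
class Signal:
    """One channel's samples (microvolts) with sampling rate and label."""

    samples: np.ndarray
    fs: float
    channel: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"non-finite samples in channel {self.channel!r}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class RawRecording:
    """Ordered multichannel recording for one subject and condition."""

    channels: tuple[Signal, ...]
    subject_id: str
    condition: str

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        if not self.channels:
            raise ValueError("recording has no channels")
        fs = {c.fs for c in self.channels}
        if len(fs) != 1:
            raise ValueError(f"channels disagree on sampling rate: {sorted(fs)}")
        lengths = {len(c) for c in self.channels}
        if len(lengths) != 1:
            raise ValueError(f"channels disagree on length: {sorted(lengths)}")
        labels = [c.channel for c in self.channels]
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise ValueError(f"duplicate channel labels: {dupes}")
        if self.condition not in ("task", "rest"):
            raise ValueError(f"condition must be 'task' or 'rest', got {self.condition!r}")

    @property
    def fs(self) -> float:
        return self.channels[0].fs

    @property
    def labels(self) -> list[str]:
        return [c.channel for c in self.channels]

    @property
    def n_samples(self) -> int:
        return len(self.channels[0])

    def to_array(self) -> np.ndarray:
        """Channels x samples array."""
        return np.stack([c.samples for c in self.channels])


@dataclass(frozen=True)
class Segment:
    """One fixed-length window of a recording, with its provenance."""

    data: np.ndarray  # channels x (window_s * fs)
    labels: tuple[str, ...]
    fs: float
    condition: str
    subject_id: str
    window_index: int

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", tuple(self.labels))
        if data.shape[0] != len(self.labels):
            raise ValueError("row count does not match channel labels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


def _normalize_label(label: str, apply_aliases: bool = False) -> str:
    lab = label.strip().upper()
    # EDF headers often carry prefixes like "EEG Fp1" or "EEG Fp1-REF"
    for prefix in ("EEG ", "EEG"):
        if lab.startswith(prefix) and len(lab) > len(prefix):
            lab = lab[len(prefix):].strip()
            break
    lab = lab.split("-")[0].strip()
    if apply_aliases:
        lab = LABEL_ALIASES.get(lab, lab)
    return lab


def read_edf(path: str | Path, subject_id: str = "", condition: str = "rest",
             apply_aliases: bool = False) -> RawRecording:
    """Read a European Data Format file into a :class:`RawRecording`.

    Channel labels are normalized to upper-case 10-20 names; the sampling
    rate is taken from the header and must be uniform across channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    labels = [_normalize_label(name, apply_aliases) for name in raw.ch_names]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate channel labels after normalization: {dupes}")
    channels = [Signal(row, fs, lab) for row, lab in zip(data, labels)]
    return RawRecording(tuple(channels), subject_id=subject_id or path.stem,
                        condition=condition)


def read_delimited(path: str | Path, fs: float | None = None,
                   labels: Sequence[str] | None = None,
                   subject_id: str = "", condition: str = "rest",
                   sep: str = ",") -> RawRecording:
    """Read a delimited recording (one column per channel).

    If a sidecar ``<path>.json`` exists its ``fs``/``labels``/``condition``/
    ``subject_id`` entries supply any argument not given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fs = fs if fs is not None else meta.get("fs")
    labels = list(labels) if labels is not None else meta.get("labels")
    subject_id = subject_id or meta.get("subject_id", path.stem)
    condition = meta.get("condition", condition) if "condition" in meta and condition == "rest" else condition
    if fs is None:
        raise ValueError("sampling rate not given and no sidecar provides it")

    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.empty:
        raise ValueError(f"empty recording file: {path}")
    try:
        data = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    if labels is None:
        labels = [f"CH{i + 1}" for i in range(data.shape[1])]
    if data.shape[1] != len(labels):
        raise ValueError(
            f"{path}: {data.shape[1]} columns but {len(labels)} channel labels")
    labels = [_normalize_label(l) for l in labels]
    channels = [Signal(data[:, j], float(fs), labels[j]) for j in range(len(labels))]
    return RawRecording(tuple(channels), subject_id=subject_id, condition=condition)


def write_delimited(rec: RawRecording, path: str | Path, sep: str = ",") -> Path:
    """Write a recording as delimited text plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, rec.to_array().T, delimiter=sep, fmt="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "fs": rec.fs, "labels": rec.labels,
        "condition": rec.condition, "subject_id": rec.subject_id,
    }))
    return path


def _butter_sos(low: float, high: float | None, order: int, fs: float):
    nyq = fs / 2.0
    if high is None:
        if not 0 < low < nyq:
            raise ValueError(f"high-pass cutoff {low} Hz outside (0, {nyq})")
        return sps.butter(order, low, btype="highpass", fs=fs, output="sos")
    if not (0 <= low < high < nyq):
        raise ValueError(
            f"cutoffs must satisfy 0 <= low < high < fs/2; got ({low}, {high}) at fs={fs}")
    if low == 0:
        return sps.butter(order, high, btype="lowpass", fs=fs, output="sos")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(sig: Signal, low: float, high: float | None = 45.0,
             order: int = 4) -> Signal:
    """Zero-phase (forward-backward) Butterworth band-limit of one channel.

    ``high=None`` gives a high-pass-only filter at ``low`` Hz.  Output has
    the same length and sampling rate; phase is preserved, which the
    downstream spectral decomposition assumes.
    """
    sos = _butter_sos(low, high, order, sig.fs)
    # a sub-Hz high-pass edge has a multi-second impulse response; default
    # padding is far too short for it and leaks transients across the window
    padlen = len(sig) - 1
    if low > 0:
        padlen = min(padlen, int(3 * sig.fs / low))
    filtered = sps.sosfiltfilt(sos, sig.samples, padlen=padlen)
    return replace(sig, samples=filtered)


def notch(sig: Signal, freq: float = 50.0, q: float = 30.0) -> Signal:
    """Optional zero-phase line-noise notch (off by default in presets)."""
    b, a = sps.iirnotch(freq, q, fs=sig.fs)
    return replace(sig, samples=sps.filtfilt(b, a, sig.samples))


def common_average_reference(rec: RawRecording) -> RawRecording:
    """Subtract the instantaneous mean across channels (CAR) per sample."""
    data = rec.to_array()
    data = data - data.mean(axis=0, keepdims=True)
    channels = [replace(c, samples=data[i]) for i, c in enumerate(rec.channels)]
    return replace(rec, channels=tuple(channels))


def channel_mean_reference(rec: RawRecording) -> RawRecording:
    """Subtract each channel's own temporal mean."""
    channels = [replace(c, samples=c.samples - c.samples.mean())
                for c in rec.channels]
    return replace(rec, channels=tuple(channels))


def preprocess(rec: RawRecording, preset: str = "mat",
               low: float | None = None, high: float | None = None,
               order: int = 4, line_notch: bool = False) -> RawRecording:
    """Apply a dataset preset's filtering chain.

    ``mat``: 0.5-45 Hz band-pass.  ``stew``: 1 Hz high-pass followed by
    common-average re-referencing.  ``custom`` uses the explicit cutoffs.
    """
    if preset == "mat":
        lo, hi = 0.5, 45.0
    elif preset == "stew":
        lo, hi = 1.0, None
    elif preset == "custom":
        if low is None:
            raise ValueError("custom preset requires explicit cutoffs")
        lo, hi = low, high
    else:
        raise ValueError(f"unknown preset {preset!r}")
    channels = tuple(bandpass(c, lo, hi, order) for c in rec.channels)
    out = replace(rec, channels=channels)
    if line_notch:
        out = replace(out, channels=tuple(notch(c) for c in out.channels))
    if preset == "stew":
        out = common_average_reference(out)
    return out


def segment_record(rec: RawRecording, window_s: float = 4.0,
                   overlap_s: float = 0.0) -> list[Segment]:
    """Slice a recording into fixed-length windows.

    Default stride equals the window (no overlap); a trailing partial
    window is discarded.  A recording shorter than one window yields an
    empty list with a logged warning.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0 <= overlap_s < window_s:
        raise ValueError("overlap_s must lie in [0, window_s)")
    win = int(round(window_s * rec.fs))
    step = int(round((window_s - overlap_s) * rec.fs))
    n = rec.n_samples
    if n < win:
        logger.warning("recording %s/%s shorter (%d samples) than one %g-s window",
                       rec.subject_id, rec.condition, n, window_s)
        return []
    data = rec.to_array()
    segments = []
    for idx, start in enumerate(range(0, n - win + 1, step)):
        segments.append(Segment(data[:, start:start + win], tuple(rec.labels),
                                rec.fs, rec.condition, rec.subject_id, idx))
    return segments
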