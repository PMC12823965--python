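"""Synthetic two-condition multichannel EEG with lobe-localized effects.

Each channel is a 1/f-shaped background plus narrowband-filtered-noise
oscillators in the theta (4-7 Hz), alpha (8-12 Hz) and beta (13-30 Hz)
bands.  Under the task condition, frontal-lobe channels receive a theta
amplitude gain, all channels an alpha amplitude suppression, and all
channels an extra broadband-noise admixture (the irregularity effect) —
the classic frontal-theta / alpha-modulation signature of mental effort.
Oscillators are filtered noise rather than pure tones so that the
entropy features downstream are non-degenerate.

Per-subject band gains are log-normal, drawn once per subject (shared by
that subject's rest and task recordings), which makes subject-grouped
cross-validation genuinely harder than segment-level CV.  Everything is
bitwise reproducible from ``(seed, subject, condition)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_preprocess import RawRecording, Segment, Signal, preprocess, segment_record
from .lobe_montage import build_montage

BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (13.0, 30.0)}

_PRESET_FS = {"mat19": 500.0, "stew14": 128.0}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings: montage, protocol durations, and effect sizes.

    Amplitudes are microvolt RMS.  ``frontal_theta_gain`` multiplies the
    theta oscillator amplitude on frontal channels under task;
    ``alpha_suppression`` (<= 1) multiplies the alpha amplitude on every
    channel under task; ``irregularity_delta`` adds that fraction of the
    background amplitude as extra white noise under task.
    ``inter_subject_sd`` is the SD of the per-subject log-normal band
    gains.  A value of 1.0 / 1.0 / 0.0 is the null (no-effect) setting.
    """

    montage_id: str = "stew14"
    fs: float | None = None
    rest_duration_s: float = 60.0
    task_duration_s: float = 60.0
    n_subjects: int = 10
    background_exponent: float = 1.0
    background_amp: float = 20.0
    band_amps: dict = field(default_factory=lambda: {
        "theta": 6.0, "alpha": 8.0, "beta": 4.0})
    frontal_theta_gain: float = 2.5
    alpha_suppression: float = 0.7
    irregularity_delta: float = 0.1
    inter_subject_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.rest_duration_s <= 0 or self.task_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.frontal_theta_gain <= 0 or self.alpha_suppression <= 0:
            raise ValueError("gains must be positive")
        fs = self.fs
        preset_fs = _PRESET_FS.get(self.montage_id)
        if fs is None:
            if preset_fs is None:
                raise ValueError("fs required for a custom montage")
            object.__setattr__(self, "fs", preset_fs)
        elif preset_fs is not None and fs != preset_fs:
            raise ValueError(
                f"montage {self.montage_id} implies fs={preset_fs}, got {fs}")

    @property
    def preset(self) -> str:
        """Preprocessing preset matching the montage."""
        return "mat" if self.montage_id == "mat19" else "stew"


def strong_config(**overrides) -> SynthConfig:
    """The strong-effect study setting (frontal theta x2.5, alpha x0.7)."""
    return SynthConfig(**overrides)


def null_config(**overrides) -> SynthConfig:
    """No condition effect at all: task and rest are exchangeable."""
    overrides.setdefault("frontal_theta_gain", 1.0)
    overrides.setdefault("alpha_suppression", 1.0)
    overrides.setdefault("irregularity_delta", 0.0)
    return SynthConfig(**overrides)


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped white noise with 1/f^exponent power, unit RMS."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spectrum * shaping, n=n)
    return x / x.std()


def _band_oscillation(n: int, fs: float, band: tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    """Narrowband-filtered white noise, unit RMS."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + int(2 * fs)))[int(fs):int(fs) + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _subject_gains(config: SynthConfig, subject_index: int) -> dict[str, float]:
    """Per-subject log-normal gain per band, shared across conditions."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1000 + subject_index]))
    return {band: float(rng.lognormal(0.0, config.inter_subject_sd))
            for band in BANDS}


def generate_record(config: SynthConfig, subject: int | str,
                    condition: str) -> RawRecording:
    """One synthetic recording for a subject under one condition."""
    if condition not in ("task", "rest"):
        raise ValueError(f"condition must be 'task' or 'rest', got {condition!r}")
    sub_idx = int(str(subject).lstrip("S")) if isinstance(subject, str) else int(subject)
    montage = build_montage(config.montage_id)
    labels = sorted(montage.channels)
    frontal = montage.mapping["frontal"]
    duration = config.task_duration_s if condition == "task" else config.rest_duration_s
    n = int(round(duration * config.fs))
    gains = _subject_gains(config, sub_idx)
    cond_code = 1 if condition == "task" else 0
    channels = []
    for ci, label in enumerate(labels):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, sub_idx, cond_code, ci]))
        x = config.background_amp * _pink_noise(n, config.background_exponent, rng)
        for band, (lo, hi) in BANDS.items():
            amp = config.band_amps.get(band, 0.0) * gains[band]
            if condition == "task":
                if band == "theta" and label in frontal:
                    amp *= config.frontal_theta_gain
                if band == "alpha":
                    amp *= config.alpha_suppression
            if amp > 0:
                x = x + amp * _band_oscillation(n, config.fs, (lo, hi), rng)
        if condition == "task" and config.irregularity_delta > 0:
            x = x + (config.irregularity_delta * config.background_amp
                     ) * rng.standard_normal(n)
        channels.append(Signal(x, config.fs, label))
    return RawRecording(tuple(channels), subject_id=f"S{sub_idx:02d}",
                        condition=condition)


def generate_dataset(config: SynthConfig, window_s: float = 4.0,
                     filtered: bool = True) -> list[Segment]:
    """Rest + task recordings for every subject, preprocessed and windowed.

    Each subject contributes ``floor(rest/4) + floor(task/4)`` segments;
    equal durations give a balanced class split.  Segments keep subject
    ids so grouped CV can be requested downstream.
    """
    segments: list[Segment] = []
    for sub in range(config.n_subjects):
        for condition in ("rest", "task"):
            rec = generate_record(config, sub, condition)
            if filtered:
                rec = preprocess(rec, preset=config.preset)
            segments.extend(segment_record(rec, window_s=window_s))
    return segments
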