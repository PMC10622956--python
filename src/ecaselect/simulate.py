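"""Synthetic motor-imagery EEG with planted ground truth.

Emulates the geometry of a standard four-class motor-imagery session — 22
channels, 250 Hz, trials spanning -0.5 s to 4 s around the cue, 72 trials per
class — with class-dependent band-power modulation (event-related
desynchronization, ERD) of an 8-13 Hz mu rhythm on designated informative
channels, over a pink-noise background.

Every channel carries 1/f^alpha background noise plus white sensor noise plus
a narrowband mu rhythm (band-passed white noise rather than a sinusoid, to
avoid trivially separable phase cues).  During a trial of class k the rhythm
amplitude on that class's informative channels is reduced by ``erd_depth``
from cue onset to trial end, so band power there drops by the factor
``(1 - erd_depth)**2`` relative to other-class trials.  Trials are separated
by rest gaps so slow standardization statistics cannot bleed class
information across trials.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocess import EEGRecording, SampleSet, bandpass_filter, crop_trials, ema_standardize

__all__ = ["MONTAGE_22", "SimConfig", "GroundTruth", "generate_recording", "generate_sampleset"]

#: The 22-electrode 10-20 montage of the standard four-class motor-imagery set.
MONTAGE_22 = [
    "Fz",
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2",
    "POz",
]

# Contralateral motor-cortex layout: left hand -> C4, right hand -> C3,
# feet -> Cz, tongue -> CPz (indices into MONTAGE_22).
_DEFAULT_INFORMATIVE = {0: (11,), 1: (7,), 2: (9,), 3: (15,)}


@dataclass
class SimConfig:
    """Generator configuration; the defaults are the emulated study conditions.

    ``informative_channels`` maps each class to the channel indices whose mu
    rhythm desynchronizes during that class's trials.  ``erd_depth`` is the
    fractional amplitude reduction in (0, 1); band power drops by its square.
    Background noise is pink (1/f) at ``pink_rms`` plus white sensor noise at
    ``white_rms``; the mu rhythm has baseline RMS ``rhythm_rms`` (all uV).
    """

    n_channels: int = 22
    sampling_rate_hz: float = 250.0
    trial_seconds: float = 4.5
    pre_cue_seconds: float = 0.5
    gap_seconds: float = 2.0
    n_trials_per_class: int = 72
    n_classes: int = 4
    informative_channels: dict[int, tuple[int, ...]] | None = None
    erd_band_hz: tuple[float, float] = (8.0, 13.0)
    erd_depth: float = 0.5
    pink_exponent: float = 1.0
    pink_rms: float = 10.0
    white_rms: float = 1.0
    rhythm_rms: float = 15.0
    seed: int = 20200220

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_classes < 1 or self.n_trials_per_class < 1:
            raise ValueError("all counts must be positive")
        if not (0.0 < self.erd_depth < 1.0):
            raise ValueError("erd_depth must lie in (0, 1)")
        if self.pre_cue_seconds < 0 or self.trial_seconds <= self.pre_cue_seconds:
            raise ValueError("trial must extend past the cue")
        if self.informative_channels is None:
            if self.n_channels == len(MONTAGE_22) and self.n_classes <= 4:
                self.informative_channels = {
                    k: v for k, v in _DEFAULT_INFORMATIVE.items() if k < self.n_classes
                }
            else:  # spread one informative channel per class across the montage
                self.informative_channels = {
                    k: ((k * self.n_channels) // self.n_classes,)
                    for k in range(self.n_classes)
                }
        self.informative_channels = {
            int(k): tuple(int(c) for c in v) for k, v in self.informative_channels.items()
        }
        for k, chans in self.informative_channels.items():
            if k >= self.n_classes or any(c >= self.n_channels or c < 0 for c in chans):
                raise ValueError(
                    f"informative channel map entry {k}: {chans} is out of range"
                )

    @property
    def channel_names(self) -> list[str]:
        if self.n_channels == len(MONTAGE_22):
            return list(MONTAGE_22)
        return [f"ch{i}" for i in range(self.n_channels)]


@dataclass
class GroundTruth:
    """Planted structure of a generated session, for recovery testing."""

    informative_channels: dict[int, tuple[int, ...]]
    trial_labels: np.ndarray
    channel_names: list[str]

    @property
    def informative_names(self) -> dict[int, tuple[str, ...]]:
        return {
            k: tuple(self.channel_names[c] for c in v)
            for k, v in self.informative_channels.items()
        }

    @property
    def all_informative(self) -> set[str]:
        return {n for names in self.informative_names.values() for n in names}

    def to_json(self) -> str:
        return json.dumps(
            {
                "informative_channels": {
                    str(k): list(v) for k, v in self.informative_channels.items()
                },
                "informative_names": {
                    str(k): list(v) for k, v in self.informative_names.items()
                },
                "trial_labels": self.trial_labels.tolist(),
                "channel_names": self.channel_names,
            }
        )


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float, alpha: float, rms: float) -> np.ndarray:
    """1/f^alpha noise per channel, scaled to the requested RMS."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms


def _narrowband(rng: np.random.Generator, shape: tuple[int, int], fs: float, band: tuple[float, float], rms: float) -> np.ndarray:
    """Band-passed white noise per channel at the requested RMS."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms


def generate_recording(cfg: SimConfig) -> tuple[EEGRecording, GroundTruth]:
    """Generate a continuous session of concatenated trials in random order.

    Returns the recording (with one cue event per trial) and the ground truth
    (trial labels and the planted class-to-channel map).
    """
    fs = cfg.sampling_rate_hz
    trial_len = int(round(cfg.trial_seconds * fs))
    pre = int(round(cfg.pre_cue_seconds * fs))
    gap = int(round(cfg.gap_seconds * fs))
    n_trials = cfg.n_trials_per_class * cfg.n_classes
    total = n_trials * (trial_len + gap)

    rng = np.random.default_rng(cfg.seed)
    labels = np.repeat(np.arange(cfg.n_classes), cfg.n_trials_per_class)
    rng.shuffle(labels)

    background = _pink_noise(rng, (cfg.n_channels, total), fs, cfg.pink_exponent, cfg.pink_rms)
    sensor = rng.standard_normal((cfg.n_channels, total)) * cfg.white_rms
    rhythm = _narrowband(rng, (cfg.n_channels, total), fs, cfg.erd_band_hz, cfg.rhythm_rms)

    envelope = np.ones((cfg.n_channels, total))
    events = np.empty((n_trials, 2), dtype=int)
    for i, label in enumerate(labels):
        start = i * (trial_len + gap)
        cue = start + pre
        events[i] = (cue, label)
        task_end = start + trial_len
        for ch in cfg.informative_channels.get(int(label), ()):
            envelope[ch, cue:task_end] = 1.0 - cfg.erd_depth

    signal = background + sensor + rhythm * envelope
    rec = EEGRecording(signal, cfg.channel_names, fs, events)
    gt = GroundTruth(dict(cfg.informative_channels), labels.copy(), cfg.channel_names)
    return rec, gt


def generate_sampleset(
    cfg: SimConfig,
    bandpass: tuple[float, float] = (1.0, 40.0),
    ema_decay: float = 0.999,
    window_samples: int | None = None,
    stride_samples: int = 62,
) -> tuple[SampleSet, GroundTruth]:
    """Generate a recording and run the default preprocessing chain on it.

    Band-pass 1-40 Hz, EMA standardization (decay 0.999), then sliding-window
    cropping of the full trial span (cue-relative ``[-pre_cue, trial_end)``).
    With the default geometry the window is 4 s (1,000 samples) and the
    stride 62 samples, giving 3 crops per trial: 288 trials -> 864 balanced
    samples of shape 22 x 1,000.  For non-default geometries the window
    defaults to the task duration and is capped at the segment length.
    """
    rec, gt = generate_recording(cfg)
    rec = bandpass_filter(rec, *bandpass)
    rec = ema_standardize(rec, ema_decay)
    fs = cfg.sampling_rate_hz
    t_start = -cfg.pre_cue_seconds
    t_end = cfg.trial_seconds - cfg.pre_cue_seconds
    segment = int(round(t_end * fs)) - int(round(t_start * fs))
    if window_samples is None:
        window_samples = min(int(round((cfg.trial_seconds - cfg.pre_cue_seconds) * fs)), segment)
    ss = crop_trials(rec, t_start, t_end, window_samples, stride_samples)
    return ss, gt
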