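"""Continuous-EEG preprocessing: band-pass filtering, exponential-moving-average
standardization, and sliding-window cropping of cued trials into fixed-length
training samples.

The pipeline order is band-pass -> EMA standardize -> crop.  All operations are
channel-local and leave channel names, sampling rate and event markers intact
until cropping.  Windows are 0-based and half-open; an event's sample index
marks the cue onset (t = 0), and crops are placed relative to it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "SampleSet",
    "bandpass_filter",
    "ema_standardize",
    "crop_trials",
    "save_sampleset",
    "load_sampleset",
    "read_raw_recording",
]


@dataclass
class EEGRecording:
    """A continuous multichannel EEG signal with cue events.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        The signal in microvolts.
    channel_names : list of str
    sampling_rate : float
        Sampling frequency in Hz.
    events : ndarray, shape (n_events, 2)
        Rows of ``(sample_index, class_label)``; the sample index marks cue
        onset.
    """

    signal: np.ndarray
    channel_names: list[str]
    sampling_rate: float
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels, samples)")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must equal signal rows")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        self.events = np.asarray(self.events, dtype=int).reshape(-1, 2)
        if self.events.size and (
            self.events[:, 0].min() < 0
            or self.events[:, 0].max() >= self.signal.shape[1]
        ):
            raise ValueError("event sample indices must lie within the signal")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class SampleSet:
    """Cropped training samples with labels and trial provenance.

    ``samples`` has shape (n_samples, n_channels, n_times); ``trial_ids`` maps
    each crop back to the trial (event) it was cut from.
    """

    samples: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        if self.samples.ndim != 3:
            raise ValueError("samples must be 3-D (n, channels, time)")
        n = self.samples.shape[0]
        if self.labels.shape != (n,) or self.trial_ids.shape != (n,):
            raise ValueError("labels and trial_ids must have one entry per sample")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValueError("channel_names length must equal the channel axis")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_times(self) -> int:
        return self.samples.shape[2]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).size)


def bandpass_filter(
    rec: EEGRecording, low_hz: float, high_hz: float, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied independently per channel.

    A 4th-order filter is run forward and backward (``sosfiltfilt``), doubling
    the effective order and cancelling phase distortion.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for sampling rate "
            f"{rec.sampling_rate} Hz"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return EEGRecording(filtered, rec.channel_names, rec.sampling_rate, rec.events)


def ema_standardize(
    rec: EEGRecording, decay: float = 0.999, eps: float = 1e-4
) -> EEGRecording:
    """Standardize each channel by exponential-moving-average statistics.

    Per channel, a running mean ``m_t = decay*m_{t-1} + (1-decay)*x_t`` (with
    ``m`` initialized at the first sample) and running variance
    ``v_t = decay*v_{t-1} + (1-decay)*(x_t - m_t)**2`` (initialized at 1) are
    tracked; the output is ``(x_t - m_t) / max(sqrt(v_t), eps)``.  Both
    recursions are first-order IIR filters and are evaluated with
    ``scipy.signal.lfilter``.
    """
    if not (0.0 < decay < 1.0):
        raise ValueError(f"decay must lie in (0, 1), got {decay}")
    x = rec.signal
    b, a = [1.0 - decay], [1.0, -decay]
    # zi = decay*x0 makes m_0 = x_0 exactly.
    zi_m = decay * x[:, :1]
    m, _ = sps.lfilter(b, a, x, axis=1, zi=zi_m)
    sq = (x - m) ** 2
    zi_v = decay * np.ones((x.shape[0], 1))
    v, _ = sps.lfilter(b, a, sq, axis=1, zi=zi_v)
    out = (x - m) / np.maximum(np.sqrt(v), eps)
    return EEGRecording(out, rec.channel_names, rec.sampling_rate, rec.events)


def crop_count(segment: int, window: int, stride: int) -> int:
    """Number of stride-spaced windows that fit in a segment."""
    if window > segment:
        return 0
    return (segment - window) // stride + 1


def crop_trials(
    rec: EEGRecording,
    t_start_s: float,
    t_end_s: float,
    window_samples: int,
    stride_samples: int,
) -> SampleSet:
    """Cut each cued trial into sliding-window crops.

    For every event the segment ``[event + t_start, event + t_end)`` (times in
    seconds relative to cue onset) is extracted, then all windows of
    ``window_samples`` at offsets 0, stride, 2*stride, ... that fit are kept.
    Each crop inherits the trial's class label; crops never span trials.
    Trials whose segment exceeds the recording bounds are skipped with a
    warning.
    """
    if stride_samples < 1:
        raise ValueError("stride must be at least 1 sample")
    fs = rec.sampling_rate
    off_start = int(round(t_start_s * fs))
    off_end = int(round(t_end_s * fs))
    segment = off_end - off_start
    if window_samples > segment:
        raise ValueError(
            f"window of {window_samples} samples exceeds the {segment}-sample segment"
        )
    crops, labels, trial_ids = [], [], []
    for trial_id, (onset, label) in enumerate(rec.events):
        lo, hi = onset + off_start, onset + off_end
        if lo < 0 or hi > rec.n_samples:
            warnings.warn(
                f"trial {trial_id} at sample {onset} exceeds recording bounds; skipped",
                stacklevel=2,
            )
            continue
        seg = rec.signal[:, lo:hi]
        for off in range(0, segment - window_samples + 1, stride_samples):
            crops.append(seg[:, off : off + window_samples])
            labels.append(label)
            trial_ids.append(trial_id)
    samples = (
        np.stack(crops)
        if crops
        else np.empty((0, rec.n_channels, window_samples))
    )
    return SampleSet(samples, np.array(labels, dtype=int), np.array(trial_ids, dtype=int), rec.channel_names)


# ---------------------------------------------------------------------------
# I/O


def save_sampleset(path: str, ss: SampleSet) -> None:
    """Write a SampleSet to HDF5 (``.h5``/``.hdf5``) or NPZ (anything else)."""
    if str(path).endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=ss.samples)
            f.create_dataset("labels", data=ss.labels)
            f.create_dataset("trial_ids", data=ss.trial_ids)
            f.create_dataset(
                "channel_names",
                data=np.array(ss.channel_names, dtype=h5py.string_dtype()),
            )
    else:
        np.savez(
            path,
            samples=ss.samples,
            labels=ss.labels,
            trial_ids=ss.trial_ids,
            channel_names=np.array(ss.channel_names, dtype=object),
        )


def load_sampleset(path: str) -> SampleSet:
    if str(path).endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            return SampleSet(
                f["samples"][...],
                f["labels"][...],
                f["trial_ids"][...],
                [n.decode() if isinstance(n, bytes) else str(n) for n in f["channel_names"][...]],
            )
    with np.load(path, allow_pickle=True) as f:
        return SampleSet(
            f["samples"], f["labels"], f["trial_ids"], [str(n) for n in f["channel_names"]]
        )


def read_raw_recording(
    path: str, event_map: dict[str, int] | None = None
) -> EEGRecording:
    """Read a continuous GDF or EDF recording into an :class:`EEGRecording`.

    Events are taken from the file's annotations; ``event_map`` maps
    annotation descriptions to integer class labels (annotations not in the
    map are ignored).  When ``event_map`` is None, the cue annotations of the
    standard four-class motor-imagery montage ('769'..'772', left hand, right
    hand, feet, tongue) are used.  Requires ``mne``.
    """
    import mne  # deferred: only needed for real recordings

    raw = mne.io.read_raw(path, preload=True, verbose="error")
    if event_map is None:
        event_map = {"769": 0, "770": 1, "771": 2, "772": 3}
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        key = str(desc).strip()
        if key in event_map:
            events.append((int(round(onset * raw.info["sfreq"])), event_map[key]))
    sig = raw.get_data() * 1e6  # mne uses volts; this package uses microvolts
    return EEGRecording(sig, list(raw.ch_names), float(raw.info["sfreq"]), np.array(events, dtype=int).reshape(-1, 2))


def sampleset_to_json_meta(ss: SampleSet) -> str:
    """Small JSON description (shape, class balance) used by reports."""
    classes, counts = np.unique(ss.labels, return_counts=True)
    return json.dumps(
        {
            "n_samples": len(ss),
            "n_channels": ss.n_channels,
            "n_times": ss.n_times,
            "class_counts": {int(c): int(n) for c, n in zip(classes, counts)},
        }
    )
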