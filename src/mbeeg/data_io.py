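"""Data preparation operators and the HDF5 trial container.

Covers the study's preprocessing, which is deliberately minimal: cue-aligned
window extraction (0.5 s before the cue, 4.5 s total -> 1125 samples at
250 Hz), motor-cortex channel selection by the 'C' naming rule, anti-aliased
2x downsampling for 500 Hz recordings, and per-channel standardization with
training-set statistics. No band-pass filtering or artifact rejection.
Vendor format conversion (GDF/EDF/MAT) is out of scope; trials live in a
simple named-array HDF5 container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal import filtfilt, firwin

from .containers import TrialDataset

__all__ = [
    "ContinuousRecording",
    "extract_trial_window",
    "select_motor_channels",
    "downsample_half",
    "ChannelStandardizer",
    "standardize_per_channel",
    "save_trials",
    "load_trials",
    "TrialFormatError",
]


class TrialFormatError(Exception):
    """Raised when a trial container is malformed."""


@dataclass
class ContinuousRecording:
    """An unsegmented multichannel recording with cue events."""

    samples: np.ndarray  # (channels, total_samples)
    channel_names: list[str]
    sampling_rate: float
    event_onsets: np.ndarray  # sample indices of cues
    event_labels: np.ndarray  # 1-based class of each cue
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.event_onsets = np.asarray(self.event_onsets, dtype=np.int64)
        self.event_labels = np.asarray(self.event_labels, dtype=np.int64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (channels, total_samples)")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("one name per channel required")
        if self.event_onsets.shape != self.event_labels.shape:
            raise ValueError("event onsets and labels must align")
        if np.any(np.diff(self.event_onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        if self.event_onsets.size and (
                self.event_onsets.min() < 0
                or self.event_onsets.max() >= self.samples.shape[1]):
            raise ValueError("event onsets outside the recording")


def extract_trial_window(rec: ContinuousRecording, pre_cue_s: float = 0.5,
                         total_s: float = 4.5) -> TrialDataset:
    """Cut one fixed window per cue: [onset - pre_cue, onset - pre_cue + total).

    At 250 Hz the default 4.5 s window is 1125 samples. No filtering is
    applied. Windows that fall outside the recording raise an error listing
    the offending onsets.
    """
    rate = rec.sampling_rate
    length = int(round(total_s * rate))
    shift = int(round(pre_cue_s * rate))
    starts = rec.event_onsets - shift
    bad = np.flatnonzero((starts < 0) | (starts + length > rec.samples.shape[1]))
    if bad.size:
        raise ValueError(
            "trial windows out of bounds for onsets at samples "
            f"{rec.event_onsets[bad].tolist()}"
        )
    signals = np.stack([rec.samples[:, s:s + length] for s in starts])
    class_names = rec.class_names or [
        f"class{i}" for i in range(1, int(rec.event_labels.max()) + 1)
    ]
    return TrialDataset(signals=signals, labels=rec.event_labels,
                        sampling_rate=rate, class_names=class_names,
                        channel_names=list(rec.channel_names))


def select_motor_channels(rec: ContinuousRecording) -> ContinuousRecording:
    """Keep channels whose name contains 'C' (case-sensitive), in order.

    The 'C' row of the 10-20 nomenclature (C3, Cz, FC1, CP2, ...) covers the
    motor cortex; on the 128-electrode high-gamma montage this rule retains
    44 sensors.
    """
    keep = [i for i, name in enumerate(rec.channel_names) if "C" in name]
    if not keep:
        raise ValueError("no channel name contains 'C'; nothing to select")
    return ContinuousRecording(
        samples=rec.samples[keep],
        channel_names=[rec.channel_names[i] for i in keep],
        sampling_rate=rec.sampling_rate,
        event_onsets=rec.event_onsets.copy(),
        event_labels=rec.event_labels.copy(),
        class_names=list(rec.class_names),
    )


def downsample_half(rec: ContinuousRecording, *,
                    anti_alias: bool = True) -> ContinuousRecording:
    """Halve the sampling rate (e.g. 500 -> 250 Hz).

    By default an anti-aliasing low-pass (31-tap FIR, zero-phase) precedes
    decimation; ``anti_alias=False`` drops every second sample unfiltered,
    for replication of naive pipelines. Event onsets are remapped by halving.
    """
    if rec.sampling_rate % 2 != 0:
        raise ValueError(f"sampling rate {rec.sampling_rate} is not even")
    n = rec.samples.shape[1]
    x = rec.samples[:, :2 * (n // 2)]
    if anti_alias:
        # zero-phase half-band FIR (31 taps, Hamming), then keep every 2nd
        taps = firwin(31, 0.5)
        out = filtfilt(taps, [1.0], x, axis=1)[:, ::2]
    else:
        out = x[:, ::2]
    return ContinuousRecording(
        samples=out,
        channel_names=list(rec.channel_names),
        sampling_rate=rec.sampling_rate / 2,
        event_onsets=rec.event_onsets // 2,
        event_labels=rec.event_labels.copy(),
        class_names=list(rec.class_names),
    )


class ChannelStandardizer:
    """Per-channel z-scoring with statistics frozen on the training set.

    Fit on training trials (mean/std per channel over all trials and
    samples), then apply to training and test data alike, so the test
    session is transformed with training statistics only.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, data: TrialDataset) -> "ChannelStandardizer":
        x = data.signals
        self.mean_ = x.mean(axis=(0, 2))
        self.std_ = x.std(axis=(0, 2))
        dead = np.flatnonzero(self.std_ == 0)
        if dead.size:
            names = ([data.channel_names[i] for i in dead]
                     if data.channel_names else dead.tolist())
            raise ValueError(f"zero-variance channel(s): {names}")
        return self

    def transform(self, data: TrialDataset) -> TrialDataset:
        if self.mean_ is None:
            raise RuntimeError("standardizer is not fitted")
        z = (data.signals - self.mean_[None, :, None]) / self.std_[None, :, None]
        return TrialDataset(signals=z, labels=data.labels.copy(),
                            sampling_rate=data.sampling_rate,
                            class_names=list(data.class_names),
                            channel_names=None if data.channel_names is None
                            else list(data.channel_names))

    def fit_transform(self, data: TrialDataset) -> TrialDataset:
        return self.fit(data).transform(data)


def standardize_per_channel(train: TrialDataset,
                            test: TrialDataset | None = None):
    """Convenience wrapper: fit on train, transform train (and test)."""
    scaler = ChannelStandardizer().fit(train)
    if test is None:
        return scaler.transform(train)
    return scaler.transform(train), scaler.transform(test)


def save_trials(data: TrialDataset, path) -> None:
    """Write a TrialDataset to the named-array HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("signals", data=data.signals)
        fh.create_dataset("labels", data=data.labels)
        fh.attrs["sampling_rate"] = data.sampling_rate
        fh.attrs["class_names"] = [str(c) for c in data.class_names]
        if data.channel_names is not None:
            fh.attrs["channel_names"] = [str(c) for c in data.channel_names]


def load_trials(path) -> TrialDataset:
    """Read the container back; round-trips bit-exactly."""
    with h5py.File(path, "r") as fh:
        for key in ("signals", "labels"):
            if key not in fh:
                raise TrialFormatError(f"container missing dataset '{key}'")
        if "sampling_rate" not in fh.attrs:
            raise TrialFormatError("container missing attribute 'sampling_rate'")
        signals = np.asarray(fh["signals"])
        labels = np.asarray(fh["labels"])
        if signals.ndim != 3:
            raise TrialFormatError(
                f"signals must be 3-D (trials, channels, samples), "
                f"got shape {signals.shape}"
            )
        if labels.shape != (signals.shape[0],):
            raise TrialFormatError(
                f"labels length {labels.shape} does not match "
                f"{signals.shape[0]} trials"
            )
        class_names = list(fh.attrs.get(
            "class_names",
            [f"class{i}" for i in range(1, int(labels.max()) + 1)]))
        channel_names = fh.attrs.get("channel_names")
        return TrialDataset(
            signals=signals, labels=labels,
            sampling_rate=float(fh.attrs["sampling_rate"]),
            class_names=[str(c) for c in class_names],
            channel_names=None if channel_names is None
            else [str(c) for c in channel_names])
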