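"""Labelled EEG trial container shared by every pipeline stage.

A motor-imagery dataset is a stack of cue-aligned trials: ``signals`` holds
one fixed-length multichannel window per trial (trials x channels x samples)
and ``labels`` the imagined movement class of each trial, coded 1..n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrialDataset"]


@dataclass
class TrialDataset:
    """Labelled multichannel EEG trials.

    Parameters
    ----------
    signals : ndarray, shape (n_trials, n_channels, n_samples)
        Trial windows, in volts or standardized units.
    labels : ndarray of int, shape (n_trials,)
        Class label of each trial, values in ``{1..n_classes}``.
    sampling_rate : float
        Sampling frequency in Hz.
    class_names : list of str
        One name per class; ``len(class_names)`` defines ``n_classes``.
    channel_names : list of str, optional
        Electrode names, if known.
    """

    signals: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    class_names: list[str]
    channel_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.signals.ndim != 3:
            raise ValueError(
                f"signals must be (trials, channels, samples), got shape {self.signals.shape}"
            )
        t, c, s = self.signals.shape
        if t < 1 or c < 1 or s < 1:
            raise ValueError("signals must have at least one trial, channel and sample")
        if self.labels.shape != (t,):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match {t} trials"
            )
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        n = len(self.class_names)
        if n < 1:
            raise ValueError("class_names must not be empty")
        if self.labels.min() < 1 or self.labels.max() > n:
            raise ValueError(
                f"labels must lie in 1..{n}, got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )
        if self.channel_names is not None and len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx) -> "TrialDataset":
        """Return a new dataset restricted to the given trial indices."""
        idx = np.asarray(idx)
        return TrialDataset(
            signals=self.signals[idx],
            labels=self.labels[idx],
            sampling_rate=self.sampling_rate,
            class_names=list(self.class_names),
            channel_names=None if self.channel_names is None else list(self.channel_names),
        )
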