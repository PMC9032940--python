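"""Synthetic motor-imagery EEG with class-dependent ERD structure.

Real motor imagery attenuates the mu rhythm (8-12 Hz) over the motor-cortex
electrodes contralateral to the imagined limb (event-related
desynchronization, ERD). The generator emulates exactly that decodable
physics: every class is assigned a contiguous, disjoint electrode group;
all groups carry a band-limited mu-rhythm-like oscillation over 1/f
background noise (background at a quarter of the oscillation's RMS by default, so
the rhythm dominates its band the way a strong mu rhythm dominates over
sensorimotor cortex at rest), and the group belonging to a trial's class
has its oscillation amplitude attenuated by ``erd_depth``. With depth 0 the classes
are statistically identical (null configuration); with depth near 1 a
band-power rule already separates them, so a trained decoder should too.

The generator makes no attempt to match real inter-subject variability,
artifacts, or the difficulty of the benchmark recordings; it provides a
controlled, seeded stand-in with the same shape regime (e.g. 22 electrodes
x 1125 samples at 250 Hz, 4 classes) so the full train/evaluate pipeline
can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TrialDataset

__all__ = ["SynthConfig", "generate_synthetic_mi", "make_bci2a_like",
           "class_channel_groups"]

#: class naming convention for the four-class paradigm
FOUR_CLASS_NAMES = ["left_hand", "right_hand", "feet", "tongue"]


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults mirror the four-class 22x1125 regime."""

    n_trials_per_class: int = 50
    channels: int = 22
    time_samples: int = 1125
    sampling_rate: float = 250.0
    n_classes: int = 4
    carrier_band_hz: tuple[float, float] = (8.0, 12.0)
    erd_depth: float = 0.8
    osc_amplitude: float = 1.0
    noise_scale: float = 0.25
    noise_color: str = "pink"  # "pink" (1/f) or "white"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.n_classes > self.channels:
            raise ValueError("each class needs its own channel group: "
                             "n_classes must not exceed channels")
        if self.n_classes < 2 or self.n_trials_per_class < 1:
            raise ValueError("need n_classes >= 2 and n_trials_per_class >= 1")
        lo, hi = self.carrier_band_hz
        if not 0 < lo < hi <= self.sampling_rate / 2:
            raise ValueError("carrier band must satisfy 0 < lo < hi <= Nyquist")
        if self.noise_color not in ("pink", "white"):
            raise ValueError("noise_color must be 'pink' or 'white'")
        if self.noise_scale < 0 or self.osc_amplitude < 0:
            raise ValueError("noise_scale and osc_amplitude must be >= 0")


def class_channel_groups(cfg: SynthConfig) -> list[np.ndarray]:
    """Contiguous, disjoint electrode group of each class (1-based class k
    maps to groups[k-1])."""
    size = cfg.channels // cfg.n_classes
    return [np.arange(k * size, (k + 1) * size) for k in range(cfg.n_classes)]


def _unit_rms(x: np.ndarray, axis: int = -1) -> np.ndarray:
    rms = np.sqrt(np.mean(x ** 2, axis=axis, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _background_noise(rng, shape, rate, color) -> np.ndarray:
    white = rng.standard_normal(shape)
    if color == "white":
        return _unit_rms(white)
    T = shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(T, d=1.0 / rate)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC drift
    return _unit_rms(np.fft.irfft(spec * scale, n=T, axis=-1))


def _band_limited(rng, shape, rate, band) -> np.ndarray:
    """Unit-RMS Gaussian oscillation confined to the carrier band."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return _unit_rms(np.fft.irfft(spec * mask, n=shape[-1], axis=-1))


def generate_synthetic_mi(cfg: SynthConfig) -> TrialDataset:
    """Generate a balanced, seeded TrialDataset per the configuration."""
    rng = np.random.default_rng(cfg.seed)
    n_trials = cfg.n_trials_per_class * cfg.n_classes
    labels = np.repeat(np.arange(1, cfg.n_classes + 1), cfg.n_trials_per_class)
    labels = rng.permutation(labels)
    groups = class_channel_groups(cfg)

    shape = (n_trials, cfg.channels, cfg.time_samples)
    signals = cfg.noise_scale * _background_noise(
        rng, shape, cfg.sampling_rate, cfg.noise_color)
    osc = _band_limited(rng, shape, cfg.sampling_rate, cfg.carrier_band_hz)

    # every channel carries the rhythm; only the trial's own class group is
    # ERD-attenuated (channels outside all groups are never modulated)
    amp = np.full((n_trials, cfg.channels), cfg.osc_amplitude)
    for k, grp in enumerate(groups):
        amp[np.ix_(labels == k + 1, grp)] *= (1.0 - cfg.erd_depth)
    signals += amp[:, :, None] * osc

    names = (FOUR_CLASS_NAMES if cfg.n_classes == 4
             else [f"class{k}" for k in range(1, cfg.n_classes + 1)])
    return TrialDataset(signals=signals.astype(np.float32), labels=labels,
                        sampling_rate=cfg.sampling_rate, class_names=names)


def make_bci2a_like(seed: int = 0, n_trials_per_class: int = 50,
                    erd_depth: float = 0.8, noise_scale: float = 0.25
                    ) -> tuple[TrialDataset, TrialDataset]:
    """Two-session four-class dataset in the 22 x 1125 @ 250 Hz shape regime.

    Returns (session_T, session_E): identical class-conditional generative
    parameters, disjoint noise realizations — mimicking the train/test
    session split of the within-subject protocol.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2 ** 31)
    sessions = []
    for s in seeds:
        cfg = SynthConfig(n_trials_per_class=n_trials_per_class,
                          erd_depth=erd_depth, noise_scale=noise_scale,
                          seed=int(s))
        sessions.append(generate_synthetic_mi(cfg))
    return sessions[0], sessions[1]
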