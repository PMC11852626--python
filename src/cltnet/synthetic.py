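"""Synthetic motor-imagery-like EEG trial generator.

Each trial is 1/f^alpha colored background noise plus a band-limited
sensorimotor rhythm (band-pass-filtered white noise, not a pure sinusoid,
so trials have realistic within-class variability). Class identity is
carried by event-related desynchronization (ERD): the rhythm amplitude on
channel c for class y is scaled by ``(1 - erd_map[y, c])``, so an
attenuation of 0.8 suppresses 80% of that channel's rhythm amplitude for
that class — the band-power signature a motor-imagery decoder exploits.

Multiple subjects are emulated by jittering the ERD map and the
rhythm-to-noise ratio per subject. Generation is deterministic per seed.

The generator emulates the spectral statistics of sensorimotor EEG, not its
physiology: there is no volume conduction/forward model, no artifacts
(blinks, EMG), and no non-stationarity within a trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data_io import EEGTrialSet

__all__ = ["SynthConfig", "generate", "make_fixture", "default_erd_map", "FIXTURES"]


def default_erd_map(n_classes: int, n_channels: int, depth: float = 0.5) -> np.ndarray:
    """A simple class-specific topography: channels are split into
    ``n_classes`` contiguous blocks and class y attenuates block y by
    ``depth`` (its "contralateral" sensorimotor territory)."""
    erd = np.zeros((n_classes, n_channels))
    edges = np.linspace(0, n_channels, n_classes + 1).astype(int)
    for c in range(n_classes):
        erd[c, edges[c]:edges[c + 1]] = depth
    return erd


@dataclass
class SynthConfig:
    """Parameters of the ERD/ERS trial generator.

    snr is the rhythm-to-noise amplitude ratio before attenuation (both
    components are normalized to unit RMS, then the rhythm is scaled by
    ``snr * (1 - erd)``); noise_exponent is the spectral slope alpha of the
    1/f^alpha background; subject_shift scales per-subject jitter of the
    ERD map (additive, clipped to [0, 1]) and of log-snr.
    """

    n_subjects: int = 1
    trials_per_class: int = 72
    n_classes: int = 4
    channels: int = 22
    fs: float = 250.0
    T: int = 1000
    rhythm_band: tuple[float, float] = (8.0, 12.0)
    erd_map: np.ndarray | None = None     # (n_classes, channels) in [0, 1]
    erd_depth: float = 0.5                # used when erd_map is None
    noise_exponent: float = 1.0
    snr: float = 0.5
    subject_shift: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.trials_per_class, self.n_classes,
               self.channels, self.T) < 1:
            raise ValueError("all counts must be positive")
        lo, hi = self.rhythm_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("rhythm_band must satisfy 0 < low < high < fs/2")
        if self.erd_map is None:
            self.erd_map = default_erd_map(self.n_classes, self.channels, self.erd_depth)
        self.erd_map = np.asarray(self.erd_map, dtype=np.float64)
        if self.erd_map.shape != (self.n_classes, self.channels):
            raise ValueError("erd_map must have shape (n_classes, channels)")
        if self.erd_map.min() < 0 or self.erd_map.max() > 1:
            raise ValueError("erd attenuation factors must lie in [0, 1]")


def _colored_noise(rng: np.random.Generator, shape: tuple, T: int,
                   alpha: float, fs: float) -> np.ndarray:
    """1/f^alpha noise along the last axis, unit RMS per series."""
    white = rng.standard_normal(shape + (T,))
    W = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(T, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-alpha / 2.0)
    scale[0] = 0.0                         # no DC drift
    x = np.fft.irfft(W * scale, n=T, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd == 0, 1.0, sd)


def _band_rhythm(rng: np.random.Generator, shape: tuple, T: int,
                 band: tuple[float, float], fs: float) -> np.ndarray:
    """Band-pass-filtered white noise along the last axis, unit RMS."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    # pad so the filter transient does not dominate short trials
    pad = min(T, 4 * int(fs))
    white = rng.standard_normal(shape + (T + 2 * pad,))
    x = signal.sosfiltfilt(sos, white, axis=-1)[..., pad:pad + T]
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd == 0, 1.0, sd)


def generate(cfg: SynthConfig) -> list[EEGTrialSet]:
    """Generate one labelled EEGTrialSet per subject, deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    n_trials = cfg.trials_per_class * cfg.n_classes
    channel_names = tuple(f"ch{i}" for i in range(cfg.channels))
    class_names = tuple(f"class{i}" for i in range(cfg.n_classes))
    subjects = []
    for _ in range(cfg.n_subjects):
        erd = np.clip(cfg.erd_map + cfg.subject_shift
                      * rng.standard_normal(cfg.erd_map.shape), 0.0, 1.0)
        snr = cfg.snr * np.exp(cfg.subject_shift * rng.standard_normal())
        labels = np.repeat(np.arange(cfg.n_classes), cfg.trials_per_class)
        labels = labels[rng.permutation(n_trials)]
        noise = _colored_noise(rng, (n_trials, cfg.channels), cfg.T,
                               cfg.noise_exponent, cfg.fs)
        rhythm = _band_rhythm(rng, (n_trials, cfg.channels), cfg.T,
                              cfg.rhythm_band, cfg.fs)
        amp = snr * (1.0 - erd[labels])            # (n_trials, channels)
        data = noise + amp[:, :, None] * rhythm
        subjects.append(EEGTrialSet(
            data=data.astype(np.float32),
            labels=labels,
            fs=cfg.fs,
            channel_names=channel_names,
            class_names=class_names,
        ))
    return subjects


# -- canonical fixtures -------------------------------------------------------

FIXTURES: dict[str, SynthConfig] = {
    # tiny smoke-test set: 40 trials, 3 channels, 500 samples, 2 classes
    "tiny-2class": SynthConfig(
        n_subjects=1, trials_per_class=20, n_classes=2, channels=3,
        fs=250.0, T=500, erd_depth=0.6, snr=0.8, subject_shift=0.0, seed=101),
    # mirrors the 4-class, 22-channel, 250 Hz, 1000-sample session geometry
    "default-4class-22ch": SynthConfig(
        n_subjects=1, trials_per_class=18, n_classes=4, channels=22,
        fs=250.0, T=1000, erd_depth=0.5, snr=0.5, subject_shift=0.0, seed=202),
    # strongly separable two-class task used for learning-sanity checks:
    # deep (0.8) class-specific rhythm suppression at unit rhythm-to-noise
    "strong-erd-2class": SynthConfig(
        n_subjects=1, trials_per_class=200, n_classes=2, channels=3,
        fs=250.0, T=500, erd_depth=0.8, snr=1.0, subject_shift=0.0, seed=303),
}


def make_fixture(name: str) -> EEGTrialSet:
    """A canonical pinned-seed trial set from the fixture registry."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture '{name}'; available: {sorted(FIXTURES)}")
    return generate(FIXTURES[name])[0]
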