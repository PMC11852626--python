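"""Epoch-structured EEG trial sets: container, preprocessing, persistence.

The central object is :class:`EEGTrialSet`, a labelled ``(trials, channels,
samples)`` array with sampling rate and channel/class metadata — the shape in
which cue-aligned motor-imagery epochs are conventionally analysed.
Preprocessing covers window extraction (cropping the motor-imagery segment out
of each recorded trial) and per-trial, per-channel z-score normalization.

The native on-disk format is a single HDF5 file with datasets ``/data``
(float32) and ``/labels`` (int64) and attributes ``fs``, ``channel_names``
and ``class_names``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import h5py
import numpy as np

log = logging.getLogger(__name__)

#: Motor-imagery window of the 4-class cued paradigm, in milliseconds from
#: trial onset: the 2–6 s segment following the cue. At 250 Hz this maps to
#: the half-open sample range [500, 1500), i.e. 1-based samples 501–1500,
#: and yields exactly 1000 samples per trial.
BCI_IV_2A_WINDOW_MS = (2001, 6000)

#: Class order for the 4-class cued paradigm.
BCI_IV_2A_CLASSES = ("left hand", "right hand", "feet", "tongue")


class FormatError(ValueError):
    """A persisted trial-set container is missing or mangling a field."""


@dataclass
class EEGTrialSet:
    """Labelled 3-D EEG epoch container: ``data[trial, channel, sample]``.

    Invariants (enforced by :meth:`validate`): one label per trial, all values
    finite, positive sampling rate, labels index into ``class_names``, channel
    axis matches ``channel_names``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    class_names: tuple[str, ...]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channel_names = tuple(str(c) for c in self.channel_names)
        self.class_names = tuple(str(c) for c in self.class_names)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, channels, samples), got ndim={self.data.ndim}")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("number of trials and number of labels differ")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.fs > 0:
            raise ValueError("sampling frequency must be positive")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels must lie in [0, n_classes)")

    # -- convenience --------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices) -> "EEGTrialSet":
        indices = np.asarray(indices)
        return replace(self, data=self.data[indices], labels=self.labels[indices])

    def full_window_ms(self) -> tuple[float, float]:
        """The (start, end) millisecond window spanning the whole recording."""
        return (0.0, self.n_samples * 1000.0 / self.fs - 1.0)


def concat_trialsets(sets: Sequence[EEGTrialSet]) -> EEGTrialSet:
    """Concatenate trial sets sharing channel/class structure and fs."""
    if not sets:
        raise ValueError("no trial sets to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.channel_names != first.channel_names:
            raise ValueError("inconsistent channel sets across trial sets")
        if s.class_names != first.class_names:
            raise ValueError("inconsistent class sets across trial sets")
        if s.fs != first.fs:
            raise ValueError("inconsistent sampling rates across trial sets")
        if s.n_samples != first.n_samples:
            raise ValueError("inconsistent trial lengths across trial sets")
    return replace(first,
                   data=np.concatenate([s.data for s in sets], axis=0),
                   labels=np.concatenate([s.labels for s in sets], axis=0))


@dataclass
class PreprocessConfig:
    """Window/channel selection and normalization switches.

    ``window_start_ms``/``window_end_ms`` are inclusive millisecond bounds
    relative to trial onset; millisecond t maps to 0-based sample
    ``floor(t*fs/1000)`` and the extracted length is
    ``floor((end - start + 1) * fs / 1000)`` samples.
    """

    window_start_ms: float
    window_end_ms: float
    channels_keep: tuple[str, ...] | None = None
    zscore: bool = True

    def __post_init__(self):
        if not self.window_end_ms > self.window_start_ms:
            raise ValueError("window_end_ms must exceed window_start_ms")
        if self.channels_keep is not None:
            self.channels_keep = tuple(str(c) for c in self.channels_keep)
            if len(self.channels_keep) == 0:
                raise ValueError("channels_keep must be non-empty")


def window_sample_range(start_ms: float, end_ms: float, fs: float) -> tuple[int, int]:
    """Map an inclusive millisecond window to a half-open 0-based sample range."""
    i0 = int(np.floor(start_ms * fs / 1000.0))
    n = int(np.floor((end_ms - start_ms + 1) * fs / 1000.0))
    return i0, i0 + n


def extract_window(trialset: EEGTrialSet, cfg: PreprocessConfig) -> EEGTrialSet:
    """Crop the analysis window and channel subset out of each trial.

    Raises a range error if the window exceeds the recording and a lookup
    error for unknown channel names. Labels are unchanged; channel order
    follows ``cfg.channels_keep``.
    """
    i0, i1 = window_sample_range(cfg.window_start_ms, cfg.window_end_ms, trialset.fs)
    if i0 < 0 or i1 > trialset.n_samples:
        raise IndexError(
            f"window [{cfg.window_start_ms}, {cfg.window_end_ms}] ms maps to samples "
            f"[{i0}, {i1}) outside the recorded span of {trialset.n_samples} samples")
    if cfg.channels_keep is None:
        ch_idx = np.arange(trialset.n_channels)
        names = trialset.channel_names
    else:
        missing = [c for c in cfg.channels_keep if c not in trialset.channel_names]
        if missing:
            raise KeyError(f"unknown channel name(s): {missing}")
        ch_idx = np.array([trialset.channel_names.index(c) for c in cfg.channels_keep])
        names = cfg.channels_keep
    out = replace(trialset,
                  data=trialset.data[:, ch_idx, i0:i1],
                  channel_names=names)
    if cfg.zscore:
        out = zscore_normalize(out)
    return out


def zscore_normalize(trialset: EEGTrialSet) -> EEGTrialSet:
    """Z-score each (trial, channel) time series (population sd over time).

    Degenerate rule: a constant time series (sd == 0) becomes all zeros — the
    mean is removed and the rescaling is skipped — with a logged warning.
    """
    x = trialset.data.astype(np.float64)
    mu = x.mean(axis=2, keepdims=True)
    sd = x.std(axis=2, keepdims=True)
    degenerate = sd == 0
    if np.any(degenerate):
        log.warning("zscore_normalize: %d constant (trial, channel) series set to zero",
                    int(degenerate.sum()))
    out = np.where(degenerate, 0.0, (x - mu) / np.where(degenerate, 1.0, sd))
    return replace(trialset, data=out.astype(np.float32))


# -- persistence ------------------------------------------------------------

def save_trialset(trialset: EEGTrialSet, path) -> None:
    """Write the native single-file container (HDF5)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trialset.data.astype(np.float32))
        f.create_dataset("labels", data=trialset.labels.astype(np.int64))
        f.attrs["fs"] = float(trialset.fs)
        f.attrs["channel_names"] = list(trialset.channel_names)
        f.attrs["class_names"] = list(trialset.class_names)


def load_trialset(path) -> EEGTrialSet:
    """Read the native container, validating structure and invariants."""
    with h5py.File(path, "r") as f:
        for name in ("data", "labels"):
            if name not in f:
                raise FormatError(f"container is missing required dataset '{name}'")
        for name in ("fs", "channel_names", "class_names"):
            if name not in f.attrs:
                raise FormatError(f"container is missing required attribute '{name}'")
        return EEGTrialSet(
            data=f["data"][...],
            labels=f["labels"][...],
            fs=float(f.attrs["fs"]),
            channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            class_names=tuple(str(c) for c in f.attrs["class_names"]),
        )


# -- optional GDF import -----------------------------------------------------

#: Cue event codes of the 4-class cued-paradigm GDF sessions, in class order.
GDF_2A_EVENT_CODES = {"769": 0, "770": 1, "771": 2, "772": 3}


def load_gdf_session(path, trial_span_s: float = 7.0,
                     event_codes: dict[str, int] | None = None,
                     class_names: Sequence[str] = BCI_IV_2A_CLASSES) -> EEGTrialSet:
    """Import one GDF session into an :class:`EEGTrialSet` (optional path).

    Requires ``mne``. Epochs are cut from each cue event onset over
    ``trial_span_s`` seconds; EOG channels are dropped. The event-code →
    class mapping defaults to the 4-class cue annotations 769–772.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("GDF import requires the optional 'mne' dependency "
                          "(pip install cltnet[gdf])") from exc
    event_codes = dict(GDF_2A_EVENT_CODES if event_codes is None else event_codes)
    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    raw.pick("eeg")
    fs = float(raw.info["sfreq"])
    n_span = int(round(trial_span_s * fs))
    sig = raw.get_data()
    onsets, labels = [], []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc in event_codes:
            onsets.append(int(round(onset * fs)))
            labels.append(event_codes[desc])
    trials = [sig[:, o:o + n_span] for o in onsets if o + n_span <= sig.shape[1]]
    labels = [l for o, l in zip(onsets, labels) if o + n_span <= sig.shape[1]]
    if not trials:
        raise FormatError("no complete cue-aligned trials found in GDF session")
    return EEGTrialSet(
        data=np.stack(trials).astype(np.float32),
        labels=np.asarray(labels, dtype=np.int64),
        fs=fs,
        channel_names=tuple(raw.ch_names),
        class_names=tuple(class_names),
    )
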