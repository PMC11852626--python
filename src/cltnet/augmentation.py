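"""Segmentation-and-recombination (S&R) augmentation of EEG trials.

Each training trial is divided into K consecutive time segments; an
artificial trial of class y is assembled by taking segment j (in its
original temporal position) from a uniformly sampled donor trial of the
same class, independently per segment, donors drawn with replacement.
Labels of artificial trials equal the donor class.

Provenance (the per-segment donor assignment) can be recorded so any
artificial trial is exactly replayable, which also makes the augmentation
auditable: every sample value in an artificial trial exists at the same
(channel, time) position in some source trial of the same class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data_io import EEGTrialSet

__all__ = ["AugmentConfig", "AugmentResult", "segment_recombine", "provenance",
           "segment_boundaries", "replay"]


@dataclass
class AugmentConfig:
    """S&R parameters.

    k
        Number of consecutive segments per trial. When k does not divide the
        trial length T, the first ``T mod k`` segments get one extra sample
        so segments stay contiguous and exhaustive.
    n_per_class
        Artificial trials generated per class; ``None`` matches the original
        per-class trial counts (doubling the training set).
    seed
        RNG seed for donor sampling.
    """

    k: int = 8
    n_per_class: int | None = None
    seed: int = 0
    record_provenance: bool = True

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_per_class is not None and self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")


@dataclass
class AugmentResult:
    """Artificial trials plus optional per-trial donor provenance."""

    trials: EEGTrialSet
    #: per artificial trial: list of (segment_index, donor_trial_index) pairs,
    #: donor indices referring to the source trial set; None if not recorded.
    donors: list[list[tuple[int, int]]] | None
    boundaries: list[tuple[int, int]]


def segment_boundaries(T: int, k: int) -> list[tuple[int, int]]:
    """Half-open sample ranges of the k contiguous, exhaustive segments."""
    if k > T:
        raise ValueError(f"k={k} exceeds trial length T={T}")
    base, rem = divmod(T, k)
    bounds, start = [], 0
    for j in range(k):
        width = base + (1 if j < rem else 0)
        bounds.append((start, start + width))
        start += width
    return bounds


def segment_recombine(trialset: EEGTrialSet, cfg: AugmentConfig) -> AugmentResult:
    """Generate artificial trials by same-class segment recombination.

    Returns only the artificial trials; callers concatenate with the
    originals. Deterministic for a fixed ``cfg.seed``.
    """
    T = trialset.n_samples
    bounds = segment_boundaries(T, cfg.k)
    rng = np.random.default_rng(cfg.seed)

    class_indices = {c: np.flatnonzero(trialset.labels == c)
                     for c in range(trialset.n_classes)}
    counts = {}
    for c in range(trialset.n_classes):
        n = len(class_indices[c]) if cfg.n_per_class is None else cfg.n_per_class
        if n > 0 and len(class_indices[c]) == 0:
            raise ValueError(f"class {c} has no source trials but n_per_class={n} requested")
        counts[c] = n

    new_data, new_labels = [], []
    donors: list[list[tuple[int, int]]] | None = [] if cfg.record_provenance else None
    for c in range(trialset.n_classes):
        pool = class_indices[c]
        for _ in range(counts[c]):
            picks = pool[rng.integers(0, len(pool), size=cfg.k)]
            trial = np.empty_like(trialset.data[0])
            for j, (lo, hi) in enumerate(bounds):
                trial[:, lo:hi] = trialset.data[picks[j], :, lo:hi]
            new_data.append(trial)
            new_labels.append(c)
            if donors is not None:
                donors.append([(j, int(picks[j])) for j in range(cfg.k)])

    if new_data:
        data = np.stack(new_data)
        labels = np.asarray(new_labels, dtype=np.int64)
    else:
        data = np.empty((0,) + trialset.data.shape[1:], dtype=trialset.data.dtype)
        labels = np.empty((0,), dtype=np.int64)
    out = replace(trialset, data=data, labels=labels)
    return AugmentResult(trials=out, donors=donors, boundaries=bounds)


def provenance(result: AugmentResult) -> list[list[tuple[int, int]]]:
    """The recorded (segment_index, donor_trial_index) lists per artificial trial."""
    if result.donors is None:
        raise RuntimeError("provenance was not recorded; rerun with record_provenance=True")
    return result.donors


def replay(source: EEGTrialSet, result: AugmentResult) -> np.ndarray:
    """Rebuild artificial trials from recorded provenance (bit-exact)."""
    rec = provenance(result)
    out = np.empty_like(result.trials.data)
    for i, assignment in enumerate(rec):
        for j, donor in assignment:
            lo, hi = result.boundaries[j]
            out[i, :, lo:hi] = source.data[donor, :, lo:hi]
    return out
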