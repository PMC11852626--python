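"""Experiment harness: ablation table, attention-head sweep, run manifests.

Ablation switches bypass one stage at a time while keeping the rest of the
network and the training conditions (seed, split, schedule) identical:

* ``no_transformer`` — the encoder is replaced by an identity pass-through
  (widths match, so this is well-typed).
* ``no_lstm``        — likewise for the stacked LSTM.
* ``no_sr``          — S&R augmentation is disabled; training uses exactly
  the original trials.
* ``no_spatial``     — the depthwise spatial convolution is replaced by a
  channel-mean collapse tiled to the same width.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data_io import EEGTrialSet
from .model import CLTNet, ModelConfig, count_parameters
from .training import TrainConfig, evaluate_model, fit

__all__ = ["ablate", "head_sweep", "RunManifest", "ABLATION_SWITCHES"]

ABLATION_SWITCHES = ("no_transformer", "no_lstm", "no_sr", "no_spatial")


def _variant_configs(mcfg: ModelConfig, tcfg: TrainConfig, switch: str | None
                     ) -> tuple[ModelConfig, TrainConfig]:
    if switch is None:
        return mcfg, tcfg
    if switch == "no_transformer":
        return replace(mcfg, use_transformer=False), tcfg
    if switch == "no_lstm":
        return replace(mcfg, use_lstm=False), tcfg
    if switch == "no_sr":
        return mcfg, replace(tcfg, augment=None)
    if switch == "no_spatial":
        return replace(mcfg, spatial_mode="mean"), tcfg
    raise ValueError(f"unknown ablation switch '{switch}'; "
                     f"valid: {ABLATION_SWITCHES}")


def ablate(trialset: EEGTrialSet, mcfg: ModelConfig, tcfg: TrainConfig,
           switches: Sequence[str]) -> pd.DataFrame:
    """One train+evaluate cycle per ablation variant on identical seeds.

    Rows: the full model first, then one row per requested switch. Each
    variant trains with the same TrainConfig seed, so splits and batch
    order coincide; evaluation is on the variant's own validation split
    (the subject-specific protocol's held-out 30%).
    """
    for s in switches:
        if s not in ABLATION_SWITCHES:
            raise ValueError(f"unknown ablation switch '{s}'; valid: {ABLATION_SWITCHES}")
    rows = []
    for name, switch in [("full", None)] + [(s, s) for s in switches]:
        m, t = _variant_configs(mcfg, tcfg, switch)
        model, hist = fit(trialset, m, t)
        val_idx = _validation_indices(trialset, t)
        report = evaluate_model(model, trialset.subset(val_idx))
        rows.append({"variant": name,
                     "accuracy": report.accuracy,
                     "kappa": report.kappa,
                     "selected_epoch": hist.selected_epoch,
                     "n_parameters": count_parameters(model)})
    return pd.DataFrame(rows)


def _validation_indices(trialset: EEGTrialSet, tcfg: TrainConfig) -> np.ndarray:
    # reproduce fit()'s split deterministically from the same seed stream
    from .training import _stratified_split
    ss = np.random.SeedSequence(tcfg.seed)
    s_split = int(ss.spawn(4)[0].generate_state(1)[0]) % (2 ** 31)
    _, va = _stratified_split(trialset, tcfg.val_fraction, s_split)
    if len(va) == 0:
        raise ValueError("ablation evaluation needs val_fraction > 0")
    return va


def head_sweep(trialset: EEGTrialSet, mcfg: ModelConfig, tcfg: TrainConfig,
               heads: Sequence[int]) -> pd.DataFrame:
    """Train/evaluate once per attention-head count (d_k held fixed)."""
    rows = []
    for h in heads:
        if h < 1:
            raise ValueError("head count must be >= 1")
        m = replace(mcfg, h=h)
        model, hist = fit(trialset, m, tcfg)
        val_idx = _validation_indices(trialset, tcfg)
        report = evaluate_model(model, trialset.subset(val_idx))
        rows.append({"heads": h,
                     "accuracy": report.accuracy,
                     "kappa": report.kappa,
                     "n_parameters": count_parameters(model)})
    return pd.DataFrame(rows)


# -- run manifests ------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one CLI command: enough to reproduce or audit the run."""

    command: str
    config: dict
    seed: int | None
    code_version: str = __version__
    inputs: dict[str, str] = field(default_factory=dict)    # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    @staticmethod
    def now() -> str:
        return datetime.now(timezone.utc).isoformat()

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _sha256(path)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        with open(path, "w") as f:
            f.write(self.to_json())
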