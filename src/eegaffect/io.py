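"""CSV-directory persistence and run configuration.

Layout (diff-able plain text):

* ``meta.json`` — sampling rates, channel order, label scale
* ``eeg_subject<k>_trial<j>.csv`` — samples x channels, header = channel names
* ``accel_subject<k>_trial<j>.csv`` — samples x 3 axes (x, y, z)
* ``labels.csv`` — trial, subject, valence, arousal
"""
from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EpochSet, LabelVector
from .preprocess import AccelTrace

__all__ = ["read_epochs", "write_epochs", "RunConfig", "run_manifest"]

VERSION = "0.1.0"


class MissingChannelError(ValueError):
    pass


class SamplingRateMismatchError(ValueError):
    pass


class LabelMismatchError(ValueError):
    pass


def write_epochs(path, epochs: EpochSet, labels: dict | None = None,
                 accel: AccelTrace | None = None) -> None:
    """Write an epoch set (plus optional labels/accelerometer) as a CSV dir."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs": epochs.fs,
        "channels": list(epochs.channel_names),
        "fs_accel": accel.fs_accel if accel is not None else None,
        "label_scale": list(labels[next(iter(labels))].scale) if labels else None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    for i in range(epochs.n_trials):
        subj = epochs.subject_ids[i]
        trial = int(epochs.trial_ids[i])
        name = f"eeg_subject{subj}_trial{trial}.csv"
        pd.DataFrame(epochs.data[i].T,
                     columns=list(epochs.channel_names)).to_csv(
            path / name, index=False, float_format="%.8g")
        if accel is not None:
            pd.DataFrame(accel.data[i].T, columns=["x", "y", "z"]).to_csv(
                path / f"accel_subject{subj}_trial{trial}.csv",
                index=False, float_format="%.8g")
    if labels is not None:
        rows = {"trial": [int(t) for t in epochs.trial_ids],
                "subject": list(epochs.subject_ids)}
        for name, lv in labels.items():
            rows[name] = lv.values.tolist()
        pd.DataFrame(rows).to_csv(path / "labels.csv", index=False,
                                  float_format="%.8g")


def read_epochs(path):
    """Read a CSV-dir recording.

    Returns ``(epochs, labels_or_None, accel_or_None)``; raises named errors
    on missing channels, inconsistent sampling metadata, or labels that do
    not join onto the trials.
    """
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    channels = meta["channels"]
    files = sorted(path.glob("eeg_subject*_trial*.csv"),
                   key=lambda p: _sort_key(p.name))
    if not files:
        raise FileNotFoundError(f"no eeg_subject*_trial*.csv under {path}")
    data, subjects, trials = [], [], []
    for f in files:
        df = pd.read_csv(f)
        missing = [c for c in channels if c not in df.columns]
        if missing:
            raise MissingChannelError(f"{f.name}: missing channels {missing}")
        data.append(df[channels].to_numpy().T)
        subj, trial = _parse_name(f.name)
        subjects.append(subj)
        trials.append(trial)
    lengths = {d.shape[1] for d in data}
    if len(lengths) != 1:
        raise SamplingRateMismatchError(
            f"trials have heterogeneous lengths {sorted(lengths)}")
    epochs = EpochSet(data=np.stack(data), fs=meta["fs"],
                      channel_names=tuple(channels),
                      subject_ids=np.asarray(subjects),
                      trial_ids=np.asarray(trials))

    labels = None
    labels_path = path / "labels.csv"
    if labels_path.exists():
        lab = pd.read_csv(labels_path).set_index("trial")
        try:
            lab = lab.loc[trials]
        except KeyError as exc:
            raise LabelMismatchError(f"labels.csv missing trials: {exc}") from None
        scale = tuple(meta.get("label_scale") or (1.0, 10.0))
        labels = {name: LabelVector(lab[name].to_numpy(), scale)
                  for name in lab.columns if name not in ("subject",)}

    accel = None
    accel_files = sorted(path.glob("accel_subject*_trial*.csv"),
                         key=lambda p: _sort_key(p.name))
    if accel_files:
        if len(accel_files) != len(files):
            raise LabelMismatchError(
                "accelerometer trial count does not match EEG trial count")
        arrs = [pd.read_csv(f)[["x", "y", "z"]].to_numpy().T
                for f in accel_files]
        accel = AccelTrace(data=np.stack(arrs), fs_accel=meta["fs_accel"])
    return epochs, labels, accel


def _parse_name(name: str):
    stem = name.rsplit(".", 1)[0]
    _, subj_part, trial_part = stem.split("_")
    subj = subj_part.removeprefix("subject")
    trial = int(trial_part.removeprefix("trial"))
    return (int(subj) if subj.isdigit() else subj), trial


def _sort_key(name: str):
    subj, trial = _parse_name(name)
    return (str(subj), trial)


_KNOWN_KEYS = {
    "seed", "label", "paths", "sim", "preprocess", "battery",
    "selection", "protocol",
}


@dataclass
class RunConfig:
    """Pipeline configuration: stage toggles, battery, protocol, seeds."""

    seed: int = 0
    label: str = "valence"
    paths: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=lambda: {
        "reference": True,
        "filter": {"low": 0.1, "high": 40.0, "order": 4},
        "motion": True,
        "autoreject": True,
    })
    battery: list | None = None
    selection: dict = field(default_factory=lambda: {"aggregate": "mean"})
    protocol: str = "split"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "label": self.label, "paths": self.paths,
            "sim": self.sim, "preprocess": self.preprocess,
            "battery": self.battery, "selection": self.selection,
            "protocol": self.protocol,
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_manifest(config: RunConfig) -> dict:
    """Provenance triple embedded next to every output artifact."""
    return {"config_hash": config.config_hash, "seed": config.seed,
            "version": VERSION}
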