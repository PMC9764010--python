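"""Shared domain containers: epoch tensors, montage metadata, frequency bands, labels.

Amplitudes are microvolts (uV) throughout; thresholds stated in uV assume this.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np

__all__ = [
    "EpochSet",
    "Montage",
    "BandSet",
    "LabelVector",
    "EMOTIV_CHANNELS",
    "default_montage",
    "default_bands",
    "select_channels",
    "segment",
]

#: Channel order of the 14-electrode Emotiv Epoc montage (10-20 positions).
EMOTIV_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)


class UnknownChannelError(KeyError):
    """Requested channel name is not present in the epoch set."""


@dataclass
class EpochSet:
    """Trials x channels x samples tensor with montage and bookkeeping metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        Ordered channel labels, one per channel axis entry.
    subject_ids
        Per-trial subject tag (any hashable; defaults to 0 for all trials).
    retained
        Per-trial boolean mask of trials that survived rejection
        (defaults to all True).
    trial_ids
        Parent-trial index of each row; after :func:`segment` several rows
        share a parent trial.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    subject_ids: np.ndarray = None  # type: ignore[assignment]
    retained: np.ndarray = None  # type: ignore[assignment]
    trial_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        n = self.data.shape[0]
        if self.subject_ids is None:
            self.subject_ids = np.zeros(n, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.retained is None:
            self.retained = np.ones(n, dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.trial_ids is None:
            self.trial_ids = np.arange(n)
        self.trial_ids = np.asarray(self.trial_ids)
        for name, arr in (("subject_ids", self.subject_ids),
                          ("retained", self.retained),
                          ("trial_ids", self.trial_ids)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise UnknownChannelError(name) from None

    def copy_with(self, **kwargs) -> "EpochSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Montage:
    """Electrode montage with scalp-region map and homologous left/right pairs."""

    channels: tuple[str, ...]
    region_map: dict[str, str]
    asymmetry_pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        missing = [c for c in self.channels if c not in self.region_map]
        if missing:
            raise ValueError(f"region_map missing channels: {missing}")
        seen: set[str] = set()
        for left, right in self.asymmetry_pairs:
            if left in seen or right in seen:
                raise ValueError("asymmetry pairs must be disjoint")
            seen.update((left, right))

    def region_channels(self, region: str) -> tuple[str, ...]:
        return tuple(c for c in self.channels if self.region_map[c] == region)

    @property
    def regions(self) -> tuple[str, ...]:
        out = []
        for c in self.channels:
            r = self.region_map[c]
            if r not in out:
                out.append(r)
        return tuple(out)

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "region_map": dict(self.region_map),
            "asymmetry_pairs": [list(p) for p in self.asymmetry_pairs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(
            channels=tuple(d["channels"]),
            region_map=dict(d["region_map"]),
            asymmetry_pairs=tuple(tuple(p) for p in d["asymmetry_pairs"]),
        )


def default_montage() -> Montage:
    """The 14-channel Emotiv montage with its four scalp regions and the
    seven homologous left/right electrode pairs."""
    region_map = {}
    for ch in ("F3", "F4", "F7", "F8", "AF3", "AF4", "FC5", "FC6"):
        region_map[ch] = "frontal"
    for ch in ("T7", "T8"):
        region_map[ch] = "temporal"
    for ch in ("P7", "P8"):
        region_map[ch] = "parietal"
    for ch in ("O1", "O2"):
        region_map[ch] = "occipital"
    pairs = (
        ("F3", "F4"), ("F7", "F8"), ("AF3", "AF4"), ("FC5", "FC6"),
        ("T7", "T8"), ("P7", "P8"), ("O1", "O2"),
    )
    return Montage(channels=EMOTIV_CHANNELS, region_map=region_map,
                   asymmetry_pairs=pairs)


@dataclass(frozen=True)
class BandSet:
    """Named EEG frequency intervals in Hz."""

    bands: dict[str, tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name}: low must be < high")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    def __iter__(self):
        return iter(self.bands)

    def items(self):
        return self.bands.items()

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.bands.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "BandSet":
        return cls({k: (float(v[0]), float(v[1])) for k, v in d.items()})


def default_bands() -> BandSet:
    """Delta/theta/alpha/beta/gamma intervals used across the pipeline."""
    return BandSet({
        "delta": (0.5, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 12.0),
        "beta": (12.0, 30.0),
        "gamma": (30.0, 45.0),
    })


@dataclass
class LabelVector:
    """Per-trial continuous affect ratings (valence or arousal)."""

    values: np.ndarray
    scale: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = self.scale
        if self.values.size and (self.values.min() < lo or self.values.max() > hi):
            raise ValueError("label values fall outside the stated scale")

    def __len__(self) -> int:
        return len(self.values)

    def take(self, idx) -> "LabelVector":
        return LabelVector(self.values[idx], self.scale)


def select_channels(epochs: EpochSet, names) -> EpochSet:
    """Slice and reorder the channel axis to the requested channel list.

    Raises :class:`UnknownChannelError` if any requested name is absent.
    """
    idx = [epochs.channel_index(n) for n in names]
    return epochs.copy_with(data=epochs.data[:, idx, :],
                            channel_names=tuple(names))


def segment(epochs: EpochSet, window_s: float, overlap_s: float = 0.0) -> EpochSet:
    """Cut every trial into fixed-length windows ("segments as trials").

    With zero overlap a trial of L seconds yields ``floor(L / window_s)``
    segments; a trailing partial window is discarded.  Subject ids and the
    parent-trial index propagate to each segment, so per-trial labels can be
    broadcast to segment rows downstream.
    """
    win = int(round(window_s * epochs.fs))
    if win < 2:
        raise ValueError("window must cover at least 2 samples")
    if overlap_s >= window_s:
        raise ValueError("overlap must be shorter than the window")
    step = win - int(round(overlap_s * epochs.fs))
    n_samples = epochs.n_samples
    starts = list(range(0, n_samples - win + 1, step))
    if not starts:
        warnings.warn("window longer than trial; zero segments produced")
    chunks, subj, trial, kept = [], [], [], []
    for i in range(epochs.n_trials):
        for s in starts:
            chunks.append(epochs.data[i, :, s:s + win])
            subj.append(epochs.subject_ids[i])
            trial.append(epochs.trial_ids[i])
            kept.append(epochs.retained[i])
    data = (np.stack(chunks) if chunks
            else np.empty((0, epochs.n_channels, win)))
    return EpochSet(
        data=data, fs=epochs.fs, channel_names=epochs.channel_names,
        subject_ids=np.asarray(subj, dtype=epochs.subject_ids.dtype)
        if subj else np.empty(0, dtype=int),
        retained=np.asarray(kept, dtype=bool) if kept else np.empty(0, dtype=bool),
        trial_ids=np.asarray(trial) if trial else np.empty(0, dtype=int),
    )
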