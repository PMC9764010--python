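"""Preprocessing: re-referencing, band-pass filtering, accelerometer-guided
motion-artifact removal, and cross-validated peak-to-peak trial rejection.

The trial-rejection stage searches a grid of candidate peak-to-peak thresholds
with K-fold cross-validation: for each fold and candidate it compares the mean
of the retained ("good") training trials against the per-sensor median of the
validation trials under the Frobenius norm, and keeps the threshold with the
lowest mean error across folds.
"""
from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA
from sklearn.model_selection import KFold

from .core import EpochSet

__all__ = [
    "AccelTrace",
    "ICADecomposition",
    "AutorejectResult",
    "average_reference",
    "bandpass",
    "highpass",
    "ica_decompose",
    "remove_motion_artifacts",
    "ptp",
    "autoreject_global",
    "autoreject_local",
]


@dataclass
class AccelTrace:
    """Per-trial 3-axis accelerometer recording paired with an EpochSet."""

    data: np.ndarray  # (n_trials, 3, n_samples_accel)
    fs_accel: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 3:
            raise ValueError("accelerometer data must be (n_trials, 3, n_samples)")


@dataclass
class ICADecomposition:
    """Blind source separation of one trial: ``mixing @ sources + mean``
    reconstructs the input."""

    sources: np.ndarray    # (n_sources, n_samples)
    mixing: np.ndarray     # (n_channels, n_sources)
    unmixing: np.ndarray   # (n_sources, n_channels)
    mean: np.ndarray       # (n_channels,)

    def reconstruct(self, sources: np.ndarray | None = None) -> np.ndarray:
        src = self.sources if sources is None else sources
        return self.mixing @ src + self.mean[:, None]


@dataclass
class AutorejectResult:
    """Outcome of the cross-validated threshold search."""

    threshold_star: float
    candidate_thresholds: np.ndarray
    fold_errors: np.ndarray   # (n_candidates, K)
    rejected: np.ndarray      # per-trial bool

    def to_dict(self) -> dict:
        return {
            "threshold_star": float(self.threshold_star),
            "candidate_thresholds": self.candidate_thresholds.tolist(),
            "fold_errors": self.fold_errors.tolist(),
            "rejected": self.rejected.astype(bool).tolist(),
        }


def average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract, at every time point, the mean amplitude across electrodes.

    Idempotent and linear; after the operation the cross-channel mean is zero
    at every sample.
    """
    if epochs.n_channels < 2:
        raise ValueError("average reference undefined for a single channel")
    ref = epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=epochs.data - ref)


def _band_sos(low: float, high: float, fs: float, order: int):
    nyq = fs / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz must be below Nyquist {nyq} Hz")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(epochs: EpochSet, low: float = 0.1, high: float = 40.0,
             order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass applied per channel per trial.

    Forward-backward application avoids group-delay distortion of
    time-domain features.
    """
    sos = _band_sos(low, high, epochs.fs, order)
    return epochs.copy_with(data=signal.sosfiltfilt(sos, epochs.data, axis=-1))


def highpass(x: np.ndarray, cutoff: float, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass along the last axis."""
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def ica_decompose(trial: np.ndarray, seed: int | None = 0,
                  n_sources: int | None = None) -> ICADecomposition:
    """Separate one trial (channels x samples) into independent sources.

    Deterministic for a fixed seed.  Raises on rank-deficient input, naming
    the deficient dimension.
    """
    trial = np.asarray(trial, dtype=float)
    n_channels, n_samples = trial.shape
    if n_samples < n_channels:
        raise ValueError("need more samples than channels")
    rank = np.linalg.matrix_rank(trial - trial.mean(axis=1, keepdims=True))
    if (n_sources or n_channels) > rank:
        raise ValueError(
            f"rank-deficient input: rank {rank} < {n_sources or n_channels} "
            "requested sources"
        )
    # tight convergence matters: a partially converged rotation can smear a
    # high-variance artifact direction across several sources
    ica = FastICA(n_components=n_sources, random_state=seed, max_iter=2000,
                  tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on short windows
        sources = ica.fit_transform(trial.T).T
    return ICADecomposition(
        sources=sources,
        mixing=ica.mixing_,
        unmixing=ica.components_,
        mean=ica.mean_,
    )


def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def remove_motion_artifacts(epochs: EpochSet, accel: AccelTrace,
                            hp_cutoff: float = 3.0, sd_mult: float = 2.0,
                            seed: int | None = 0) -> EpochSet:
    """Scrub accelerometer-correlated ICA sources from each trial.

    Per trial: decompose into independent sources, correlate every source with
    every accelerometer axis (linearly resampled to the EEG grid), and flag
    sources whose |Pearson r| exceeds mean + ``sd_mult``*SD of that axis's
    correlations.  Flagged sources are high-pass filtered at ``hp_cutoff`` Hz
    (motion sits below ~3 Hz) and the trial is remixed; trials with no flagged
    source are returned bit-identical.
    """
    out = epochs.data.copy()
    n_samples = epochs.n_samples
    for i in range(epochs.n_trials):
        if i >= accel.data.shape[0] or not np.isfinite(accel.data[i]).all():
            warnings.warn(f"trial {i}: no accelerometer trace; passed through")
            continue
        axes = np.empty((3, n_samples))
        t_eeg = np.arange(n_samples) / epochs.fs
        t_acc = np.arange(accel.data.shape[2]) / accel.fs_accel
        for a in range(3):
            axes[a] = np.interp(t_eeg, t_acc, accel.data[i, a])
        # average referencing leaves the trial rank-deficient by one; fit as
        # many sources as the data supports
        trial = epochs.data[i]
        rank = np.linalg.matrix_rank(trial - trial.mean(axis=1, keepdims=True))
        dec = ica_decompose(trial, seed=seed,
                            n_sources=None if rank >= trial.shape[0] else rank)
        n_src = dec.sources.shape[0]
        r = np.empty((n_src, 3))
        for s in range(n_src):
            for a in range(3):
                r[s, a] = _abs_pearson(dec.sources[s], axes[a])
        flagged = np.zeros(n_src, dtype=bool)
        for a in range(3):
            thr = r[:, a].mean() + sd_mult * r[:, a].std()
            flagged |= r[:, a] > thr
        if not flagged.any():
            continue
        src = dec.sources.copy()
        src[flagged] = highpass(src[flagged], hp_cutoff, epochs.fs)
        out[i] = dec.reconstruct(src)
    return epochs.copy_with(data=out)


def ptp(x: np.ndarray) -> float:
    """Peak-to-peak amplitude, max minus min, over all elements."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("ptp of empty input")
    return float(x.max() - x.min())


def _autoreject_errors(data: np.ndarray, candidates: np.ndarray,
                       folds: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Fold-error matrix e[l, k] for candidate threshold l and fold k."""
    ptps = data.max(axis=(1, 2)) - data.min(axis=(1, 2))
    errors = np.full((len(candidates), len(folds)), np.inf)
    for k, (train_idx, val_idx) in enumerate(folds):
        val_median = np.median(data[val_idx], axis=0)
        train_ptps = ptps[train_idx]
        for l, thr in enumerate(candidates):
            good = train_idx[train_ptps < thr]
            if good.size == 0:
                continue  # candidate disqualified for this fold
            train_mean = data[good].mean(axis=0)
            errors[l, k] = np.linalg.norm(train_mean - val_median)
    return errors


def default_candidates(epochs: EpochSet, n: int = 30) -> np.ndarray:
    """Candidate threshold grid: n values spanning the 1st-99th percentile of
    observed trial peak-to-peak amplitudes."""
    ptps = epochs.data.max(axis=(1, 2)) - epochs.data.min(axis=(1, 2))
    lo, hi = np.percentile(ptps, [1, 99])
    if lo == hi:
        hi = lo + 1.0
    return np.linspace(lo, hi, n)


def autoreject_global(epochs: EpochSet, candidates=None, K: int = 10,
                      seed: int | None = 0) -> AutorejectResult:
    """Cross-validated search for the peak-to-peak rejection threshold.

    Ties in the mean fold error are broken toward the smallest threshold
    (the most aggressive rejection among equal-error candidates).  A trial is
    rejected when its peak-to-peak amplitude is >= the chosen threshold.
    """
    n = epochs.n_trials
    if K < 2 or n < K:
        raise ValueError("need n_trials >= K >= 2")
    candidates = (default_candidates(epochs) if candidates is None
                  else np.asarray(candidates, dtype=float))
    if candidates.size == 0 or np.any(np.diff(candidates) < 0):
        raise ValueError("candidates must be non-empty and sorted ascending")
    kf = KFold(n_splits=K, shuffle=True, random_state=seed)
    folds = [(tr, va) for tr, va in kf.split(np.arange(n))]
    errors = _autoreject_errors(epochs.data, candidates, folds)
    mean_err = errors.mean(axis=1)
    if not np.isfinite(mean_err).any():
        raise ValueError("every candidate leaves an empty good set in some fold")
    l_star = int(np.argmin(mean_err))  # first minimum = smallest threshold
    t_star = float(candidates[l_star])
    ptps = epochs.data.max(axis=(1, 2)) - epochs.data.min(axis=(1, 2))
    return AutorejectResult(
        threshold_star=t_star,
        candidate_thresholds=candidates,
        fold_errors=errors,
        rejected=ptps >= t_star,
    )


def autoreject_local(epochs: EpochSet, candidates=None, K: int = 10,
                     seed: int | None = 0) -> list[AutorejectResult]:
    """Per-channel variant: the threshold search run independently on each
    (epochs x 1 x time) slice, yielding one result per sensor."""
    results = []
    for c in range(epochs.n_channels):
        sub = epochs.copy_with(data=epochs.data[:, c:c + 1, :],
                               channel_names=(epochs.channel_names[c],))
        results.append(autoreject_global(sub, candidates=candidates, K=K,
                                         seed=seed))
    return results
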