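"""Per-segment EEG feature battery: complexity and continuity descriptors.

Scalar operations act on a single 1-s window (one channel); pair features
(differential / rational asymmetry) act on homologous left/right windows.
:func:`extract_features` evaluates a battery over a segmented
:class:`~eegaffect.core.EpochSet`, sharing band-filtered tensors across
features for speed, and is tested to agree with the scalar path.

Conventions: population variance (divide by n) everywhere, natural
logarithms, amplitudes in microvolts.
"""
from __future__ import annotations

from dataclasses import dataclass
import logging
import math

import numpy as np
from scipy import signal as sps
from scipy.spatial import cKDTree

from .core import BandSet, EpochSet, Montage, default_bands, default_montage

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec", "FeatureMatrix", "DEFAULT_BATTERY", "ALL_CODES",
    "shannon_entropy", "subband_information_quantity",
    "hjorth_mobility", "hjorth_complexity", "false_nearest_neighbor",
    "differential_entropy", "dasm", "rasm",
    "median_frequency", "band_power", "std_dev",
    "spikes", "sharp_spike", "delta_burst_after_spike",
    "bursts", "suppressions", "diffuse_slowing",
    "extract_features",
]

_BAND_LETTER = {"A": "alpha", "B": "beta", "D": "delta", "G": "gamma",
                "T": "theta"}

#: order of the Butterworth band-isolation filter used by sub-band features
BAND_FILTER_ORDER = 7


@dataclass(frozen=True)
class FeatureSpec:
    """One feature code: its battery group and whether it is computed per
    channel or per homologous electrode pair."""

    code: str
    kind: str          # "complexity" | "continuity"
    per_pair: bool = False
    band: str | None = None


def _specs() -> dict[str, FeatureSpec]:
    out: dict[str, FeatureSpec] = {}

    def add(code, kind, per_pair=False, band=None):
        out[code] = FeatureSpec(code, kind, per_pair, band)

    add("S.E.", "complexity")
    for letter, band in _BAND_LETTER.items():
        add(f"S.E.{letter}.", "complexity", band=band)
    add("H.M.", "complexity")
    add("H.C.", "complexity")
    add("F.N.N.", "complexity")
    for letter, band in _BAND_LETTER.items():
        add(f"D.{letter}.", "complexity", per_pair=True, band=band)
        add(f"R.{letter}.", "complexity", per_pair=True, band=band)
    add("M.F.", "continuity")
    for letter, band in _BAND_LETTER.items():
        add(f"B.P.{letter}.", "continuity", band=band)
    add("S.D.", "continuity")
    add("D.S.", "continuity")
    add("S.K.", "continuity")
    add("S.S.N.", "continuity")
    add("D.B.A.S.", "continuity")
    add("N.B.", "continuity")
    add("B.L.M.", "continuity")
    add("B.L.S.", "continuity")
    add("N.S.", "continuity")
    add("S.L.M.", "continuity")
    add("S.L.S.", "continuity")
    return out


SPECS: dict[str, FeatureSpec] = _specs()
ALL_CODES: tuple[str, ...] = tuple(sorted(SPECS))

#: Codes excluded from the default battery (dropped by cross-dataset
#: variance screening); they stay individually callable.
EXCLUDED_CODES: tuple[str, ...] = (
    "S.E.", "F.N.N.", "D.S.", "S.K.", "D.B.A.S.",
    "N.B.", "B.L.M.", "B.L.S.", "N.S.", "S.L.M.", "S.L.S.",
)

#: The 25-code default battery: 15 per-channel + 10 pair codes.
DEFAULT_BATTERY: tuple[str, ...] = tuple(
    c for c in ALL_CODES if c not in EXCLUDED_CODES
)


# ---------------------------------------------------------------------------
# scalar building blocks

def _as_window(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty window")
    return x


def _band_filter(x: np.ndarray, band: tuple[float, float], fs: float,
                 order: int = BAND_FILTER_ORDER) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} outside (0, {nyq})")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _var(x: np.ndarray, axis=-1) -> np.ndarray:
    return np.var(x, axis=axis)  # population convention


def shannon_entropy(x, n_bins: int = 32) -> float:
    """Histogram Shannon entropy in nats over ``n_bins`` fixed-width bins
    spanning the window's [min, max]; a constant window has entropy 0."""
    x = _as_window(x)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def subband_information_quantity(x, band, fs: float, n_bins: int = 32) -> float:
    """Shannon entropy of the Butterworth band-isolated window (SIQ).

    A constant window has no band content and scores 0 directly (filtering
    residue would otherwise produce entropy of numerical noise).
    """
    x = _as_window(x)
    if x.max() == x.min():
        return 0.0
    return shannon_entropy(_band_filter(x, band, fs), n_bins)


def hjorth_mobility(x) -> float:
    """sqrt(var(dx)/var(x)) — proportional to the spectrum's mean frequency."""
    x = _as_window(x)
    v = _var(x)
    if v == 0:
        raise ValueError("mobility undefined for a flat window")
    return float(np.sqrt(_var(np.diff(x)) / v))


def hjorth_complexity(x) -> float:
    """mobility(dx)/mobility(x) — near 1 for a pure sinusoid, > 1 for noise."""
    x = _as_window(x)
    d = np.diff(x)
    if _var(x) == 0 or _var(d) == 0:
        raise ValueError("complexity undefined when a variance vanishes")
    return hjorth_mobility(d) / hjorth_mobility(x)


def false_nearest_neighbor(x, dim: int = 2, delay: int = 1,
                           rtol: float = 15.0) -> float:
    """Fraction of delay-embedding points whose nearest neighbour at
    dimension ``dim`` becomes false at ``dim + 1`` (distance-ratio test)."""
    x = _as_window(x)
    n_vec = x.size - dim * delay
    if n_vec < 2:
        raise ValueError("window too short for the requested embedding")
    emb = np.stack([x[i * delay: i * delay + n_vec] for i in range(dim)], axis=1)
    tree = cKDTree(emb)
    dist, idx = tree.query(emb, k=2)
    dist, idx = dist[:, 1], idx[:, 1]
    nxt = x[np.arange(n_vec) + dim * delay]
    false = np.abs(nxt - nxt[idx]) > rtol * np.maximum(dist, 1e-300)
    return float(false.mean())


def differential_entropy(x) -> float:
    """Gaussian closed form 0.5*ln(2*pi*e*var) on the sample variance."""
    x = _as_window(x)
    v = _var(x)
    if v == 0:
        raise ValueError("differential entropy undefined for zero variance")
    return 0.5 * math.log(2 * math.pi * math.e * v)


def dasm(left, right, band, fs: float) -> float:
    """Differential asymmetry: DE(band-filtered left) - DE(band-filtered right)."""
    return (differential_entropy(_band_filter(_as_window(left), band, fs))
            - differential_entropy(_band_filter(_as_window(right), band, fs)))


def rasm(left, right, band, fs: float) -> float:
    """Rational asymmetry: DE(left)/DE(right) on band-filtered windows."""
    hr = differential_entropy(_band_filter(_as_window(right), band, fs))
    if hr == 0:
        raise ValueError("right-side differential entropy is exactly zero")
    hl = differential_entropy(_band_filter(_as_window(left), band, fs))
    return hl / hr


def median_frequency(x, fs: float) -> float:
    """Smallest frequency at which the cumulative periodogram reaches half of
    the total power."""
    x = _as_window(x)
    f, p = sps.periodogram(x, fs=fs)
    total = p.sum()
    if total == 0:
        raise ValueError("median frequency undefined for zero power")
    return float(f[np.searchsorted(np.cumsum(p), total / 2.0)])


def band_power(x, band, fs: float) -> float:
    """Mean periodogram power of the Butterworth band-isolated window (uV^2)."""
    filt = _band_filter(_as_window(x), band, fs)
    _, p = sps.periodogram(filt, fs=fs)
    return float(p.mean())


def std_dev(x) -> float:
    """Population standard deviation of the window (uV)."""
    return float(np.std(_as_window(x)))


def _spike_indices(x: np.ndarray, k_sd: float, min_dist: int) -> np.ndarray:
    thr = x.mean() + k_sd * x.std()
    peaks, _ = sps.find_peaks(x, height=thr, distance=min_dist)
    return peaks


def spikes(x, k_sd: float = 3.0, min_dist: int = 7) -> int:
    """Count of local maxima above mean + ``k_sd`` SD with at least
    ``min_dist`` samples between accepted peaks."""
    return int(len(_spike_indices(_as_window(x), k_sd, min_dist)))


def _run_bounds(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) bounds of maximal True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def sharp_spike(x, fs: float = 128.0, k_sd: float = 3.0,
                min_dist: int = 7) -> int:
    """Spikes whose above-threshold excursion lasts under 70 ms."""
    x = _as_window(x)
    if x.std() == 0:
        return 0
    peaks = _spike_indices(x, k_sd, min_dist)
    if len(peaks) == 0:
        return 0
    thr = x.mean() + k_sd * x.std()
    max_width = 0.070 * fs
    above = x > thr
    count = 0
    for start, stop in _run_bounds(above):
        if np.any((peaks >= start) & (peaks < stop)) and (stop - start) < max_width:
            count += 1
    return count


def delta_burst_after_spike(x, fs: float = 128.0, delta_band=(0.5, 4.0),
                            k_sd: float = 3.0, min_dist: int = 7,
                            mode: str = "diff") -> float:
    """Change in delta-band activity around detected spikes (uV).

    For each spike, the mean of the 7 delta-band samples after the peak is
    combined with the mean of the 7 before; ``mode="diff"`` (default) takes
    after-minus-before, ``mode="sum"`` adds them.  Spikes within 7 samples of
    a window edge are skipped; contributions sum over spikes.
    """
    x = _as_window(x)
    if x.std() == 0:
        return 0.0
    peaks = _spike_indices(x, k_sd, min_dist)
    if len(peaks) == 0:
        return 0.0
    delta = _band_filter(x, delta_band, fs)
    total = 0.0
    for p in peaks:
        if p - 7 < 0 or p + 8 > x.size:
            continue
        before = delta[p - 7: p].mean()
        after = delta[p + 1: p + 8].mean()
        total += (after - before) if mode == "diff" else (after + before)
    return float(total)


def bursts(x, fs: float = 128.0, sd_mult: float = 2.0):
    """High-amplitude run statistics: (count, mean length s, SD of length s).

    A burst is a maximal run of samples with |amplitude| above
    mean(|x|) + ``sd_mult``*SD(|x|); empty statistics are reported as zeros.
    """
    x = np.abs(_as_window(x))
    thr = x.mean() + sd_mult * x.std()
    runs = _run_bounds(x > thr)
    if not runs:
        return 0, 0.0, 0.0
    lengths = np.array([stop - start for start, stop in runs]) / fs
    return len(runs), float(lengths.mean()), float(lengths.std())


def suppressions(x, fs: float = 128.0, thr: float = 10.0,
                 min_run_s: float = 0.1):
    """Amplitude-suppression run statistics: (count, mean length s, SD s).

    A suppression is a maximal run with |amplitude| below ``thr`` uV lasting
    at least ``min_run_s`` seconds (guards against single-sample crossings).
    """
    x = np.abs(_as_window(x))
    min_len = max(1, int(round(min_run_s * fs)))
    runs = [(a, b) for a, b in _run_bounds(x < thr) if b - a >= min_len]
    if not runs:
        return 0, 0.0, 0.0
    lengths = np.array([stop - start for start, stop in runs]) / fs
    return len(runs), float(lengths.mean()), float(lengths.std())


def diffuse_slowing(x, fs: float = 128.0, bands: BandSet | None = None) -> int:
    """1 when delta-band power exceeds the summed power of all other bands."""
    bands = bands or default_bands()
    powers = {name: band_power(x, interval, fs)
              for name, interval in bands.items()}
    delta = powers.pop("delta")
    return int(delta > sum(powers.values()))


# ---------------------------------------------------------------------------
# battery evaluation over an EpochSet

@dataclass
class FeatureMatrix:
    """Segments x feature-columns matrix with per-column and per-row metadata.

    ``column_meta`` holds ``(location, code)`` tuples, where *location* is a
    channel name for per-channel features and ``"LEFT/RIGHT"`` for pair
    features; ``row_meta`` holds ``(subject, trial, segment)`` per row.
    """

    values: np.ndarray
    column_meta: list[tuple[str, str]]
    row_meta: list[tuple[object, int, int]]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_meta), len(self.column_meta)):
            raise ValueError("metadata does not match matrix shape")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def codes(self) -> tuple[str, ...]:
        seen = []
        for _, code in self.column_meta:
            if code not in seen:
                seen.append(code)
        return tuple(seen)

    def columns_for_code(self, code: str) -> np.ndarray:
        return np.array([i for i, (_, c) in enumerate(self.column_meta)
                         if c == code], dtype=int)

    def columns_for_channel(self, channel: str) -> np.ndarray:
        """Per-channel feature columns attributed to one electrode (pair
        columns are not attributed to either electrode)."""
        return np.array([i for i, (loc, c) in enumerate(self.column_meta)
                         if loc == channel and not SPECS[c].per_pair],
                        dtype=int)

    def select_columns(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(self.values[:, idx],
                             [self.column_meta[i] for i in idx],
                             list(self.row_meta))

    def select_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(self.values[idx],
                             list(self.column_meta),
                             [self.row_meta[i] for i in np.flatnonzero(idx)
                              if idx.dtype == bool] if idx.dtype == bool
                             else [self.row_meta[i] for i in idx])

    def to_dataframe(self):
        import pandas as pd

        cols = pd.MultiIndex.from_tuples(self.column_meta,
                                         names=["channel", "feature"])
        return pd.DataFrame(self.values, columns=cols)

    def to_csv(self, path, row_meta_path=None):
        """Write values with a two-row (channel, feature) header; row metadata
        goes to a JSON sidecar when a path is given."""
        self.to_dataframe().to_csv(path, index=False)
        if row_meta_path is not None:
            import json

            with open(row_meta_path, "w") as fh:
                json.dump([{"subject": str(s), "trial": int(t), "segment": int(g)}
                           for s, t, g in self.row_meta], fh)


def _entropy_rows(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Vectorised histogram entropy along the last axis."""
    lead = X.shape[:-1]
    n = X.shape[-1]
    flat = X.reshape(-1, n)
    lo = flat.min(axis=1, keepdims=True)
    hi = flat.max(axis=1, keepdims=True)
    span = hi - lo
    ok = span[:, 0] > 0
    out = np.zeros(flat.shape[0])
    if ok.any():
        sub = flat[ok]
        idx = ((sub - lo[ok]) / span[ok] * n_bins).astype(int)
        np.clip(idx, 0, n_bins - 1, out=idx)
        offsets = np.arange(sub.shape[0])[:, None] * n_bins
        counts = np.bincount((idx + offsets).ravel(),
                             minlength=sub.shape[0] * n_bins)
        counts = counts.reshape(sub.shape[0], n_bins)
        p = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
        out[ok] = h
    return out.reshape(lead)


def _mobility_rows(X: np.ndarray) -> np.ndarray:
    v = np.var(X, axis=-1)
    dv = np.var(np.diff(X, axis=-1), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(dv / v)


def extract_features(epochs: EpochSet, battery=None,
                     montage: Montage | None = None,
                     bands: BandSet | None = None,
                     n_bins: int = 32) -> FeatureMatrix:
    """Evaluate a feature battery on every (segment, channel) of ``epochs``.

    ``epochs`` is expected to be segmented (1-s windows as rows).  Per-channel
    codes contribute one column per channel, pair codes one column per
    homologous electrode pair.  Non-finite feature values (e.g. Hjorth
    mobility of a flat window) are imputed as 0 and counted in the log so
    downstream matrices stay numeric.
    """
    battery = tuple(battery) if battery is not None else DEFAULT_BATTERY
    if not battery:
        raise ValueError("battery must not be empty")
    unknown = [c for c in battery if c not in SPECS]
    if unknown:
        raise ValueError(f"unknown feature codes: {unknown}")
    montage = montage or default_montage()
    bands = bands or default_bands()
    fs = epochs.fs
    X = epochs.data  # (n_seg, n_ch, n_samp)
    n_seg, n_ch, _ = X.shape

    needed_bands = sorted({SPECS[c].band for c in battery
                           if SPECS[c].band is not None}
                          | ({"delta"} if any(c in ("D.S.", "D.B.A.S.")
                                              for c in battery) else set()))
    banded: dict[str, np.ndarray] = {}
    for name in needed_bands:
        lo, hi = bands[name]
        sos = sps.butter(BAND_FILTER_ORDER, [lo, hi], btype="bandpass",
                         fs=fs, output="sos")
        banded[name] = sps.sosfiltfilt(sos, X, axis=-1)

    def mean_psd(arr):
        _, p = sps.periodogram(arr, fs=fs, axis=-1)
        return p.mean(axis=-1)

    band_pows = {name: mean_psd(banded[name]) for name in needed_bands}
    de_bands = {}
    for name in needed_bands:
        v = np.var(banded[name], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            de_bands[name] = 0.5 * np.log(2 * math.pi * math.e * v)

    pair_idx = [(epochs.channel_index(l), epochs.channel_index(r))
                for l, r in montage.asymmetry_pairs
                if l in epochs.channel_names and r in epochs.channel_names]
    pair_names = [f"{l}/{r}" for l, r in montage.asymmetry_pairs
                  if l in epochs.channel_names and r in epochs.channel_names]

    def per_channel(code: str) -> np.ndarray:
        """(n_seg, n_ch) block for one per-channel code."""
        spec = SPECS[code]
        if code == "S.E.":
            return _entropy_rows(X, n_bins)
        if code.startswith("S.E."):
            out = _entropy_rows(banded[spec.band], n_bins)
            flat = X.max(axis=-1) == X.min(axis=-1)
            out[flat] = 0.0  # constant raw window: no band content
            return out
        if code == "H.M.":
            return _mobility_rows(X)
        if code == "H.C.":
            with np.errstate(divide="ignore", invalid="ignore"):
                return _mobility_rows(np.diff(X, axis=-1)) / _mobility_rows(X)
        if code == "M.F.":
            f, p = sps.periodogram(X, fs=fs, axis=-1)
            tot = p.sum(axis=-1, keepdims=True)
            cum = np.cumsum(p, axis=-1)
            with np.errstate(invalid="ignore"):
                reached = cum >= tot / 2.0
            first = reached.argmax(axis=-1)
            out = f[first]
            out[tot[..., 0] == 0] = np.nan
            return out
        if code.startswith("B.P."):
            return band_pows[spec.band]
        if code == "S.D.":
            return np.std(X, axis=-1)
        if code == "D.S.":
            delta = band_pows["delta"]
            others = sum(band_pows[b] for b in needed_bands if b != "delta")
            return (delta > others).astype(float)
        # remaining continuity codes: per-window loops
        out = np.empty((n_seg, n_ch))
        for i in range(n_seg):
            for c in range(n_ch):
                w = X[i, c]
                try:
                    if code == "F.N.N.":
                        out[i, c] = false_nearest_neighbor(w)
                    elif code == "S.K.":
                        out[i, c] = spikes(w)
                    elif code == "S.S.N.":
                        out[i, c] = sharp_spike(w, fs=fs)
                    elif code == "D.B.A.S.":
                        out[i, c] = delta_burst_after_spike(w, fs=fs,
                                                            delta_band=bands["delta"])
                    elif code in ("N.B.", "B.L.M.", "B.L.S."):
                        nb, blm, bls = bursts(w, fs=fs)
                        out[i, c] = {"N.B.": nb, "B.L.M.": blm,
                                     "B.L.S.": bls}[code]
                    elif code in ("N.S.", "S.L.M.", "S.L.S."):
                        ns, slm, sls = suppressions(w, fs=fs)
                        out[i, c] = {"N.S.": ns, "S.L.M.": slm,
                                     "S.L.S.": sls}[code]
                    else:  # pragma: no cover
                        raise ValueError(code)
                except ValueError:
                    out[i, c] = np.nan
        return out

    blocks, meta = [], []
    for code in battery:
        spec = SPECS[code]
        if spec.per_pair:
            de = de_bands[spec.band]
            cols = np.empty((n_seg, len(pair_idx)))
            for j, (li, ri) in enumerate(pair_idx):
                if code.startswith("D."):
                    cols[:, j] = de[:, li] - de[:, ri]
                else:
                    with np.errstate(divide="ignore", invalid="ignore"):
                        cols[:, j] = de[:, li] / de[:, ri]
            blocks.append(cols)
            meta.extend((pair_names[j], code) for j in range(len(pair_idx)))
        else:
            blocks.append(per_channel(code))
            meta.extend((epochs.channel_names[c], code) for c in range(n_ch))

    values = np.concatenate(blocks, axis=1) if blocks else np.empty((n_seg, 0))
    bad = ~np.isfinite(values)
    if bad.any():
        logger.info("imputed %d non-finite feature values as 0", int(bad.sum()))
        values = np.where(bad, 0.0, values)

    seg_counter: dict[int, int] = {}
    row_meta = []
    for i in range(n_seg):
        t = int(epochs.trial_ids[i])
        seg_counter[t] = seg_counter.get(t, -1) + 1
        row_meta.append((epochs.subject_ids[i], t, seg_counter[t]))
    return FeatureMatrix(values, meta, row_meta)
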