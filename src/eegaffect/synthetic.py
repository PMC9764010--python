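"""Synthetic portable-EEG generator with planted affective structure.

Emulates the shape of image/video-elicited affect recordings: subjects x
trials x 14 channels at 128 Hz, per-trial valence/arousal ratings, a 3-axis
accelerometer trace, and injectable artifacts (motion leakage, spikes,
amplitude suppressions, high peak-to-peak bad trials).

Label-feature coupling is planted by modulating the power of a band-limited
component at chosen electrodes as exp(beta * z), z the standardised label;
beta is calibrated numerically so that the band-power feature correlates with
the label at the requested r.  The background is 1/f noise, which captures
the spectral tilt of resting EEG but none of its physiology (no ERPs, no
eye-blink morphology).
"""
from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

from .core import EMOTIV_CHANNELS, EpochSet, LabelVector, default_bands
from .preprocess import AccelTrace

__all__ = ["SimConfig", "generate", "inject_motion", "inject_bad_trials"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic recording campaign.

    Defaults mirror a 15-participant image-viewing session: 40 five-second
    trials per subject at 128 Hz on the 14-channel montage, ratings uniform
    on a 1-10 scale, ~10 uV 1/f background, and sparse artifacts.
    """

    n_subjects: int = 15
    n_trials_per_subject: int = 40
    trial_s: float = 5.0
    fs: float = 128.0
    channels: tuple[str, ...] = EMOTIV_CHANNELS
    label_scale: tuple[float, float] = (1.0, 10.0)
    #: (electrode, band, target label, correlation) entries
    effects: list = field(default_factory=lambda: [
        ("F3", "alpha", "valence", 0.4),
        ("F4", "beta", "arousal", 0.4),
        ("T8", "gamma", "arousal", 0.3),
    ])
    #: ((left, right), band, target label, correlation) entries
    asymmetry_effects: list = field(default_factory=list)
    noise_sigma: float = 10.0      # uV, background 1/f
    noise_exponent: float = 1.0    # spectral slope of the background
    component_sigma: float = 5.0   # uV, baseline std of planted components
    motion_rate: float = 0.1
    spike_rate: float = 0.05
    suppression_rate: float = 0.05
    bad_trial_rate: float = 0.05
    motion_gain: float = 5.0       # in multiples of trial signal SD
    bad_trial_ptp: float = 400.0   # uV
    fs_accel: float = 32.0
    seed: int = 0

    def __post_init__(self):
        for rate in (self.motion_rate, self.spike_rate,
                     self.suppression_rate, self.bad_trial_rate):
            if not 0 <= rate <= 1:
                raise ValueError("artifact rates must lie in [0, 1]")
        for entry in list(self.effects) + list(self.asymmetry_effects):
            if not abs(entry[3]) < 1:
                raise ValueError("effect sizes must satisfy |r| < 1")
        if abs(self.fs * self.trial_s - round(self.fs * self.trial_s)) > 1e-9:
            raise ValueError("fs * trial_s must be integral")


def _pink_rows(shape, exponent: float, rng) -> np.ndarray:
    """Unit-variance 1/f^exponent noise along the last axis."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_rows(shape, band, fs, rng, stabilize_win: int | None = None) -> np.ndarray:
    """Unit-variance band-limited noise along the last axis.

    With ``stabilize_win`` set, every non-overlapping window of that many
    samples is normalised to unit power, so the component's energy at the
    analysis timescale is carried by the planted modulation rather than by
    the chi-squared fluctuation of filtered noise.
    """
    sos = sps.butter(7, list(band), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    if stabilize_win:
        n = x.shape[-1]
        for start in range(0, n - stabilize_win + 1, stabilize_win):
            seg = x[..., start:start + stabilize_win]
            sd = seg.std(axis=-1, keepdims=True)
            sd[sd == 0] = 1.0
            x[..., start:start + stabilize_win] = seg / sd
        return x
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_power_rows(X: np.ndarray, band, fs) -> np.ndarray:
    sos = sps.butter(7, list(band), btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, X, axis=-1)
    _, p = sps.periodogram(filt, fs=fs, axis=-1)
    return p.mean(axis=-1)


def _calibrate_beta(target_r: float, band, comp_sigma: float,
                    noise_sigma: float, exponent: float, fs: float,
                    seed: int, trial_s: float = 5.0, n_trials_cal: int = 300,
                    win_s: float = 1.0) -> float:
    """Find beta so that corr(segment band power, label) hits ``target_r``.

    The calibration mirrors the trial-level synthesis — the component is
    normalised per trial and then cut into 1-s windows, so within-trial power
    fluctuation is part of the measured correlation.  Common random numbers
    make the correlation a smooth function of beta for Brent root-finding;
    clamps with a warning when the target is unreachable at beta <= 4.
    """
    rng = np.random.default_rng(seed)
    n_samp = int(round(trial_s * fs))
    win = int(round(win_s * fs))
    n_win = n_samp // win
    z_trial = rng.uniform(-np.sqrt(3), np.sqrt(3), size=n_trials_cal)
    z = np.repeat(z_trial, n_win)
    bg = _pink_rows((n_trials_cal, n_samp), exponent, rng) * noise_sigma
    comp = _band_rows((n_trials_cal, n_samp), band, fs, rng,
                      stabilize_win=win)

    def corr_at(beta: float) -> float:
        amp = comp_sigma * np.exp(beta * z_trial / 2.0)
        x = bg + amp[:, None] * comp
        wins = x[:, : n_win * win].reshape(n_trials_cal * n_win, win)
        bp = _band_power_rows(wins, band, fs)
        return float(np.corrcoef(bp, z)[0, 1])

    target = abs(target_r)
    sign = 1.0 if target_r >= 0 else -1.0
    # corr_at rises from 0 and flattens (or dips) at large beta, so scan a
    # grid for the first bracket containing the target, then refine.
    grid = np.linspace(0.05, 4.0, 12)
    vals = [corr_at(b) for b in grid]
    lo = 1e-4
    for b, v in zip(grid, vals):
        if v >= target:
            return sign * brentq(lambda x: corr_at(x) - target, lo, b,
                                 xtol=1e-3)
        lo = b
    warnings.warn(f"target r={target_r} unreachable; using closest beta")
    return sign * float(grid[int(np.argmax(vals))])


def _synth_accel(n_trials: int, n_samples: int, fs: float, rng) -> AccelTrace:
    """Low-frequency (<3 Hz) random-walk accelerometer traces, unit variance."""
    walk = np.cumsum(rng.standard_normal((n_trials, 3, n_samples)), axis=-1)
    sos = sps.butter(4, 3.0, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, walk, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return AccelTrace(data=x / sd, fs_accel=fs)


def inject_motion(epochs: EpochSet, accel: AccelTrace, trials,
                  gain: float, seed: int = 0, axes=(0, 1, 2)) -> EpochSet:
    """Add gain-scaled, channel-weighted copies of accelerometer axes to the
    EEG of the chosen trials; other trials are untouched.

    ``gain`` is expressed in multiples of the trial's signal SD, so gain 0 is
    the identity.  Restricting ``axes`` plants a single accelerometer-
    correlated component (the cleanest test case for the scrubber).
    """
    rng = np.random.default_rng(seed)
    weights = rng.uniform(0.3, 1.0, size=(3, epochs.n_channels))
    out = epochs.data.copy()
    t_eeg = np.arange(epochs.n_samples) / epochs.fs
    t_acc = np.arange(accel.data.shape[2]) / accel.fs_accel
    for i in trials:
        if not 0 <= i < epochs.n_trials:
            raise IndexError(f"trial index {i} out of range")
        sd = epochs.data[i].std()
        for a in axes:
            axis = np.interp(t_eeg, t_acc, accel.data[i, a])
            axis = axis - axis.mean()
            asd = axis.std() or 1.0
            out[i] += gain * sd * weights[a][:, None] * (axis / asd)[None, :]
    return epochs.copy_with(data=out)


def inject_bad_trials(epochs: EpochSet, trials, ptp_target: float) -> EpochSet:
    """Rescale the chosen trials so their peak-to-peak amplitude matches
    ``ptp_target`` uV (warning if that would shrink them)."""
    out = epochs.data.copy()
    for i in trials:
        if not 0 <= i < epochs.n_trials:
            raise IndexError(f"trial index {i} out of range")
        current = out[i].max() - out[i].min()
        if current == 0:
            out[i] += np.linspace(0, ptp_target, epochs.n_samples)[None, :]
            continue
        if ptp_target < current:
            warnings.warn("ptp target below the trial's current amplitude")
        out[i] = out[i] * (ptp_target / current)
    return epochs.copy_with(data=out)


def generate(cfg: SimConfig):
    """Generate one synthetic campaign.

    Returns ``(epochs, labels, accel, manifest)`` where ``labels`` maps
    ``"valence"``/``"arousal"`` to per-trial :class:`LabelVector`s and
    ``manifest`` records the calibrated effect gains and exact artifact
    locations.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    bands = default_bands()
    n_trials = cfg.n_subjects * cfg.n_trials_per_subject
    n_ch = len(cfg.channels)
    n_samp = int(round(cfg.fs * cfg.trial_s))
    lo, hi = cfg.label_scale

    labels = {
        name: LabelVector(rng.uniform(lo, hi, size=n_trials), cfg.label_scale)
        for name in ("valence", "arousal")
    }
    z = {name: (lv.values - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12))
         for name, lv in labels.items()}

    data = _pink_rows((n_trials, n_ch, n_samp), cfg.noise_exponent,
                      rng) * cfg.noise_sigma

    ch_index = {c: i for i, c in enumerate(cfg.channels)}
    manifest: dict = {"effects": [], "asymmetry_effects": [],
                      "motion_trials": [], "spike_trials": [],
                      "suppression_trials": [], "bad_trials": [],
                      "seed": cfg.seed}

    for k, (electrode, band_name, target, r) in enumerate(cfg.effects):
        beta = _calibrate_beta(r, bands[band_name], cfg.component_sigma,
                               cfg.noise_sigma, cfg.noise_exponent, cfg.fs,
                               seed=(cfg.seed * 1000 + k) % (2**31 - 1),
                               trial_s=cfg.trial_s)
        comp = _band_rows((n_trials, n_samp), bands[band_name], cfg.fs, rng,
                          stabilize_win=int(round(cfg.fs)))
        amp = cfg.component_sigma * np.exp(beta * z[target] / 2.0)
        data[:, ch_index[electrode], :] += amp[:, None] * comp
        manifest["effects"].append(
            {"electrode": electrode, "band": band_name, "target": target,
             "r": r, "beta": float(beta)})

    for k, (pair, band_name, target, r) in enumerate(cfg.asymmetry_effects):
        beta = _calibrate_beta(r, bands[band_name], cfg.component_sigma,
                               cfg.noise_sigma, cfg.noise_exponent, cfg.fs,
                               seed=(cfg.seed * 1000 + 500 + k) % (2**31 - 1),
                               trial_s=cfg.trial_s)
        left, right = pair
        for name, half in ((left, +0.5), (right, -0.5)):
            comp = _band_rows((n_trials, n_samp), bands[band_name], cfg.fs,
                              rng, stabilize_win=int(round(cfg.fs)))
            amp = cfg.component_sigma * np.exp(half * beta * z[target])
            data[:, ch_index[name], :] += amp[:, None] * comp
        manifest["asymmetry_effects"].append(
            {"pair": list(pair), "band": band_name, "target": target,
             "r": r, "beta": float(beta)})

    epochs = EpochSet(
        data=data, fs=cfg.fs, channel_names=cfg.channels,
        subject_ids=np.repeat(np.arange(cfg.n_subjects),
                              cfg.n_trials_per_subject),
    )
    accel = _synth_accel(n_trials, int(round(cfg.fs_accel * cfg.trial_s)),
                         cfg.fs_accel, rng)

    motion_trials = np.flatnonzero(rng.random(n_trials) < cfg.motion_rate)
    if motion_trials.size:
        epochs = inject_motion(epochs, accel, motion_trials, cfg.motion_gain,
                               seed=cfg.seed % (2**31 - 1))
    manifest["motion_trials"] = motion_trials.tolist()

    spike_trials = np.flatnonzero(rng.random(n_trials) < cfg.spike_rate)
    for i in spike_trials:
        ch = rng.integers(n_ch)
        pos = rng.integers(10, n_samp - 10)
        width = 5
        bump = 8 * cfg.noise_sigma * sps.windows.hann(width)
        epochs.data[i, ch, pos:pos + width] += bump
    manifest["spike_trials"] = spike_trials.tolist()

    supp_trials = np.flatnonzero(rng.random(n_trials) < cfg.suppression_rate)
    supp_len = int(round(0.3 * cfg.fs))
    for i in supp_trials:
        pos = int(rng.integers(0, n_samp - supp_len))
        epochs.data[i, :, pos:pos + supp_len] *= 0.05
    manifest["suppression_trials"] = supp_trials.tolist()

    bad_trials = np.flatnonzero(rng.random(n_trials) < cfg.bad_trial_rate)
    if bad_trials.size:
        epochs = inject_bad_trials(epochs, bad_trials, cfg.bad_trial_ptp)
    manifest["bad_trials"] = bad_trials.tolist()

    return epochs, labels, accel, manifest
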