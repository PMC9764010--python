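# Methods

This note records the models, conventions, and design choices behind
`eegaffect`, and what the synthetic-data experiments do and do not show.

## Signal model and conventions

All amplitudes are microvolts; sampling is 128 Hz on the 14-channel 10–20
consumer montage unless configured otherwise. The montage's four scalp
regions are frontal {F3, F4, F7, F8, AF3, AF4, FC5, FC6}, temporal
{T7, T8}, parietal {P7, P8}, occipital {O1, O2}; the seven homologous
left/right pairs are (F3,F4), (F7,F8), (AF3,AF4), (FC5,FC6), (T7,T8),
(P7,P8), (O1,O2) — the only homologous pairing the montage admits.
Variance is population-normalised (divide by n) throughout, so Hjorth
ratios, standard deviation, and differential entropy are internally
consistent. Trials within one `EpochSet` share a length; heterogeneous
recordings are represented as several sets or pre-cropped.

## Preprocessing

*Referencing* subtracts the instantaneous cross-channel mean (idempotent,
linear). *Filtering* is a 4th-order Butterworth band-pass, 0.1–40 Hz by
default, applied forward–backward (zero phase). The zero-phase choice is
deliberate: single-pass IIR filtering would shift feature timing within
1-s windows. Consequence: quoted stop-band attenuations are those of the
squared magnitude response, and edge transients from the 0.1 Hz pole decay
over seconds — trials shorter than a few seconds retain some transient.

*Motion scrubbing* decomposes each trial with FastICA (deterministic given
a seed; `max_iter=2000`, `tol=1e-6` — tight convergence matters because a
partially converged rotation smears a high-variance artifact direction
across several sources). Accelerometer axes are linearly resampled to the
EEG grid; sources whose |Pearson r| with any axis exceeds that axis's
mean + 2·SD across sources are high-pass filtered at 3 Hz (motion energy
lives below ~3 Hz) and the trial is remixed through the mixing matrix.
Absolute correlation is used because ICA sign is indeterminate. After
average referencing the trial is rank-deficient by one; the decomposition
then fits rank-many sources. Trials without an accelerometer trace pass
through with a warning; trials with no flagged source are bit-identical.

*Trial rejection* searches a candidate peak-to-peak threshold grid
(default: 30 values between the 1st and 99th percentile of observed trial
peak-to-peak amplitudes) with K-fold cross-validation (default K = 10).
The retained-train-mean vs validation-median Frobenius error follows the
interpretation that the training mean is taken over the *good* trials
`G_l` only. A candidate that empties `G_l` in a fold receives an infinite
error there; ties in the mean error resolve to the smallest threshold
(the most aggressive of the equal-error options), and rejection uses
`ptp(X_i) >= T*`. The local variant runs the same search per channel.

## Feature battery

The default battery is 25 codes: five sub-band entropies (S.E.A/B/D/G/T),
Hjorth mobility and complexity, median frequency, five band powers,
standard deviation, sharp-spike count, and five DASM + five RASM pair
features. Numerical conventions worth noting:

- **Shannon entropy**: fixed-width histogram, 32 bins over the window's
  [min, max], natural log. A constant window scores 0; so does the SIQ of
  a constant window (filtering residue is not treated as band content).
- **Band isolation** for SIQ, band power, and pair features uses a single
  order-7 Butterworth band-pass (zero-phase). The gamma band's 45 Hz edge
  exceeds the 40 Hz preprocessing low-pass; gamma features are computed on
  whatever survives, which mirrors how such pipelines behave in practice.
- **Band power** is the mean periodogram power of the band-filtered
  window, in µV².
- **Differential entropy** uses the Gaussian closed form ½ln(2πeσ̂²);
  DASM/RASM are its difference/ratio across a pair, per band.
- **Spikes** are `find_peaks` maxima above mean + 3·SD with ≥ 7 samples
  separation; a *sharp* spike's above-threshold excursion lasts < 70 ms
  (9 samples at 128 Hz). The delta-burst-after-spike change is
  after-minus-before (7-sample means of the delta-filtered copy); a
  `mode="sum"` switch provides the additive reading. Note that the
  order-7 delta filter's rise time exceeds the 7-sample span, so a raw
  amplitude step appears attenuated in this feature.
- **Bursts** are runs of |x| above mean(|x|) + 2·SD(|x|); the rule cannot
  flag runs occupying more than ~20% of the window (they lift their own
  threshold). **Suppressions** are runs of |x| < 10 µV lasting ≥ 0.1 s.
- Non-finite feature values (e.g. Hjorth mobility of a flat window) are
  imputed as 0 and counted in the log.

`extract_features` shares band-filtered tensors across features and is
tested to agree with the scalar operations.

## Selection and evaluation

Columns are screened by a variance filter (threshold 0, with an exact
constant-column check to defeat floating-point residue). Each surviving
column's F-score is `ρ²/(1−ρ²)·(n−2)`; per-feature and per-electrode
scores are the mean of the code's (or electrode's) column scores — the
aggregation was an open choice; the mean is the default and `max` is kept
as an option. Pair columns are excluded from electrode attribution. Ties
resolve by canonical order (montage order for electrodes, alphabetical
code for features). Region summaries pool the top-k electrodes of one or
more ranking tables and report integer-truncated percentages.

Splits are at segment level (each 1-s segment is a sample carrying its
trial's label), mirroring how such pipelines are usually scored; a
consequence — demonstrated by the null experiments below — is that
segment rows of one trial are not independent, so segment-level F-tests
on multi-second trials are anti-conservative. LOSO avoids the worst of
this by holding out whole subjects. Rankings are computed once, not
re-ranked per LOSO fold, to keep label information out of the held-out
subject. The regressor is a 100-tree squared-error random forest with
library-default depth settings, seeded for bit-reproducibility.

Metrics follow the standard definitions (RMSE, R², MAE, explained
variance). EV differs from R² only through the mean residual; for
`y=[1,2,3]`, `ŷ=[2,2,2]` the residuals have zero mean and EV = R² = 0,
while a constant-offset prediction gives EV = 1 with R² < 0.

## Synthetic data

The generator emulates an image-viewing campaign: by default 15 subjects ×
40 five-second trials at 128 Hz, ratings uniform on 1–10, background
1/f-exponent-1 noise at 10 µV, and sparse artifacts (motion leakage rate
0.1, spikes 0.05, suppressions 0.05, high-amplitude bad trials 0.05 at
400 µV peak-to-peak). Affective structure is planted per
(electrode, band, label, r) entry: an order-7 band-filtered noise
component whose power is modulated as exp(β·z) in the standardised label
z, with β calibrated by common-random-number root finding so that the
segment-level band-power/label correlation hits the requested r. Each 1-s
window of the planted component is normalised to unit power before
modulation ("envelope stabilisation"): without it the chi-squared power
fluctuation of filtered noise inside 1-s windows caps the achievable
correlation near 0.55, below useful planting targets. Accelerometer
traces are low-pass (<3 Hz) random walks.

What the synthetic experiments show: that every stage recovers exactly
the structure planted under its assumptions — contaminated trials, a
motion-correlated source, a label-coupled electrode/feature — and that
the F-test is calibrated on independent null rows. What they do not show:
performance on real EEG, which has non-stationary rhythms, eye-blink and
EMG morphology, volume-conducted correlations between channels, and
rating noise, none of which the generator models. Headline error numbers
on public affect datasets are therefore outside what this repository can
verify.

## Known limitations

- ICA cannot reliably isolate *Gaussian* low-frequency motion: when the
  walk subspace spans several sources, the mean + 2·SD flag may miss it
  (~7% of random draws in the single-axis planting experiment). This is
  an identifiability limit of correlating ICA sources with near-Gaussian
  regressors, not a coding defect.
- The null calibration experiment uses 1-s trials so that feature rows
  are independent; with multi-second trials the shared slow background
  plus repeated labels inflates segment-level F-statistics
  (pseudo-replication inherent to segment-level scoring).
- Problem sizes in the tests and the acceptance script (hundreds of
  trials, 10-seed repetitions, 3000-segment ranking runs) were chosen to
  make the statistical checks decisive while keeping the default suite
  quick to run.
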