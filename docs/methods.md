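# Methods

`eegscape` is a tested re-implementation of a band-resolved EEG decoding
pipeline for landscape perception: subjects watch videos of seven landscape
types (forest, wetland, grassland, desert, water, farmland, city) while
32-channel scalp EEG is recorded; the pipeline asks how well the landscape
class can be decoded from band-power-derived features of 2-s EEG segments,
and how that decodability depends on frequency band, feature family, and
classifier.  Because no public recording of this paradigm is available, the
package ships a synthetic generator that reproduces the study design and
gives every downstream stage a controllable ground truth.

## Study design emulated by the generator

One session is 14 stimulus blocks of 40 s (7 classes x 2 repeats, seeded
random order) separated by 60 s rests, with 5 s of lead-in/lead-out so that
filter edge effects land outside the blocks.  The default study has 20
subjects.  Signals are generated at 500 Hz so the 250 Hz downsampling stage
is exercised non-trivially.

Per channel the signal is a sum of:

- **1/f^alpha background** (alpha = 1.0, total power 64 uV^2 ~ 8 uV RMS),
  synthesized directly in the frequency domain (complex Gaussian spectrum
  coefficients scaled by f^(-alpha/2), one inverse FFT) — statistically
  identical to spectrally shaping white noise;
- **five narrowband oscillations**, one independent band-limited Gaussian
  process per canonical band, with baseline RMS amplitudes
  delta 5 / theta 4 / alpha 6 / beta 3 / gamma 2 uV — the usual ordering of
  resting scalp EEG band amplitudes at the uV scale;
- **artifacts**: 400 ms raised-cosine eye blinks (Poisson, 10/min, 150 uV at
  the frontopolar row, loading falling off with the squared anterior
  coordinate) and a common 50 Hz line-noise sinusoid (2 uV).

Class information enters as multiplicative band-power gains inside a
class's blocks ("class signatures").  The default signatures put log-spaced
gamma-band power gains exp(effect_size * u_k), u_k uniform on [-1, 1],
across the seven classes, reversed-order beta gains at 60% of the
log-effect, and a small left-right differential (asymmetry 0.1, log scale)
riding on gamma.  This mirrors the study's central finding — high-frequency
bands carry the discriminative signal — at the only level at which it can
be built into a simulator.  The default `effect_size` is 1.0, chosen so
that within-subject gamma-band decoding sits well above chance (roughly
70-90% with 7 classes) while delta/theta/alpha stay near chance, i.e. the
qualitative regime the study reports; `effect_size = 0` is an exact null
model (all gains identically 1).  Per-subject variability is a log-domain
gain jitter, gain^(1+u) with u ~ U(-0.1, +0.1), which leaves the null
model invariant by construction.

What the generator deliberately does **not** model: volume conduction and
correlated sources (channels are independent up to the common reference,
line noise and blink topography), non-stationarity within blocks, fatigue
or habituation across the session, and any realistic spatial structure of
the perceptual response.  Passing trend tests on this data therefore shows
that the pipeline recovers the structure that was put in — not that real
landscape EEG is decodable at these accuracies.

## Preprocessing

Canonical stage order: mastoid re-reference (subtract 0.5*(TP9+TP10), drop
the references) -> per-channel linear detrend -> polyphase resampling to
250 Hz -> zero-phase 4th-order Butterworth band-pass 0.5-70 Hz -> artifact
removal -> segmentation.  The stage list follows the study's description;
the exact order is declared canonical here because the source text
interleaves re-referencing and detrending ambiguously.

Artifact removal is contract-driven (reduce frontal blink power, preserve
clean channels' spectra) with three interchangeable methods: `ica`
(scikit-learn FastICA; components rejected when frontally dominated —
frontopolar loading > 2x the channel average — with time-course excess
kurtosis > 3; the unmixing matrix is fit on every 4th sample and applied to
the full record), `regression` (low-passed frontopolar average regressed
out of every channel), and `none`.

Segmentation cuts non-overlapping 2-s windows (500 samples at 250 Hz) from
each annotated block onset forward, keeps the montage's 29 feature
channels, discards trailing partial windows, and rejects any window with
|x| > 100 uV (the study states rejection but no threshold; 100 uV
peak-to-zero is the conventional default).  A clean 40-s block yields 20
epochs; a clean session 280; a clean 20-subject study 5600.

## Montage

The default cap is the standard 32-channel LiveAmp/actiCAP 10-20 layout.
The source never lists which channels are excluded from its 29-channel
feature set nor its exact pairings, so the package adopts the
self-consistent assignment that reproduces every published count: TP9/TP10
are the references, Oz is additionally excluded (29 = 32 - 3), the 13
left-right pairs are the 12 mirror pairs plus (FT9, FT10), and the 11
frontal-posterior pairs run along matched lateral lines
(Fp1-O1 ... Fz-Pz).  The montage is validated on load and replaceable
through the config file.

## Features

Per epoch, per band (delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma
30-70 Hz; bins half-open [lo, hi) with gamma's upper edge inclusive, so
shared printed endpoints are never double-counted):

- **MAS** = ln(mean one-sided Hann-tapered FFT amplitude over band bins),
  29 values;
- **PSD** = ln(mean Hann periodogram density over band bins), 29 values;
- **DE** = 0.5 ln(2 pi e sigma_b^2), 29 values, where sigma_b^2 is the
  band variance of the epoch;
- **DASM_i = DE(left_i) - DE(right_i)** and **RASM_i = DE(left_i)/DE(right_i)**
  over the 13 mirror pairs (RASM denominators with |DE| < 1e-6 are flagged
  NaN and the affected rows are dropped from designs);
- **DCAU_i = DE(frontal_i) - DE(posterior_i)** over the 11 caudal pairs.

The "total" band is the ordered concatenation of the five per-band vectors
(145/145/145/65/65/55 dims), which is the only reading consistent with the
published dimension table.  Natural log everywhere; the log base, backend
and bin convention are recorded in each feature table's metadata sidecar.

**DE backend.**  The band variance sigma_b^2 is estimated by default as the
variance of the epoch's orthogonal projection onto the band's discrete
Fourier subspace (un-tapered periodogram summed over band bins x bin
width) — an ideal zero-phase brick-wall band-pass evaluated exactly within
the epoch.  This choice is deliberate: on 500-sample epochs a realizable
time-domain filter loses 3-7% of band variance (edge transients for narrow
bands, passband droop for wide ones), a bias roughly ten times the Monte
Carlo standard error of a 1000-epoch conformance experiment, whereas the
projection estimator recovers the realized band variance of an in-band
signal exactly.  Its cost is rectangular-window sidelobe leakage from
strong out-of-band components, which matters little here because epochs
are already band-passed to 0.5-70 Hz and the leakage is class-independent.
Two alternative backends are provided and tested: `hann` (tapered
periodogram band sum) and `filter` (zero-phase 4th-order Butterworth,
odd-reflection padding, padlen 100).

## Classification

Per-subject 7-class decoding for every (family x band) cell with four
classifiers at the study's settings: KNN (k=5), random forest (500 trees),
linear-kernel SVM (C=1, native one-vs-one), and a back-propagation MLP
(unspecified in the source; here one hidden layer of 64 units, early
stopping on a 10% inner validation split, at most 500 iterations).

The source states both an 80/20 split and 10-fold cross-validation without
relating them; the canonical protocol here is stratified 10-fold CV over
all of a subject's epochs (each fold ~10% test), with the 80/20 stratified
holdout available as `protocol="holdout"`.  Features are standardized per
column on training-fold statistics only.  Fold assignment is seeded from
(global seed, subject id), so subjects are independent but every run is
reproducible; two runs from one seed produce byte-identical grid files.
Accuracy is the mean over held-out folds; the confusion matrix accumulates
over folds and yields per-class sensitivity (recall).  Aggregation across
subjects reports mean +/- SD (ddof = 1); the SD is across subjects, not
folds, matching the published table's shape.  `best_per_subject` reports
all tied argmax cells, ordered (band, family, classifier).

## Problem sizes used in tests and the acceptance script

Exact-arithmetic checks (epoch bookkeeping, dimensionalities) run at the
full 20-subject scale.  The statistical checks run on scaled-down studies
chosen as the package's own test sizes: 5 subjects for null calibration
(1400 held-out predictions; the 99% binomial band around 1/7 at that count
is +/-2.4 points) and for the band/family trend comparisons; the DE
conformance experiment uses 1000 band-limited Gaussian epochs conditioned
to exact realized variance, so the closed form must hold to machine
precision.  The trend checks compare, per classifier, min(gamma, beta)
against max(delta, theta, alpha) for the DE family, and min(MAS, PSD, DE)
against max(DASM, RASM, DCAU) at gamma on an asymmetry-free study — the
spatial families are informative only through the left-right differential,
so removing it makes the expected ordering strict.

## Known limitations

- Published accuracy values were measured on undeposited human EEG and are
  not reproducible from synthetic data; only their orderings are.
- RASM inherits the sign instability of near-zero DE denominators; the
  sentinel threshold (1e-6) is a pragmatic choice.
- The ICA component-selection thresholds are defaults tuned to the blink
  model, not validated selection criteria for real ocular/EMG/ECG mixtures.
- The EDF writer emits 16-bit, 1-s-record files with a fixed start stamp
  and +/-1000 uV physical range (~0.03 uV quantization); it is intended
  for synthetic data interchange, not clinical archiving.
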