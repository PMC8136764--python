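# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `remstage`.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

The pipeline operates on one EEG channel in microvolts.  Conventionally
this is C3-A2 with C4-A1 as fallback; the reader accepts any label or
index, and the fallback order is a configurable list.

* **Resampling.**  All analysis happens at 256 Hz.  Arbitrary input rates
  are converted by polyphase rational resampling (`scipy.signal.
  resample_poly`, rational approximation with denominator ≤ 1000), which
  is deterministic and anti-aliased.  Resampling happens *before*
  filtering, so the filter cutoffs are fixed fractions of 256 Hz.
* **Band limiting.**  Chebyshev type-I filters: high-pass order 1 at
  0.5 Hz, low-pass order 11 at 40 Hz, passband ripple 1 dB (a
  conventional design value, exposed in `PreprocessConfig`).  Both are
  applied forward and backward (`sosfiltfilt`, second-order sections for
  numerical stability), which doubles the effective order; the design
  intent is zero-lag behaviour, not a specific transfer function.  Edge
  transients of the order-11 low-pass decay over several seconds and are
  excluded when tests measure steady-state attenuation.
* **Segmentation.**  0-based, half-open sample intervals throughout:
  epoch *i* holds samples [7680·i, 7680·(i+1)).  Trailing partial epochs
  are dropped; unscorable epochs (UNSCORED) are discarded by default.  A
  hypnogram/signal length mismatch truncates to the shorter with a
  warning.  No artefact removal or spatial filtering is performed.

## Hypnogram dialects

Stage files are plain text, one token per line, mapped through editable
YAML tables (`data/dialects.yaml`).  The `simple` dialect (W/R/1/2/3,
unscorable 0/−1/−2) is normative and round-trips losslessly.  `dreams`
(numeric codes per 5-s scoring epoch) and `cap` (R&K-style labels) are
shipped as editable defaults for archive exports.  Native epochs shorter
than 30 s are aggregated by majority vote; ties map to UNSCORED — a
conservative choice, since UNSCORED epochs are discarded anyway — and a
trailing partial scoring window is dropped.

## Spectral estimation

* Per 1-s sub-epoch: Hann-windowed periodogram, giving exactly 1 Hz bins
  at 256 Hz.
* Per 30-s epoch (band derivation): Welch with 1-s rectangular segments
  and 50% overlap.  Rectangular segments keep a bin-aligned tone in a
  single bin, so edge frequencies of narrowband signals are bin-exact;
  for broadband EEG the window choice is immaterial.
* Band powers sum density·Δf over **half-open** [lo, hi) bin masks, so
  adjacent bands tile without double counting and band power is additive
  at bin-aligned boundaries.  Relative powers divide by total power over
  the 0.5–40 Hz analysis band.
* Spectral edge frequencies use a **closed** [lo, hi] support (otherwise
  the top bin would be unreachable) and are bin-resolution: the smallest
  grid frequency whose cumulative in-band power fraction reaches the
  requested quantile.  No interpolation between bins; this makes the
  values reproducible and testable.  SEF of a zero-power spectrum is
  undefined and raises; the feature extractor maps this degenerate case
  to 0 with a logged warning.
* Energy density is band power divided by bandwidth — the literal reading
  of the term, stated here because it admits alternatives.

## Phasic/tonic band derivation

For each REM epoch the Welch spectrum yields (SEF50, SEF95).  With the
per-epoch values collected, "belonging to the Nth percentile" is read as
*≤ the 25th percentile value* for the lower tail and *≥ the 75th* for the
upper, percentiles computed with the linear-interpolation convention.
The FREM bounds are the means of the lower-tail SEF50 and SEF95 subsets;
the TREM bounds the means of the upper-tail subsets; bounds are rounded
to integer Hz for reproducible band definitions.  The lower tail defines
the phasic band because phasic REM carries delta/theta power and tonic
REM alpha/beta power.  At least 4 epochs are required so the quartile
subsets are non-empty.  The derivation is global — individual micro-states
are never classified.

When a recording has no REM annotations, the reference bands FREM =
2–8 Hz, TREM = 7–16 Hz are used (`remstage.DEFAULT_BANDS`).

## The 164-feature registry

The registry (auditable in `data/feature_manifest.yaml`, mirrored by
`remstage.features.REGISTRY`) fixes the feature inventory:

| category       | families                                                             | count |
|----------------|----------------------------------------------------------------------|------:|
| time           | 7 moment/order stats; Hjorth (signal + 1st difference); ZCR; p25/p75/p95 + two differentials; envelope peaks (count, prominence, width); coastline (1st, 2nd difference) | 24 |
| frequency      | absolute + relative power in delta/theta/alpha/sigma/beta/gamma; SEF50/SEF95/SEFd; FREM/TREM absolute power, relative power, energy density; spectral + approximate entropy; 7 FFT-magnitude stats | 30 |
| time-frequency | 7 STFT-magnitude stats + max spectral density (0–40 Hz, 0.25-s frames); per sub-band energy, relative energy, mean, std, skewness, kurtosis, max, min for 5-level Daubechies-4 and Haar decompositions (6 sub-bands each) | 104 |
| non-linear     | TKEO mean, std, skewness, kurtosis, max, min                         | 6 |

Decisions behind the inventory:

* Time features are computed on the whole 30-s epoch; every other family
  is computed per 1-s sub-epoch and arithmetically averaged over the 30
  sub-epochs (short windows give approximate wide-sense stationarity).
* Clinical band edges follow AASM convention: delta 0.5–4, theta 4–8,
  alpha 8–13, sigma 12–16, beta 16–30, gamma 30–40 Hz (alpha and sigma
  deliberately overlap at 12–13 Hz).
* Hjorth mobility/complexity use the plain first difference, so a pure
  tone of angular frequency ω rad/sample has mobility 2·sin(ω/2); the
  sampling-rate factor is a constant that min–max scaling removes.
  "Derivative" features elsewhere (coastline, Hjorth-of-derivative) use
  first/second differences likewise.
* Percentile differentials: both p75−p25 and p95−p25 are included.
* Envelope = magnitude of the analytic signal; peaks via
  `scipy.signal.find_peaks` with mean prominence and mean half-height
  width.
* Approximate entropy uses m = 2, r = 0.2·σ of the sub-epoch (standard
  parameters), computed with an incremental Chebyshev distance-matrix
  construction and cross-checked against a brute-force oracle in the
  tests.  Spectral entropy is the Shannon entropy (nats) of the
  bin-normalized density over 0.5–40 Hz.
* Wavelet decompositions use `mode="periodization"`, making both db4 and
  Haar transforms orthogonal so sub-band energies sum exactly to signal
  energy (asserted at 1e-6 relative).  Daubechies-4 is the primary
  wavelet; Haar is the second filter.
* TKEO is Ψ[n] = x[n]² − x[n−1]·x[n+1] on the full band-limited signal.
* Degenerate inputs (flat sub-epochs, zero spectra) yield 0 for
  ratio-type and undefined-moment features, with a logged warning — the
  extractor never emits NaN.
* Every registry entry carries an amplitude-equivariance tag (invariant /
  linear / quadratic) that a property test enforces feature by feature.

## Scaling and selection

Min–max scaling maps each fitted column onto [−1, 1]; constant columns map
to 0; unseen values are *not* clipped.  The variance filter keeps scaled
columns with population variance ≥ 0.2 (the "≥" is deliberate, matching
the stated rule).  Inside cross-validation both are re-fitted on every
training fold to avoid leakage; a global fit is what the CLI `train`
command uses on its full training CSV.

## Classifiers

* **K-NN**: K = 10, Euclidean metric, inverse-distance-weighted votes.
* **Random forest**: 30 trees; the per-tree complexity cap is
  max(2, ⌊0.2·NF⌋) split nodes (NF = post-selection feature count),
  implemented as `max_leaf_nodes = cap + 1`; per-node random feature
  subsets as usual.
* **RUSBoost** (own implementation): 30 rounds of SAMME-style boosting;
  each round draws, uniformly without replacement, n_min samples per
  class (n_min = least-represented class size), fits a weak tree under
  the same node cap using the current boosting weights, and reweights on
  the full set.  Rounds with error ≥ 1 − 1/K are discarded; a perfect
  weak learner ends boosting.  `round_class_counts_` records the
  per-round class counts for auditing.
* **DT/SVM** (binary task): unrestricted-depth decision tree; RBF-kernel
  SVM (kernel unstated upstream, RBF chosen as the default and
  configurable).
* Ties (equal votes, equal boosted scores) resolve toward the lowest
  class index; all stochastic components are seeded.

Class rebalancing: `undersample_to_mean` reduces a dominant stage
(typically N2) to the rounded mean count of a named set of other classes
— default {REM, N1, N3}, i.e. the other *sleep* stages — before training.
The binary task discards wake epochs and merges N1/N2/N3 into NREM.

## Evaluation

Per-class metrics come from one-vs-rest confusion counts: accuracy =
(TP+TN)/n, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision
= TP/(TP+FP), F1 the harmonic mean.  0/0 ratios are reported as 0 and
flagged.  A micro-averaged row over pooled one-vs-rest counts accompanies
the per-class table, since per-class columns and micro-averaging answer
different questions on imbalanced data.  Cross-validation schemes:
stratified k-fold (k = 10 default, k = 5 for the smaller protocols),
stratified 80/20 holdout, and leave-one-out for the binary task.
Stratification is a deliberate choice: it keeps the scarce N1 class in
every training fold.  Predictions are pooled over folds and metrics
computed once on the pool.  The binary task's MSE column equals the
pooled misclassification fraction (1 − accuracy).

## Synthetic data

`remstage.synthetic` draws each 30-s epoch in the frequency domain:
complex Gaussian coefficients shaped by the stage profile's relative band
powers over non-overlapping synthesis bands, inverse-FFT'd, scaled to the
profile's RMS amplitude (µV), plus a small broadband noise floor (2% of
power by default).  N2 adds 13 Hz spindle bursts and phasic REM 3 Hz
sawtooth bursts (1–2 s, Hann-enveloped, 2 per epoch at 1.25× RMS), which
keep realized band powers within the generator's ±0.05 contract.  Stage
profiles encode the expected physiology — alpha-dominant wake,
theta-dominant N1, sigma-augmented N2, delta-dominant N3 — and REM epochs
are drawn phasic-like (delta/theta-weighted) or tonic-like
(alpha/sigma-weighted) with a configurable mixing fraction, making the
per-epoch SEF distribution bimodal.  Hypnograms follow a repeating
AWA→N1→N2→N3→N2→REM cycle with seeded visit durations.  All randomness
descends from one root seed via `numpy.random.SeedSequence.spawn`.

The profiles are deliberately well separated in spectrum and amplitude;
classifier recovery on this substrate (REM sensitivity/specificity ≥ 0.9
under 5-fold CV, in practice ≈ 1.0) demonstrates that the pipeline is
wired correctly, **not** that comparable accuracy is attainable on
clinical EEG, where stages overlap, artefacts abound and scorers
disagree.  The generator also makes no attempt at realistic waveform
morphology (K-complexes, eye movements, muscle tone).

For the ablation experiment, `make_band_ratio_dataset` builds a binary
REM-vs-N2 substrate in which the discriminative cue is a narrow 1-Hz
component at 7–8 Hz (REM, inside the tonic band) versus 5–6 Hz (N2,
outside it).  Both placements sit inside the clinical theta band and the
same 4–8 Hz wavelet detail sub-band with equal bandwidth; a random
per-epoch spectral tilt, a class-independent slow-wave distractor and
gain jitter blur the remaining cues, and the component's power fraction
is drawn per epoch so class distributions overlap.  Under these
conditions removing the six FREM/TREM power/energy features strictly
decreases leave-one-out K-NN accuracy — the directional claim the
acceptance suite asserts.  Wavelet filters are not brick-wall, so some
placement information still leaks into detail-band features; the
contrast was designed so this leakage is weaker than the tonic-band cue.

## Problem sizes

The seeded experiments use 200 epochs per stage (1000 total) for
parameter recovery and 150 epochs per class (300 total) for the ablation
— sizes at which feature extraction and cross-validation complete in
about a minute each while keeping Monte-Carlo variation well inside the
asserted margins.

## Known limitations

* The EDF writer covers the single-channel, integer-rate, 16-bit case the
  pipeline produces; it is not a general EDF+ writer (no annotation
  channels, no multi-signal files).
* DREAMS/CAP dialect tables are plausible defaults, not validated against
  archive exports; they are meant to be edited.
* Fold-wise scaling/selection is the default; a pipeline trained via the
  CLI fits globally on its training CSV, and the two can select slightly
  different feature subsets.
* SEF values are bin-resolution (1 Hz); interpolated edges would differ
  by up to half a bin.
* The approximate-entropy tolerance r tracks each sub-epoch's own σ,
  making the feature amplitude-invariant; band-limited 1-s windows give
  it limited dynamic range.
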