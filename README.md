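# remstage

Automatic sleep-stage classification from a **single raw EEG channel**,
built around features that describe the micro-structure of REM sleep.

Polysomnography is the clinical gold standard for sleep scoring, but it is
costly and burdensome; a reliable single-electrode method would make home
sleep monitoring practical, in particular for following REM sleep behaviour
disorder, a parasomnia that is prodromal for Parkinson's disease.  The
difficulty is that REM sleep shows low-amplitude, mixed-frequency EEG that
is easily confused with wake and N1.  `remstage` addresses this by
exploiting the fact that REM is not homogeneous: it alternates between
*phasic* periods (eye-movement bursts, sawtooth waves, increased
delta/theta power) and *tonic* periods (quiescence, increased alpha/beta
power).

## Method

For a recording resampled to 256 Hz and band-limited to 0.5–40 Hz with
zero-phase Chebyshev-I filters (high-pass order 1 at 0.5 Hz, low-pass
order 11 at 40 Hz), each 30-s epoch *e* scored as REM contributes a
spectral-edge pair

    SEF50(e) = min{ f : P(≤f)/P ≥ 0.50 },   SEF95(e) = min{ f : P(≤f)/P ≥ 0.95 }

computed from a Welch spectrum over 0.5–40 Hz.  Two frequency bands are
then derived from the distribution of these values over all REM epochs:

* **FREM** (phasic band): lower bound = mean of the SEF50 values in the
  lower quartile (≤ 25th percentile), upper bound = mean of the SEF95
  values in the lower quartile;
* **TREM** (tonic band): the same with the upper quartile (≥ 75th
  percentile);

rounded to integer Hz.  On the reference dataset this construction yields
FREM = 2–8 Hz and TREM = 7–16 Hz, which ship as the package defaults for
recordings without REM annotations.

Every epoch is then described by **164 features** in four categories —
time statistics, Hjorth parameters, zero crossings, percentiles, envelope
peaks and coastlines; clinical band powers, SEF50/SEF95/SEFd, absolute
power, relative power and energy density in the FREM and TREM bands,
spectral and approximate entropy, FFT statistics; STFT and two 5-level
wavelet decompositions (Daubechies-4 and Haar); Teager–Kaiser energy
statistics.  Time features use the whole 30-s epoch; all others are
computed per 1-s sub-epoch (1 Hz spectral resolution) and averaged.
Features are min–max scaled to [−1, 1] and columns with scaled variance
below 0.2 are dropped.

Classification uses the study's three configurations: a distance-weighted
Euclidean K-NN (K = 10), a random forest (30 trees, per-tree node cap
0.2·NF for NF selected features), and RUSBoost (30 boosting rounds, every
round randomly undersampled to the least-represented class).  Decision
trees and RBF SVMs are available for the binary REM-vs-NREM task (wake
discarded, N1/N2/N3 merged into NREM, leave-one-out validation).
Performance is reported per class as one-vs-rest accuracy, sensitivity,
specificity, precision and F1, plus a micro-averaged summary.

A seeded synthetic-data module generates stage-labelled EEG with
controllable band powers (including bimodal phasic/tonic REM mixtures),
writes standard EDF + hypnogram CSV files, and serves as the test
substrate in place of clinical recordings.

## Worked example

```bash
$ remstage simulate --out night1 --seed 42 --epochs 120
wrote night1/recording.edf and night1/hypnogram.csv

$ remstage derive-bands --edf night1/recording.edf --hypnogram night1/hypnogram.csv
{"frem": [6.0, 17.0], "trem": [11.0, 25.0]}

$ remstage extract --edf night1/recording.edf --hypnogram night1/hypnogram.csv --out features.csv
wrote 120 epochs x 164 features to features.csv

$ remstage train --features features.csv --model rf --seed 7 --out rf.joblib
trained rf on 120 epochs (118 features) -> rf.joblib

$ remstage evaluate --features features.csv --model rf --scheme kfold --k 10 --seed 7 --out report.json
                     AWA          N1          N2          N3         REM
Accuracy           1.000       1.000       1.000       1.000       1.000
Sensitivity        1.000       1.000       1.000       1.000       1.000
Specificity        1.000       1.000       1.000       1.000       1.000
Precision          1.000       1.000       1.000       1.000       1.000
F1                 1.000       1.000       1.000       1.000       1.000
Overall accuracy: 1.000

$ remstage score --edf night1/recording.edf --model rf.joblib --out scored.csv
scored 120 epochs -> scored.csv (REM 15.0%)
```

The derived bands differ from the clinical defaults because they are
data-dependent: this synthetic night mixes phasic-like and tonic-like REM
epochs whose SEF distribution is wider than real sleep EEG.  The perfect
cross-validated scores reflect the generator's deliberately well-separated
stage spectra — the recovery condition the test suite asserts — not
expected performance on clinical recordings.  The scored REM share (15%)
matches the simulated hypnogram's REM fraction.

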