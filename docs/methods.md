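# Methods

## Problem and approach

Continuous scalp-EEG seizure detection must run on hardware people will
actually wear, which makes the number and placement of electrodes a
first-order design constraint. This package implements a systematic way to
answer "how few electrodes, and which ones?" for a cross-patient
seizure-detection model: extract per-channel spectral features from short
EEG segments, train a gradient-boosted tree classifier per candidate
electrode subset, score it with a recall-restricted precision–recall metric,
and search the subset space in two stages — a sampled sweep over subset
sizes to pick a size, then an exhaustive evaluation of every subset of that
size across repeated patient-level data splits.

Because large annotated clinical EEG corpora are access-restricted, the
package ships a seeded synthetic-cohort generator with the statistical
structure the analysis depends on, so every stage is exercised end to end
without any external data.

## Synthetic cohorts

Each patient is a `PatientProfile`: a seizure onset zone (temporal, frontal,
parietal, occipital) and hemisphere, mapped to a small focal electrode set
on the 19-channel 10–20 montage (e.g. temporal-left → {F7, T3, T5}), plus
background-EEG parameters and a private seed.

**Background.** Per channel: 1/f^β Gaussian noise (β drawn per patient from
[0.8, 1.6], overall amplitude 15–25 µV SD, spectral shaping floored below
0.5 Hz so steep-β patients are not dominated by sub-delta drift) plus a
patient-specific alpha rhythm — a narrowband Gaussian process (1.5 Hz FWHM
around a patient-specific 8.5–11.5 Hz peak) with posterior dominance
(8–14 µV RMS-equivalent over parieto-occipital channels, 2–4 µV
anteriorly). Alpha is narrowband rather than a pure tone both for realism
and because a pure tone is exactly the "non-physiological dominant
component" the rejection rules screen for. This is the minimal model that
reproduces the band-power ratios, spectral slopes and edge frequencies the
features measure; it makes no attempt at biophysical forward modeling.

**Seizures.** Amplitude-modulated chirps sweeping downward through a
configurable band (default 4–9 Hz, i.e. theta with the slowing typical of
focal ictal rhythms), default 40 µV, Tukey onset/offset envelope with a slow
waxing–waning modulation. The discharge is added at full gain to the focal
channels and at a 0.2 leakage factor to their scalp neighbours (first-ring
adjacency). Durations are uniform 25–70 s; every recording carries at least
5 annotated seizures, placed uniformly with a minimum 60 s gap (a deliberate
desk-scale relaxation of clinical interictal criteria) and a 30 s edge
margin; infeasible placements raise an explicit error rather than silently
shortening events.

**Artifacts** (optional, off by default). Three classes, all recorded as
metadata so tests can locate them exactly: amplifier-dropout flatlines
(all channels zeroed — a single-electrode flatline would not survive
re-referencing, so dropout is modeled at the amplifier), high-amplitude
movement-like transients (900 µV, 3 Hz carrier so the bandpass keeps them),
and mains contamination (50 Hz on all non-reference channels). Episodes
avoid annotated seizures by 30 s.

**Cohort structure.** Zone frequencies follow a configurable target
(default 75% temporal, 12% frontal, remainder split parietal/occipital)
through largest-remainder apportionment, hemispheres 50/50. Desk-scale
defaults are 24 patients × 0.5 h at 256 Hz; all scale parameters are
configuration knobs. Equal seeds produce bit-identical cohorts.

What passing tests on this cohort do *not* show: robustness to real
inter-patient variability in ictal morphology, to electrode-contact drift,
eye/EMG artifacts beyond the three injected classes, or to the extreme
class imbalance of week-long clinical recordings (the desk-scale prevalence
of ictal segments is on the order of 10%, not 10⁻³; absolute AUC-PR values
are correspondingly much higher than on clinical data, which is why subset
results are always normalized by the same-split full-montage model).

## Preprocessing

Raw 19-channel potentials are referenced to FP2 (a forehead electrode with
reliable contact), leaving 18 analysis channels; then bandpass filtered
1–40 Hz (4th-order Butterworth, zero-phase forward-backward) with a 50 Hz
notch (IIR, Q = 30, also zero-phase); cut into 20 s segments with 10 s
overlap (half-open intervals, trailing partial windows dropped); labeled
ictal iff the segment overlaps any annotated seizure with positive measure;
and screened by three label-blind rejection rules — peak |amplitude| >
500 µV, any-channel flatline (SD < 0.1 µV), or a single PSD bin carrying
more than 50% of a channel's 1–40 Hz power. All thresholds are
configurable. Rejected segments are flagged after labeling and excluded
from every downstream table.

## Spectral features

Per accepted segment and channel, from a Welch PSD (2 s Hann windows, 50%
overlap, density scaling — 0.5 Hz resolution, so every band edge sits on a
grid point), 17 feature families: broadband root total power; relative and
relative-log power in delta [1–4), theta [4–8), alpha [8–12), beta [12–30)
and gamma [30–50] Hz (normalized by 1–40 Hz broadband power); spectral
moment (mean frequency); 90% spectral edge frequency; normalized spectral
entropy; the slope and intercept of the log-power/log-frequency OLS fit;
and an out-of-range count — how many of {root total power, slope,
intercept, edge frequency} fall outside their empirically normal range,
defined per channel as the [1st, 99th] percentile over the *non-ictal
training* rows of the current split (leakage-free, persisted with the
model).

Numerical conventions worth stating: band membership for relative powers is
half-open so the five bands tile 1–50 Hz exactly; integral-style quantities
(root power, moment, edge frequency) use trapezoidal integration on the
closed band, which makes a flat spectrum give the textbook values (mean
20.5 Hz, SEF 36.1 Hz on 1–40 Hz) at the cost of edge-frequency estimates
for near-point-mass spectra being accurate only to one grid bin; zero bins
are floored at 10⁻¹² of band power before logarithms; a zero-power segment
raises rather than producing NaNs (such segments are rejected upstream).
The gamma band deliberately extends past the 40 Hz filter edge and is
computed as specified on the post-filter PSD; its content is mostly
attenuated, which is visible in the features and intended.

The reduced 5-family mode (relative delta/theta/alpha power, root total
power, out-of-range) exists because the exhaustive stage trains tens of
thousands of models; it was chosen on the domain knowledge that
low-frequency rhythmic power carries most focal-ictal contrast.

## Splitting, balancing, classifier

Splits are made at the patient level: 75% of patients train, 25% test,
repeated (default 20 times), each split preserving the cohort's (zone,
hemisphere) strata through largest-remainder rounding (per-stratum train
counts deviate from the global fraction by at most one patient; singleton
strata cannot be stratified and go to train with a warning). Training rows
are balanced by seeded subsampling of the majority class; test rows are
never balanced. Split k derives its seed as base + k.

The classifier is a LightGBM binary model (cross-entropy objective),
single-threaded and deterministic. Hyper-parameters are tuned once — seeded
random search (default 30 draws over tree count, leaves, learning rate,
child size, λ, column subsampling) on the first split's training patients,
scored by AUC-PR-0.7 on a 75/25 patient-level validation subsplit that
mirrors the outer protocol — then frozen for every subsequent model. The
shipped defaults (60 trees, 15 leaves) are sized for desk-scale cohorts.

## The AUC-PR-0.7 metric

Precision–recall analysis fits seizure detection's imbalance better than
ROC, and sensitivities below 70% are clinically uninteresting, so the
headline metric is

AUC-PR-0.7 = (1/0.3) ∫₀.₇¹ p(r) dr,

integrated trapezoidally along the distinct-threshold PR curve with the
boundary precision at r = 0.7 obtained by linear interpolation; the curve
ends at its first full-recall point (later thresholds only add false
positives at constant recall and zero area). Score ties collapse to a
single threshold, so the metric is sample-order-free and invariant under
strictly monotone score transforms. Tests pin the implementation to a
dense-grid brute-force oracle at 10⁻⁶.

Subset models are reported as percent-of-full-AUC-PR-0.7 — 100 × the
subset's AUC over the same split's all-channel, all-feature model — and
summarized across splits by the median.

## Two-stage search

Stage 1 (`run_size_sweep`): on one split, up to 1000 sampled subsets per
size (every subset when fewer exist — sizes 1–3 and 15–17 of 18 are below
1000), full feature mode, producing the AUC-vs-size scatter from which the
working subset size is read off.

Stage 2 (`run_exhaustive`): every C(n, k) subset × every split (43,758 × 20
= 875,160 models at full scale; the desk-scale tests run C(10, 4) × 3).
Each (configuration, split) work item derives its model seed by hashing the
canonical configuration string with the split id and base seed, making
results independent of execution order and safe to resume: partial result
tables on disk are re-read and only missing pairs are computed. Ranking
ties are broken lexicographically by configuration string.

## Validation experiment

The end-to-end check is focal-electrode recovery
(`experiments.focal_recovery_experiment`): five replicate cohorts of 24
patients (0.5 h each), all temporal-left so the cohort-level focal set
{F7, T3, T5} is known, a 10-channel sub-montage, exhaustive k = 4 over 3
splits per replicate (3,165 models total). Pooled across replicates, the
median percent-of-full of configurations containing all three focal
channels must stochastically dominate that of configurations containing
none (one-sided Mann–Whitney, α = 0.01), and focal channels must
participate more frequently than non-focal ones in the top 5% of
configurations. Problem sizes here are the package's desk-scale choices;
the same code paths run the full-scale protocol unchanged.

## Known limitations

- The generator's ictal signature is a stationary-statistics narrowband
  discharge; real seizures evolve spatially and spectrally.
- EDF output is plain EDF with an annotation CSV sidecar, not EDF+.
- The artifact-rejection rule set is a three-criterion stand-in with
  configurable thresholds, not a validated clinical artifact detector.
- Percent-of-full values can exceed 100 on small test sets (a subset model
  can beat the full model on a given split); this is expected variance, not
  an error.
- Bit-identical reproducibility is guaranteed only in single-threaded mode;
  `--jobs > 1` preserves results up to floating-point-identical models but
  not file ordering.
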