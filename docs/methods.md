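# Methods

`eegdrive` re-implements, as a tested pipeline on synthetic data, the
analysis chain used in EEG studies of driver engagement that contrast
active manual driving (MD) with passive replay of the same drive (AD)
under easy and hard road conditions. This note documents the generative
model, every analysis stage, the numerical choices, and what the synthetic
results do and do not show about real recordings.

## The synthetic study

No public recordings exist for this paradigm, so the package ships a
generator whose defaults define the study conditions. Each of `n_subjects`
(default 11) completes `laps_per_mode` manual-driving laps followed by the
same number of replay laps (the fixed session order of the original
paradigm; an option randomizes lap order for order-confound experiments).
Each lap contains `segments_per_lap` = 20 road segments of 6 s alternating
Easy/Hard (10 vs 10 per lap), and every segment start is marked by an
event carrying its condition and (subject, lap, segment) ids. Signals are
29-channel extended 10-20 EEG at 500 Hz, in microvolts.

Per channel the continuous signal is a sum of:

* **1/f background** — spectrally shaped white noise (slope 1.0, spectrum
  flattened below 1 Hz), with a rank-5 shared spatial mixing (40% of
  variance) so channels are correlated and the noise covariance used by the
  inverse stage is non-trivial; channel sd 6 uV.
* **Planted band-limited oscillations** (`PlantedEffect`) — narrow-band
  *filtered noise*, not sinusoids, so coherence and entropy features are
  non-degenerate. Condition multipliers are band-power ratios relative to
  the pre-onset amplitude: the first 0.5 s of every segment carries the
  baseline amplitude, and the condition scaling ramps in (50 ms Hann
  smoothing) at the event onset, giving each epoch a condition-neutral
  baseline window.
* **Planted coupling** (`PlantedCoupling`) — a shared band-limited source
  mixed into two channel groups as `w*s + sqrt(1-w^2)*n_i`; the analytic
  magnitude-squared coherence of this component between any cross-group
  pair is `w^4`, so `w = strength**0.25` plants the requested coherence.
  The 1/f background dilutes raw-channel coherence below the planted
  component value; the ground-truth record stores the component-level
  number.
* **White sensor noise**, sd 2 uV.

Default planted effects mirror the qualitative findings the pipeline is
meant to recover: frontal-midline theta (4-7 Hz) raised in MD (power x1.8
easy, x2.4 hard); occipito-parietal alpha raised in MD (x1.7/x1.4 vs
x1.2/x0.8); motor beta raised only in MD-Hard (x2.0) — a *mode-specific*
difficulty effect; motor mu suppressed in MD-Easy (x0.5, i.e. ERD); and
fronto-parietal theta/beta coupling stronger in MD (0.55-0.65 vs 0.2).
Between-subject variability is planted two ways, both log-normal: a global
per-subject gain (sd 0.35) and a per-subject exponent on each effect's log
multipliers (sd 0.6 for the mode effects, 0.35 for motor effects), chosen
to reproduce the substantial inter-individual variability that limits
cross-subject classifiers in this literature. All amplitudes put planted
in-band power at roughly 2-4x the in-band background power, a
strong-oscillation regime consistent with the large reported effects.

Seeding: one master seed; per-subject substreams derived via
`numpy.random.SeedSequence.spawn`, so any subject is reproducible in
isolation and identical `(config, seed)` gives bit-identical recordings.

An artifact injector adds stereotyped frontal blink transients
(raised-cosine, < 4 Hz) and band-limited (> 20 Hz) EMG bursts with an
annotation table, for robustness experiments; it is not part of the default
study. ICA-based artifact removal is intentionally out of scope (published
external tooling); the pipeline accepts externally cleaned data.

## Preprocessing

Re-reference (earlobe-average mode for raw-acquisition emulation,
common-average before source analysis — the default), zero-phase band-pass
2-36 Hz (Hamming windowed-sinc FIR, transition width `min(lo, 0.25*lo+2)`
Hz, applied forward-backward), optional 50/100 Hz zero-phase IIR notches,
epoching at -0.4..1.6 s around segment onsets (edge-overlapping events are
dropped and logged), and baseline correction on -0.2..0 s. Channel-level
z-scoring is split into `zscore_fit` (training data only) / `zscore_apply`
so fold contracts can be enforced; the classifier additionally standardizes
features per training fold.

A consequence worth knowing: the 2 Hz transition width implies ~825 filter
taps (about 1.7 s of impulse response), and forward-backward application
smears power across roughly that window. The 0.2 s pre-onset baseline
abuts the active period, so a fraction of active-window band power leaks
into the baseline estimate, attenuating measured ERD/ERS at these short
epoch lengths. Active-window statistics are unaffected.

## Toy source imaging (dSPM)

The forward model is deliberately synthetic: sensors on a unit shell at
standard 10-20 positions, 96 sources on a Fibonacci lattice at radius 0.8
with radial normals, and an unbounded-medium dipole gain
`e . (s - p)/|s - p|^3` followed by an average-reference projection. ROI
sectors (Motor, mPFC, ACC, Visual, PPC, bilateral DLPFC) are contiguous
patches of the sphere assigned to the nearest electrode-group direction
within 60 degrees; `FrontalMidline` is the mPFC+ACC union. No anatomical
accuracy is claimed — the sectors are "putative" regions that sit under
the electrodes whose effects they should capture.

The inverse is a standard regularized minimum norm: noise covariance from
the baseline window with shrinkage 0.1 toward scaled identity (enforced if
the covariance is rank-deficient); diagonal source covariance `R` with
per-source depth weights `|G_i|_F^(-2*0.8)` and transverse orientation
variance `loose^2 = 0.04`; a global rescaling of `R` so the whitened gain
has unit mean sensor power (making `lambda2 = 1/SNR^2 = 0.111` at the
assumed SNR of 3 an interpretable ridge weight); kernel
`K = R G^T (G R G^T + lambda2 C)^-1`. dSPM divides each source by the
projected noise sd (square root of the orientation-triplet sum of
`diag(K C K^T)`), and only the cortical-normal component is kept. With
`loose=1, depth=0` the kernel reduces to the directly computed ridge
solution (tested against that oracle); a planted 10x-noise source is
localized to the true or an adjacent lattice site (within 1.5x the median
nearest-neighbor spacing) in >= 90% of runs.

## Spectral metrics and connectivity

Band power is the mean squared amplitude of the zero-phase band-passed
signal (4th-order Butterworth, applied per epoch) over the 0.1-0.8 s
analysis window; bands are theta 4-7, alpha 8-12, mu 8-13 (Motor only) and
beta 13-30 Hz. ERD/ERS is the percent change of active-window power
relative to the -0.2..0 s baseline. The pipeline computes the percentage
from *trial-averaged* powers: with a 0.2 s baseline the per-epoch power
ratio has a noisy denominator and is upward-biased by well over +100% on
null data, whereas the ratio of trial-averaged powers is approximately
unbiased. The per-epoch formula remains available (`erd_ers`) for
single-trial work. Even trial-averaged, a 4-7 Hz baseline window of 0.2 s
carries < 1 effective degree of freedom per epoch, so desk-scale ERD
estimates are noisy and are reported descriptively.

Connectivity between ROI time courses uses broadband Pearson correlation
(linear coupling) and Welch magnitude-squared coherence (Hann window, 50%
overlap, >= 8 segments; a single-segment coherence is identically 1, and
the estimator is upward-biased by about `1/n_segments` for independent
signals). Welch auto/cross spectra match a direct windowed-DFT
re-implementation to 1e-10.

## Wavelet features

Per epoch and channel, a 5-level db4 DWT yields five sub-bands (A5 ~0-7.8,
D5 7.8-15.6, D4 15.6-31.25, D3 31.25-62.5, D2 62.5-125 Hz at 500 Hz; D1 is
discarded as it lies above the filtered content). Boundary handling is
periodization, with the epoch cropped to the largest multiple of 2^5
(1001 -> 992 samples): this makes the transform exactly orthogonal, so
sub-band energies satisfy Parseval to 1e-8 and entropies are not inflated
by redundant boundary coefficients (symmetric extension is available but
conserves energy only approximately). Per sub-band: mean |c|, energy and
wavelet entropy (natural log, 0 log 0 = 0). Eleven fronto-parietal /
fronto-central / interhemispheric electrode pairs contribute the Pearson
correlation of their coefficient vectors per sub-band. Total: 29*5*3 +
11*5 = 490 named features per epoch. Note the A5/D5 sub-bands contain only
~31 coefficients, so their null pair correlations have sd ~0.19 — pair
features in slow bands are intrinsically noisy at this epoch length.

## Classification

Random forest (500 trees, unlimited depth, fixed seed) on the 490
features, with two-stage selection fitted per training fold: top-200 by a
200-tree forest's importances, refined to top-100 by one-way ANOVA F.
Schemes:

* **group-kfold** (default, 5 folds): GroupKFold grouped by (subject, lap)
  plus a purged gap — training epochs within 1 position of a held-out
  epoch in the same subject's timeline are excluded.
* **split-sample**: one group-aware shuffle split (30% test).
* **LOSO**: each subject held out once, for four binary tasks (mode,
  pooled difficulty, difficulty within MD, within AD), reported as mean,
  sd, 95% CI, one-sample t vs 0.5 and Cohen's d.
* **cross-mode transfer**: train Easy-vs-Hard on MD epochs, test on AD,
  with an exact binomial test against 0.5.

Class balancing is by seeded random down-sampling of majority classes
within the training fold. Every fold run re-derives the scaler statistics
from the training rows and asserts group disjointness and the purge gap;
a violation raises rather than warns.

Calibration facts established by the tests: with iid features the grouped
pipeline's null accuracy is 0.25 as it should be, and label-permuted runs
on planted data stay at chance. On *temporally ordered* null data the
grouped scheme is conservative (below chance by several points): slow
in-band background fluctuations make epochs within a lap slightly similar,
condition labels are blocked in session time (MD laps precede AD laps),
and excluding the held-out group removes the temporally closest same-class
epochs. This below-chance bias is the familiar behavior of purged grouped
CV under serial dependence; it errs in the safe direction (real skill is
understated, never invented).

## Statistics

One-sample and paired t-tests (one-tailed only for explicitly predicted
directions), Cohen's d, Benjamini-Hochberg FDR within four test families
(whole-brain maps, ROI activation, frequency modulation, connectivity;
Bonferroni available), percentile bootstrap CIs (5,000 resamples; bootstrap
p = `2*min(P(stat*<=0), P(stat*>=0))`), Fisher's p combination (zero
p-values clipped at the machine floor), and subregional consistency metrics
(directional agreement %, mean pairwise r, one-way ANOVA across
subregions). Pairing exploits the replay design: mode contrasts pair
epochs on (subject, lap-within-mode, segment) — the replay lap of the same
drive — and difficulty contrasts pair the alternating Easy/Hard segments
within a lap.

## Problem sizes and reproducibility

The shipped `quick_config` (3 subjects x 3 laps/mode x 20 segments/lap =
360 epochs) is the desk-scale profile used by the test suite and the
acceptance script; it preserves the within-lap 10-vs-10 structure and
scales the study down only in subjects and laps. The full default config
(11 subjects, 5 laps/mode) reproduces the original study's scale.
`run_study` writes a complete report bundle (events, ground truth, ROI
contrasts, ERD/ERS, connectivity matrices, FDR-annotated statistics,
classification reports, feature table, config) with SHA-256 checksums in a
manifest; re-running with the same config reproduces every output
byte-for-byte apart from the manifest timestamp.

## What passing tests show — and what they do not

The synthetic data match the study's *statistical structure* (condition-
scaled narrow-band power, coherent coupling, grouped/ordered epochs,
subject heterogeneity), so green tests demonstrate that every estimator
recovers what was planted and that the validation schemes admit no
leakage. They do not show that the pipeline would reproduce the original
effect *sizes* on real EEG: the generator has no eye/muscle artifacts by
default, no volume-conducted cortical sources (channel effects are planted
directly), no realistic head geometry, and its inter-subject variability
model is a two-parameter caricature. One known mismatch: with our
heterogeneity model, cross-subject (LOSO) decoding of difficulty is near
chance, whereas the original study found difficulty the most transferable
task — real difficulty signatures are evidently more conserved across
people than a global-gain-plus-exponent model implies.
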