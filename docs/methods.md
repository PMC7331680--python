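# Methods

This note documents the models, conventions and numerical choices behind
`n400kit`, and what the synthetic-data validation does and does not show.

## Data model and conventions

Voltages are microvolts throughout. An epoch's time axis is a uniform grid
at the sampling rate with the target-onset sample at exactly 0 ms; the
window is half-open on the right. Because 100 ms is not an integer number
of samples at 512 Hz, "the epoch starts at −100 ms" and "onset is at
0 ms" cannot both hold exactly on one uniform grid; we fix onset at 0 and
take the first sample as the earliest grid point at or after −100 ms.
The default [−100, 1000) ms window therefore has 563 samples at 512 Hz
(51 pre-onset + 512 post-onset), and exactly −100 ms appears whenever
0.1 × srate is an integer. Every word pair contributes exactly two trials,
one per condition — this pairing is a validated container invariant
because both the cross-validation scheme and the permutation scheme
depend on it.

The bundled montage (`data/montage64.csv`) is an idealized 64-channel
10-20 layout plus two mastoids, all positions unit-normalised; any
`name,x,y,z` CSV can be substituted. Neighbourhoods are k-nearest by chord
distance with lexicographic tie-breaking, so they are deterministic.

The artifact-rejection threshold is ±200 µV (a 200 mV scalp deflection is
physically implausible); it is configurable. Rejection is a non-destructive
mask: decoding deliberately ignores it (all epochs are kept for the
multivariate analyses), while the univariate branch and the SME honour it,
typically with rejection scoped to the 9 ROI channels to preserve data.

## Synthetic EEG generator

The generator emulates the *structure* of a single-session, two-condition
target-word experiment, not any particular dataset:

* **Effect**: a separable spatio-temporal Gaussian added to incongruent
  trials only — temporal Gaussian (default peak 400 ms, SD 80 ms) times a
  spatial Gaussian over electrode positions (default centre Cz, spread
  0.6 sphere units), scaled by an amplitude in µV (default −4 µV,
  negative = incongruent more negative). Injection is additive and
  linear; amplitude 0 makes the two conditions exchangeable by
  construction, which is the basis of every null-calibration study.
* **Noise**: spatially correlated 1/f ("pink", default SD 8 µV) plus
  white noise (default SD 4 µV), mixed through the Cholesky factor of a
  Gaussian spatial correlation (scale 0.5 chord units), identical in law
  for both conditions. The defaults give a single-trial SD of ~9 µV:
  a few-µV effect is invisible in single trials but clear in a 94-trial
  average, which is the qualitative regime of real child EEG. No published
  SNR was available to calibrate against, so these are order-of-magnitude
  choices, stated once and not tuned.
* **Heterogeneity**: cohorts draw each subject's latency and topography
  centre around the base effect (Gaussian jitters), and a responder
  fraction sets how many subjects get a non-zero amplitude
  (`round(fraction × n)`, assignment random but seed-deterministic).
  Ground truth (realized amplitude, latency, centre, per-channel weights)
  is returned with every subject for recovery tests.

What passing tests on this generator shows: the estimators point at the
right place/time when an effect is present, and the inference machinery
holds its nominal error rates when it is absent, under realistic
spatio-temporal noise correlation. What it does not show: robustness to
ocular/muscle artifacts (not simulated; the ICA step used on real data is
out of scope), forward-model realism, or performance at any particular
real-world SNR.

`simulate_continuous` places the simulated epochs on a zero background
with inter-trial gaps and event markers, so that epoching the recording
reproduces the direct simulation bit-for-bit under a shared seed — it
exists to exercise the epoching path, not to model continuous EEG.

## Decoding

Classifier: linear soft-margin SVM, C = 1, on raw flattened
channels × samples voltages, no scaling — the conventional default of the
standard toolboxes. Cross-validation is leave-one-target-out: one fold per
word pair, training on all other pairs' trials. Fold accuracies are
{0, ½, 1}; the subject's score is their mean.

Because the permutation studies need ~10⁵–10⁶ SVM fits on tiny training
sets that share one linear-kernel Gram matrix, the engine is a
numba-compiled SMO solver for the C-SVC dual (second-order working-set
selection, libsvm's stopping rule, tol = 10⁻³) operating on sub-blocks of
a precomputed Gram. It is the same optimisation problem that
`sklearn.svm.SVC` solves; the test suite asserts exact fold-accuracy
agreement and decision-value agreement within the stopping tolerance.
`ClassifierSpec(backend="sklearn")` switches to scikit-learn for
independent cross-checks.

**Permutation null.** A permutation flips, independently per word pair
with p = ½, the two condition labels within the pair, then the identical
LOTO procedure is re-run. Per-permutation RNG streams are derived from
(seed, permutation index), so results are reproducible and independent of
evaluation order. The significance flag is the empirical rule "observed
accuracy higher than 95% of the null accuracies", implemented exactly as
`#{null < observed} ≥ ⌈(1−α)(n_perm+1)⌉`: at 1000 permutations and
α = 0.05 this is "more than 950 of 1000 below", and the +1 keeps the test
exact (level ≤ α) at the reduced permutation counts used in desk-scale
studies — with the naive `≥ 0.95 n_perm` count the realized level at 40
permutations is ~0.07 by rank discreteness. Reported alongside: the
add-one rank p-value (bounded below by 1/(n_perm+1)), the upper-tail
p-value of a normal fit to the null (the route to finer p-values than the
rank bound), and the effect size (observed − null mean)/null SD with the
n−1 denominator.

**Pseudotrials.** Within each of `n_sets` (default 100) random
partitions, trials of each condition are averaged in groups of k
(default 12; leftovers dropped), pseudotrial pairs are formed by
construction order, and leave-one-pseudotrial-pair-out accuracies are
averaged over sets. Its permutation null flips real-trial labels within
word pairs and re-runs the identical pseudotrial analysis with the same
partitions, so the null preserves both the pairing and the averaging
structure.

## Localized decoding

Time-resolved: features are all channels × 11 samples (centre ± 5);
centres without a full window are skipped, so an epoch of n samples has
n − 10 valid centres. All windowed Gram matrices are differences of one
cumulative per-sample Gram tensor, computed once per subject.

TFCE: `TFCE(p) = Σ_h e(h)^E h^H Δh` with E = 0.5, H = 2 (the method's
standard defaults), integrated to each point's own height with a partial
top step (midpoint heights, step = max/100 unless given). The input is
accuracy − 0.5, one-sided: negative excursions score zero, matching the
directional hypothesis. Convergence: the boxcar closed form
`√L·h³/3` is matched within 1% at fine steps, and the maximum score
changes < 1% when the default step is halved.

The max-statistic correction takes, per permutation, the maximum TFCE over
the analysis window — post-onset centres only, the baseline is excluded —
and flags observed timepoints by the same exact finite-permutation rule as
the decoding flag. Family-wise error on null simulations is ≤ nominal
(checked on 100 reduced null subjects).

Searchlight: per electrode, features are its 5-electrode neighbourhood
(computed within the recorded channel set) × 11 samples. The maps are
descriptive by design — no significance machinery is attached — and are
summarised as per-channel means over four half-open 200-ms windows
spanning 200–1000 ms.

`AccuracyMap.peak_time` estimates the latency of maximal decodability as
the centroid of the (3-point-smoothed) accuracy maximum: with a
saturating curve, plain argmax returns the plateau's first sample and
biases the estimate early. `peak_channel` ranks channels by mean accuracy
over a time window, which is markedly more stable than the single-cell
argmax of the map.

## Univariate analysis

ROI: Cz, FC1, FCz, FC2, C1, C2, CP1, CPz, CP2; signal is channel-mean
then trial-mean. Pointwise tests are classic pooled-variance two-sample
t-tests (two-tailed) from 150 ms on; degenerate-variance timepoints get
p = 1 with a warning.

The cluster threshold simulates null datasets of per-trial AR(1) Gaussian
series whose lag-1 coefficient matches the observed ROI difference
waveform and whose trial counts match the data — trial-level simulation is
used (rather than waveform-level) so the simulated t-tests have the same
degrees-of-freedom structure as the observed ones. Per simulated dataset
the longest run of p < 0.05 is recorded; the threshold is the smallest
length L such that at most 5% of null longest-runs reach L, so an observed
cluster of length ≥ L is longer than 95% of the null series' longest
clusters. At φ = 0 the threshold agrees with a 10× brute-force simulation
within one sample, and it is non-decreasing in φ.

N400 area: trapezoidal integral of (congruent − incongruent) over
300–800 ms in single-sample steps, positive when incongruent is more
negative; linear and additive over subwindows by construction.

Group-level use is the same machinery applied to per-subject difference
waveforms (paired t ≡ one-sample t on differences).

## SME and reporting

The SME of a channel is the SD, over bootstrap resamples (default 10,000;
resampling accepted trials with replacement at their original counts
within each condition), of the 300–800 ms mean amplitude of the
resampled difference ERP. Epochs are baseline-corrected upstream; no
second baseline subtraction is applied. It equals the plug-in standard
error √(s²c/nc + s²i/ni) for i.i.d. scores (asserted within 5%), is
scale-equivariant, and is invariant to condition-constant shifts.
Resampling draws are shared across channels, which changes nothing in
distribution but keeps the per-channel map cheap.

`run_pipeline` applies ROI-scoped rejection (if no mask is set), the three
analyses and the SME to each subject with seeds derived from one root
seed, and emits the per-subject Yes/No table with a totals row
("13/20"-style). Flags are taken verbatim from the component analyses —
no re-thresholding. Reduced defaults (100 permutations, 1000 bootstraps)
keep a 20-subject cohort to minutes on one CPU; full-scale counts
(1000/10,000) are plain parameters.

## Validation problem sizes

Chosen so the whole suite runs in minutes on one CPU; statistical
minimums (subject counts, seed counts) are kept at full size and only
per-subject dimensions are reduced.

* Decoding null calibration: 200 null subjects, 20 pairs × 8 channels ×
  50 samples, 100 permutations each; false-positive rate ≤ 0.05 + 2
  binomial SEs. Chance centring: 100 null subjects, mean accuracy within
  2 SEs of 50%. (Note: leave-one-out accuracy on null data is mildly
  pessimistically biased — trial dependence across folds — so the mean
  sits slightly below 50%; both checks account for this only through
  their stated tolerances.)
* TFCE family-wise error: 100 null subjects, 10 pairs × 8 channels ×
  40 samples, 40 permutations.
* Parameter recovery runs in a strong-effect regime (−16 µV; width 30 ms
  for latency recovery, spatial spread 0.35 for topography recovery;
  baseline-corrected epochs): at the generator's default −4 µV the
  accuracy curve's peak location is dominated by 1/f noise at desk scale,
  so recovery there would test luck, not machinery. Latency: median
  |error| ≤ 50 ms over 20 seeds (32 pairs, 64 Hz). Topography: peak
  channel within the injected centre's 5-electrode neighbourhood in the
  majority of 20 seeds (20 pairs, 16 channels, 32 Hz).
* Sequence constraints: 100 seeds at 94 pairs (run lengths, run-length
  frequency monotonicity, half-balance, question-trial gaps in [4, 10]).
* Oracles: TFCE boxcar vs closed form; cluster threshold vs 10×
  brute-force; SME vs plug-in standard error; SMO vs sklearn SVC.

## Known limitations

* No ocular/muscle artifact model and no ICA; on real data, clean the
  continuous recording externally before `preprocess`.
* The bias metric for sequence optimisation (frequency-weighted mean
  squared deviation of conditional congruent-rates from ½) is one
  reasonable choice among several; it is zero exactly for perfectly
  balanced conditionals.
* The power calculation assumes a two-sample t on 94 + 94 trials; the
  one-tailed form is the default because the decoding hypothesis is
  directional. Tails are a parameter.
* Spherical-spline interpolation uses Perrin-style splines (order m = 4,
  regularisation 10⁻⁵, 50 Legendre terms); channels are repaired on the
  referenced continuous data and the pipeline re-runs from the filtering
  stage.
* The 0.1–40 Hz zero-phase Butterworth (4th order, forward–backward) has
  second-scale transients at the highpass edge; filter continuous data,
  not epochs, and keep recordings padded by a few seconds of real signal
  at both ends.
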