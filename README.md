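# n400kit

Single-subject EEG decoding and ERP statistics for lexical-semantic
(N400-type) effects.

## The problem

The N400 is a negative-going ERP deflection, typically centro-parietal and
300–800 ms after word onset, that grows when a word violates its semantic
context. Group averages show it robustly, but clinical and developmental
applications need a verdict for **one person**: does *this* child's brain
discriminate a congruent from an incongruent sentence ending? At the
single-subject level the effect's latency and topography vary so much that
a fixed window/electrode analysis throws away exactly the variability that
matters.

`n400kit` implements the full analysis path for a two-condition
(congruent/incongruent) target-word experiment in which every target word
appears once per condition (94 word pairs, 188 trials per session, 64-channel
10-20 EEG at 512 Hz, epochs −100…+1000 ms around target onset):

* **Unconstrained multivariate decoding.** A linear soft-margin SVM
  (C = 1) on raw voltages from all scalp channels and all time points,
  under leave-one-target-out (LOTO) cross-validation: the two trials
  sharing a target word form the test set, so the classifier never trains
  on the test word. Accuracy is the mean over the 94 folds; chance is 50%.
* **Pairing-preserving permutation inference.** Each permutation swaps
  (or not, p = ½) the two condition labels within every word pair and
  re-runs the identical LOTO procedure. The observed accuracy is
  significant when it exceeds 95% of the null accuracies (exact
  finite-permutation rule); a rank p-value
  `p = (1 + #{null ≥ acc}) / (1 + n_perm)`, a normal-fit tail p-value, and
  the effect size `(acc − mean(null)) / sd(null)` are reported.
* **Time-resolved decoding with TFCE.** The same decoder on an 11-sample
  sliding window (all channels), with threshold-free cluster enhancement
  (E = 0.5, H = 2) of the chance-centred accuracy series and max-statistic
  permutation correction over the post-onset window.
* **Time × space searchlight.** Decoding per 5-electrode neighbourhood ×
  11-sample window, summarised as four 200-ms topographic maps
  (200–1000 ms); descriptive, no significance test.
* **Univariate N400 analysis.** 9-channel centro-parietal ROI (Cz and its
  surround), pointwise two-sample t-tests from 150 ms, a minimum-cluster-
  length threshold calibrated on AR(1) null series matched to the observed
  difference waveform's lag-1 autocorrelation, and the trapezoidal area of
  the difference waveform over 300–800 ms.
* **Data quality (SME).** Bootstrap standardised measurement error of the
  300–800 ms difference-ERP amplitude, per channel, plus Spearman
  correlations against the decoding and ERP outcomes.
* **Design utilities and synthetic EEG.** Bias-minimised trial sequences
  under run-length constraints, the noncentral-t power calculation
  (94 trials/condition, d = 0.5, one-tailed → 96% power), and a synthetic
  generator (spatio-temporal Gaussian effect + spatially correlated
  1/f + white noise, per-subject latency/topography jitter) used for all
  validation.

The heavy lifting — hundreds of thousands of tiny SVM fits for the
permutation studies — runs on a numba-compiled SMO solver for the C-SVC
dual over precomputed Gram matrices; it solves the same objective with the
same stopping rule as libsvm and is asserted against `sklearn.svm.SVC` in
the test suite.

## Worked example

`examples/simulate_and_decode.py` simulates one 188-trial session with a
−4 µV effect peaking 400 ms after onset at Cz, then runs the decoding
analysis with 200 permutations:

```
trials: 188  folds: 94
decoding accuracy : 66.0%  (chance 50%)
null mean / sd    : 50.3% / 4.1%
p (rank)          : 0.0050
p (normal fit)    : 7.78e-05
effect size       : 3.78  (null SDs above chance)
significant       : True
```

The accuracy is the mean over 94 leave-one-target-out folds. The rank
p-value is bounded below by 1/(n_perm+1); the normal fit to the null is
how far smaller p-values arise. The effect size says the observed accuracy
sits 3.78 null standard deviations above chance.

Other examples: `design_sequence.py` (sequence constraints + power),
`timecourse_and_searchlight.py` (when and where the effect is decodable),
`univariate_n400.py` (ROI cluster statistics and N400 area), and
`cohort_report.py` (20 heterogeneous subjects → per-subject Yes/No summary
table with a totals row).

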