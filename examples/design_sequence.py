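"""Design utilities: a bias-minimised trial sequence and the power calculation.

Generates a 188-trial presentation order (94 congruent / 94 incongruent)
under the run-length constraints, balances each sentence frame across the
two session halves, and reports the sequential bias scores.  Also prints
the power of a two-sample t-test at 94 trials per condition.
"""

import itertools

import numpy as np

from n400kit import PowerSpec, generate_sequence, power_two_sample_t

seq = generate_sequence(94, n_candidates=1000, max_run=4, seed=0)

runs = [len(list(g)) for _, g in itertools.groupby(seq.labels)]
freq = np.bincount(runs, minlength=5)[1:5]
print(f"labels: {len(seq.labels)} "
      f"({np.sum(seq.labels == 'congruent')} congruent)")
print(f"longest same-condition run: {max(runs)}")
print(f"run-length counts (1..4): {list(freq)}")
print("bias scores (order 1/2/3): "
      + " / ".join(f"{seq.bias_scores[o]:.4f}" for o in (1, 2, 3)))
gaps = np.diff(np.concatenate(([0], seq.question_trials)))
print(f"question trials: {len(seq.question_trials)} (gaps {gaps.min()}-{gaps.max()})")

power = power_two_sample_t(PowerSpec(n_per_group=94, d=0.5, alpha=0.05, tails="one"))
print(f"power at n=94/condition, d=0.5, one-tailed alpha=0.05: {100 * power:.1f}%")
# A bias score of 0 would mean each recent-history pattern is followed by
# the two conditions equally often; small values indicate an unpredictable
# sequence.
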