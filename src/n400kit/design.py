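"""Experimental-design utilities.

Covers three jobs:

* scoring sequential bias in a two-condition trial sequence (how
  predictable the next condition is from the preceding 1, 2 or 3 trials);
* generating bias-minimised pseudo-random sequences under run-length
  constraints, with sentence frames balanced across session halves and a
  jittered question-trial schedule;
* the a-priori power calculation for a two-sample t-test, used to justify
  the number of trials per condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .epochs import CONDITIONS
from .errors import ValidationError

__all__ = [
    "TrialSequence",
    "PowerSpec",
    "sequence_bias",
    "generate_sequence",
    "power_two_sample_t",
]


@dataclass
class TrialSequence:
    """A presentation order for a two-condition session.

    ``labels[i]`` is the condition of trial i, ``pair_order[i]`` the
    target-pair id presented at trial i (each pair appears once per
    condition, once per session half).  ``bias_scores`` maps history order
    (1, 2, 3) to the sequence's bias score.  ``question_trials`` are the
    indices of trials followed by a comprehension probe.
    """

    labels: np.ndarray
    pair_order: np.ndarray
    bias_scores: dict
    question_trials: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U11")
        self.pair_order = np.asarray(self.pair_order, dtype=np.int64)
        self.question_trials = np.asarray(self.question_trials, dtype=np.int64)


@dataclass(frozen=True)
class PowerSpec:
    n_per_group: int
    d: float
    alpha: float = 0.05
    tails: str = "one"

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.tails not in ("one", "two"):
            raise ValidationError("tails must be 'one' or 'two'")


def sequence_bias(labels, order: int) -> float:
    """Sequential predictability of a two-condition label sequence.

    For every history of ``order`` preceding labels that occurs in the
    sequence, compute the conditional relative frequency of "congruent"
    among its successors; the bias is the frequency-weighted mean of the
    squared deviations of those conditionals from 0.5.  It is zero exactly
    when every observed history is followed by each condition equally
    often, and positive otherwise.
    """
    labels = [str(l) for l in labels]
    if order < 1:
        raise ValidationError("order must be >= 1")
    if len(labels) <= order:
        raise ValidationError(f"sequence of length {len(labels)} too short for order {order}")
    counts: dict = {}
    for i in range(order, len(labels)):
        hist = tuple(labels[i - order : i])
        n, c = counts.get(hist, (0, 0))
        counts[hist] = (n + 1, c + (labels[i] == "congruent"))
    total = sum(n for n, _ in counts.values())
    return float(
        sum(n * (c / n - 0.5) ** 2 for n, c in counts.values()) / total
    )


def _sample_balanced_runs(n_per: int, max_run: int, rng: np.random.Generator) -> np.ndarray:
    """One balanced random 0/1 sequence with no run longer than max_run.

    Sequential sampling: at each position choose uniformly among the
    conditions that remain feasible (counts can still be completed without
    a forbidden run).  Always terminates in one pass.
    """
    remaining = [n_per, n_per]
    seq = np.empty(2 * n_per, dtype=np.int8)
    last, run = -1, 0
    for i in range(2 * n_per):
        feasible = []
        for lab in (0, 1):
            if remaining[lab] == 0:
                continue
            r = run + 1 if lab == last else 1
            if r > max_run:
                continue
            a = remaining[lab] - 1          # same-condition trials still to place
            b = remaining[1 - lab]          # other-condition trials
            if a > (max_run - r) + b * max_run:
                continue
            if b > (a + 1) * max_run:
                continue
            feasible.append(lab)
        lab = feasible[int(rng.integers(len(feasible)))] if len(feasible) > 1 else feasible[0]
        seq[i] = lab
        remaining[lab] -= 1
        run = run + 1 if lab == last else 1
        last = lab
    return seq


def _run_lengths(seq: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(np.diff(seq) != 0)
    bounds = np.concatenate(([-1], change, [len(seq) - 1]))
    return np.diff(bounds)


def _run_freqs_non_increasing(seq: np.ndarray, max_run: int) -> bool:
    lengths = _run_lengths(seq)
    freq = np.bincount(lengths, minlength=max_run + 1)[1 : max_run + 1]
    return bool(np.all(np.diff(freq) <= 0))


def candidate_labels(
    n_pairs: int,
    n_candidates: int = 1000,
    max_run: int = 4,
    seed: int = 0,
    max_attempts_per_candidate: int = 200,
) -> list:
    """The candidate label sequences considered by :func:`generate_sequence`.

    Each candidate is balanced, has no same-condition run longer than
    ``max_run``, and has run-length frequencies non-increasing in run
    length.  Deterministic given ``seed``.
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    if n_candidates < 1:
        raise ValidationError("n_candidates must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_candidates):
        for _attempt in range(max_attempts_per_candidate):
            cand = _sample_balanced_runs(n_pairs, max_run, rng)
            if _run_freqs_non_increasing(cand, max_run):
                break
        else:
            raise RuntimeError(
                "could not draw a candidate satisfying the run-length frequency "
                "constraint; increase max_attempts_per_candidate"
            )
        out.append(np.where(cand == 0, "congruent", "incongruent"))
    return out


def generate_sequence(
    n_pairs: int,
    n_candidates: int = 1000,
    max_run: int = 4,
    seed: int = 0,
    question_period: int = 7,
    question_jitter: int = 3,
    max_attempts_per_candidate: int = 200,
) -> TrialSequence:
    """Generate a bias-minimised pseudo-random trial sequence.

    ``n_candidates`` random sequences are drawn, each constrained to have
    (a) equal condition counts, (b) no same-condition run longer than
    ``max_run``, and (c) run-length frequencies non-increasing in run
    length.  The candidate minimising the sum of the order-1, -2 and -3
    bias scores is kept.  Pair ids are then assigned so each pair occurs
    once in each half of the session, and question trials are placed
    approximately every ``question_period`` trials with a uniform jitter of
    +/- ``question_jitter``.  Deterministic given ``seed``.
    """
    n_trials = 2 * n_pairs
    candidates = candidate_labels(
        n_pairs, n_candidates, max_run, seed, max_attempts_per_candidate
    )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))

    best, best_score = None, np.inf
    for labels in candidates:
        orders = [o for o in (1, 2, 3) if n_trials > o]
        score = sum(sequence_bias(labels, o) for o in orders)
        if score < best_score:
            best, best_score = labels, score

    labels = best
    scores = {o: (sequence_bias(labels, o) if n_trials > o else 0.0) for o in (1, 2, 3)}

    # frame balancing: each pair contributes one trial per half.  The
    # first-half congruent slots receive pairs whose incongruent member
    # then fills a second-half slot, and vice versa; assignment is a
    # random permutation of pairs.
    half = n_pairs  # trials per half
    first_c = np.flatnonzero(labels[:half] == "congruent")
    pairs = rng.permutation(n_pairs)
    c_first_pairs = pairs[: len(first_c)]          # congruent in half 1
    i_first_pairs = pairs[len(first_c) :]          # incongruent in half 1
    pair_order = np.empty(n_trials, dtype=np.int64)
    queues = {
        ("congruent", 0): list(c_first_pairs),
        ("incongruent", 0): list(i_first_pairs),
        ("congruent", 1): list(i_first_pairs),
        ("incongruent", 1): list(c_first_pairs),
    }
    for i in range(n_trials):
        pair_order[i] = queues[(str(labels[i]), int(i >= half))].pop(0)

    # question trials approximately every `period` trials, jitter +/- j
    q = []
    pos = 0
    while True:
        pos += question_period + int(rng.integers(-question_jitter, question_jitter + 1))
        if pos >= n_trials:
            break
        q.append(pos)
    return TrialSequence(
        labels=labels,
        pair_order=pair_order,
        bias_scores=scores,
        question_trials=np.asarray(q, dtype=np.int64),
    )


def power_two_sample_t(spec: PowerSpec) -> float:
    """Exact power of a two-sample t-test via the noncentral t distribution.

    The noncentrality parameter is ``d * sqrt(n / 2)`` with
    ``df = 2n - 2``.  For ``d = 0`` the power equals alpha.
    """
    df = 2 * spec.n_per_group - 2
    nc = spec.d * np.sqrt(spec.n_per_group / 2.0)
    if spec.tails == "one":
        crit = stats.t.ppf(1.0 - spec.alpha, df)
        return float(stats.nct.sf(crit, df, nc))
    crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))
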