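"""Batched linear SVM engine for leave-one-target-out decoding.

Decoding with a permutation null re-fits the same soft-margin SVM hundreds
of thousands of times on tiny training sets that differ only in their
labels (and by the two held-out trials).  The linear-kernel Gram matrix is
label-independent, so it is computed once per feature window and every
fit/prediction works on sub-blocks of it.  The dual problem is solved by a
compiled SMO (sequential minimal optimisation) with maximal-violating-pair
working-set selection and the same stopping rule as libsvm (gap < 1e-3) —
i.e. the standard C-SVC objective, just without per-fit overhead.
Agreement with :class:`sklearn.svm.SVC` is asserted in the test suite.

Trials must be ordered so that pair ``p`` occupies rows ``2p`` and
``2p + 1`` of the Gram matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["gram", "loto_folds", "loto_batch", "smo_solve"]


def gram(X: np.ndarray) -> np.ndarray:
    """Linear-kernel Gram matrix of flattened trial features."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    return X @ X.T


@njit(cache=True)
def smo_solve(K, y, C, tol, max_iter):  # pragma: no cover - compiled
    """Solve the C-SVC dual on kernel matrix K with labels y in {-1, +1}.

    Returns (alpha, b) with decision f(x) = sum_j alpha_j y_j K(x_j, x) + b.
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    f = np.zeros(n)  # sum_j alpha_j y_j K_ij
    for _ in range(max_iter):
        # g_t = y_t - f_t; i maximises g over I_up, then j is chosen by
        # libsvm's second-order rule (largest decrease of the dual
        # objective among violating candidates in I_low)
        m_val = -1e300
        M_val = 1e300
        i = -1
        for t in range(n):
            g = y[t] - f[t]
            in_up = (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0)
            in_low = (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C)
            if in_up and g > m_val:
                m_val = g
                i = t
            if in_low and g < M_val:
                M_val = g
        if m_val - M_val <= tol:
            break
        j = -1
        best_obj = 0.0
        for t in range(n):
            in_low = (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C)
            if not in_low:
                continue
            g = y[t] - f[t]
            diff = m_val - g
            if diff <= 0.0:
                continue
            a = K[i, i] + K[t, t] - 2.0 * K[i, t]
            if a <= 1e-12:
                a = 1e-12
            obj = -(diff * diff) / a
            if obj < best_obj:
                best_obj = obj
                j = t
        if j < 0:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta <= 1e-12:
            eta = 1e-12
        # step along the feasible direction d_alpha_i = +y_i*delta,
        # d_alpha_j = -y_j*delta (keeps sum y*alpha = 0); delta > 0 here
        delta = (m_val - (y[j] - f[j])) / eta
        if y[i] > 0:
            delta = min(delta, C - alpha[i])
        else:
            delta = min(delta, alpha[i])
        if y[j] > 0:
            delta = min(delta, alpha[j])
        else:
            delta = min(delta, C - alpha[j])
        alpha[i] += y[i] * delta
        alpha[j] -= y[j] * delta
        for t in range(n):
            f[t] += delta * (K[t, i] - K[t, j])
    b = 0.5 * (m_val + M_val)
    return alpha, b


@njit(cache=True)
def loto_folds(K, y, C, tol, max_iter):  # pragma: no cover - compiled
    """Fold accuracies of leave-one-pair-out CV; pair p = rows (2p, 2p+1)."""
    n = K.shape[0]
    n_pairs = n // 2
    folds = np.empty(n_pairs)
    train_idx = np.empty(n - 2, dtype=np.int64)
    Ktr = np.empty((n - 2, n - 2))
    ytr = np.empty(n - 2)
    for p in range(n_pairs):
        k = 0
        for t in range(n):
            if t != 2 * p and t != 2 * p + 1:
                train_idx[k] = t
                k += 1
        for a_ in range(n - 2):
            ytr[a_] = y[train_idx[a_]]
            for b_ in range(n - 2):
                Ktr[a_, b_] = K[train_idx[a_], train_idx[b_]]
        alpha, b = smo_solve(Ktr, ytr, C, tol, max_iter)
        acc = 0.0
        for t in (2 * p, 2 * p + 1):
            s = b
            for jj in range(n - 2):
                if alpha[jj] != 0.0:
                    s += alpha[jj] * ytr[jj] * K[t, train_idx[jj]]
            pred = 1.0 if s > 0.0 else -1.0
            if pred == y[t]:
                acc += 1.0
        folds[p] = acc / 2.0
    return folds


@njit(cache=True)
def loto_batch(K, y_base, flips, C, tol, max_iter):  # pragma: no cover
    """Fold accuracies for many label-flip patterns on one Gram matrix.

    ``flips`` is (n_runs, n_pairs) uint8; flipping a pair negates the
    labels of its two trials (swapping conditions within the pair).
    Returns (n_runs, n_pairs) fold accuracies.
    """
    n_runs = flips.shape[0]
    n = K.shape[0]
    n_pairs = n // 2
    out = np.empty((n_runs, n_pairs))
    y = np.empty(n)
    for r in range(n_runs):
        for p in range(n_pairs):
            s = -1.0 if flips[r, p] else 1.0
            y[2 * p] = y_base[2 * p] * s
            y[2 * p + 1] = y_base[2 * p + 1] * s
        out[r] = loto_folds(K, y, C, tol, max_iter)
    return out
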