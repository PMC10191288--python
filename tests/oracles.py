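"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms they check: the logistic oracle is
an iterated coordinate grid search over the likelihood surface, the FDR
oracle enumerates every rank k of the step-up definition, and the pruning
oracle verifies the defining property of the greedy solution by subset
enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np


def loglik(X, y, beta):
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def grid_search_logistic(X, y, span=5.0, n_grid=21, n_rounds=40):
    """Maximize the logistic likelihood by iterated per-coordinate grid scan."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    k = X.shape[1]
    beta = np.zeros(k)
    width = span
    for _ in range(n_rounds):
        for j in range(k):
            grid = beta[j] + np.linspace(-width, width, n_grid)
            lls = []
            for val in grid:
                b = beta.copy()
                b[j] = val
                lls.append(loglik(X, y, b))
            beta[j] = grid[int(np.argmax(lls))]
        width *= 0.5
        if width < 1e-7:
            break
    return beta


def bh_enumerate(pvalues, q):
    """Step-up rejection by checking every rank k explicitly."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if ranked[k - 1] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    # adjusted values straight from the definition min_{j>=i} m p(j) / j
    adjusted = np.empty(m)
    for i in range(m):
        adjusted[order[i]] = min(
            min(m * ranked[j] / (j + 1) for j in range(i, m)), 1.0
        )
    return reject, adjusted


def prune_oracle(pvals, r2, r2_thresh):
    """The unique subset satisfying the greedy-selection defining property.

    Candidates are indices ordered by ascending p (ties already broken).
    A subset S is THE greedy solution iff for every candidate c (in priority
    order): c in S exactly when c is r^2-compatible with every
    higher-priority member of S. Verified by enumerating all subsets.
    """
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    solutions = []
    for bits in itertools.product([0, 1], repeat=m):
        S = {i for i in range(m) if bits[i]}
        ok = True
        for c in order:
            prior = [s for s in S if order.index(s) < order.index(c)]
            compatible = all(r2[c][s] < r2_thresh for s in prior)
            if (c in S) != compatible:
                ok = False
                break
        if ok:
            solutions.append(S)
    assert len(solutions) == 1, "greedy defining property must have a unique solution"
    return solutions[0]
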