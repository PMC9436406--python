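"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations from the definitions (full sign
enumeration, literal step-up, literal rank arithmetic) and share no code
with the package implementation they check.
"""

from itertools import product

import numpy as np


def midranks(values):
    """Midranks computed literally: rank = mean position among sorted values."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        # positions less+1 .. less+equal, averaged
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def wilcoxon_exact_bruteforce(x, y):
    """Two-sided exact signed-rank p by literal enumeration of sign vectors."""
    d = [a - b for a, b in zip(x, y)]
    d = [v for v in d if v != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = midranks([abs(v) for v in d])
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    w_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=n)
    ]
    total = len(w_all)
    p_le = sum(1 for w in w_all if w <= w_obs + 1e-9) / total
    p_ge = sum(1 for w in w_all if w >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def bh_stepup_direct(p):
    """Literal BH step-up: p_(i) -> min_{j>=i} m p_(j) / j, in input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [0.0] * m
    for i in range(m):
        adj_sorted[i] = min(
            min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0
        )
    out = [0.0] * m
    for i, idx in enumerate(order):
        out[idx] = adj_sorted[i]
    return out


def friedman_chi2_direct(matrix):
    """Friedman chi-square from literal rank arithmetic (with tie correction)."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    ranks = np.array([midranks(row) for row in matrix])
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3 * n * (k + 1)
    ties = 0.0
    for row in matrix:
        _, c = np.unique(row, return_counts=True)
        ties += float((c**3 - c).sum())
    corr = 1.0 - ties / (n * k * (k * k - 1))
    return chi2 / corr if corr > 0 else 0.0


def friedman_permutation_p(matrix, n_perm, seed):
    """Permutation p-value: re-randomise treatment labels within each block."""
    rng = np.random.default_rng(seed)
    matrix = np.asarray(matrix, dtype=float)
    obs = friedman_chi2_direct(matrix)
    count = 0
    perm = matrix.copy()
    for _ in range(n_perm):
        for row in perm:
            rng.shuffle(row)
        if friedman_chi2_direct(perm) >= obs - 1e-12:
            count += 1
    return count / n_perm
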