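"""Independent oracles used by the test suite.

These deliberately re-derive model quantities by the most naive route
available (per-individual double loops, exact enumeration) and never
call the implementation they check.
"""

import numpy as np


def naive_payoffs_diluted(adj, types, B, C, D, C_link):
    """Literal per-individual, per-neighbor evaluation of the diluted game."""
    n = adj.shape[0]
    deg = [int(sum(adj[i])) for i in range(n)]
    u = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j == i or not adj[i, j] or not types[j]:
                continue
            u[i] += B / deg[j]
            if types[i]:
                u[i] += D / (deg[i] * deg[j])
        u[i] -= types[i] * C + deg[i] * C_link
    return u


def naive_payoffs_per_link(adj, types, B, C, D_pl, C_link):
    """Literal evaluation of the per-link (prisoner's dilemma) game."""
    n = adj.shape[0]
    deg = [int(sum(adj[i])) for i in range(n)]
    u = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j == i or not adj[i, j]:
                continue
            u[i] += types[j] * B + types[i] * types[j] * D_pl
        u[i] -= types[i] * deg[i] * C + deg[i] * C_link
    return u


def newborn_set_size_pmf(d_p, n_other, p_n, p_r):
    """Exact pmf of the newborn's connection count: 1 (the parent) plus
    Binomial(d_p, p_n) plus Binomial(n_other, p_r), by convolution."""
    from math import comb

    def binom_pmf(m, p):
        return np.array([comb(m, k) * p**k * (1 - p) ** (m - k) for k in range(m + 1)])

    pmf = np.convolve(binom_pmf(d_p, p_n), binom_pmf(n_other, p_r))
    sizes = np.arange(pmf.size) + 1
    return sizes, pmf
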