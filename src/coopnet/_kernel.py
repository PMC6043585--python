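"""Numba-compiled inner loop of the death–birth simulation.

Everything here operates in place on preallocated numpy arrays and draws
from a single ``numpy.random.Generator``. Numba executes ``Generator``
methods with the same bit stream as pure numpy, so the public wrappers in
:mod:`coopnet.network`, :mod:`coopnet.game` and :mod:`coopnet.evolution`
call the very same compiled functions that the long-run driver uses —
there is one implementation of every stochastic event, and trajectories
are a pure function of (seed, config).

Random-draw order within one death–birth step (fixed contract):

1. one ``integers`` draw for the individual selected to die;
2. one draw for the parent: ``integers`` under neutral dynamics, else a
   single ``random`` inverted through the cumulative fitness;
3. if ``mu > 0``, one ``random`` draw for the allele mutation;
4. per evolving linking trait (p_n first, then p_r), one ``random`` draw
   for whether it mutates and, only if it does, one ``normal`` draw;
5. one ``random`` draw per living candidate (in index order, skipping the
   newborn's slot and the parent) for the wiring of the newborn.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "link_mask",
    "remove_individual",
    "compute_payoffs",
    "fitness_from_payoffs",
    "sample_parent",
    "mutate_type_draw",
    "mutate_trait_draw",
    "run_steps",
]


@njit(cache=True)
def link_mask(adj, parent, p_n, p_r, skip, rng, out):
    """Draw the newborn's connection set into ``out`` (uint8 mask).

    The parent is linked with certainty (no draw); each neighbor of the
    parent independently with probability ``p_n``; every other living
    individual with probability ``p_r``. ``skip`` is the newborn's own
    slot (-1 when the newborn is not represented in ``adj``).
    """
    n = adj.shape[0]
    for j in range(n):
        if j == skip:
            out[j] = 0
            continue
        if j == parent:
            out[j] = 1
        elif adj[parent, j]:
            out[j] = 1 if rng.random() < p_n else 0
        else:
            out[j] = 1 if rng.random() < p_r else 0
    return out


@njit(cache=True)
def remove_individual(adj, deg, dead):
    """Delete ``dead``'s edges in place, keeping neighbor degrees current."""
    n = adj.shape[0]
    for j in range(n):
        if adj[dead, j]:
            deg[j] -= 1
            adj[dead, j] = 0
            adj[j, dead] = 0
    deg[dead] = 0


@njit(cache=True)
def compute_payoffs(adj, deg, types, B, C, D, C_link, D_pl, per_link, out, scratch):
    """Payoffs of every living individual under the current network.

    Diluted model (default): u_i = sum_j a_ij p_j (B/d_j + p_i D/(d_i d_j))
    - p_i C - d_i C_link. A cooperator's total benefit B is split equally
    among its partners, so isolated cooperators give nothing and keep
    paying C.

    Per-link model: u_i = sum_j a_ij (p_j B + p_i p_j D_pl)
    - p_i d_i C - d_i C_link, with benefit and cost proportional to the
    number of partners.
    """
    n = adj.shape[0]
    if per_link:
        for j in range(n):
            scratch[j] = 1.0 if types[j] else 0.0
        for i in range(n):
            k = 0.0
            row = adj[i]
            for j in range(n):
                k += row[j] * scratch[j]
            if types[i]:
                out[i] = k * (B + D_pl) - deg[i] * C - deg[i] * C_link
            else:
                out[i] = k * B - deg[i] * C_link
    else:
        for j in range(n):
            if types[j] and deg[j] > 0:
                scratch[j] = B / deg[j]
            else:
                scratch[j] = 0.0
        if D == 0.0:
            for i in range(n):
                s = 0.0
                row = adj[i]
                for j in range(n):
                    s += row[j] * scratch[j]
                if types[i]:
                    out[i] = s - C - deg[i] * C_link
                else:
                    out[i] = s - deg[i] * C_link
        else:
            for i in range(n):
                s = 0.0
                s2 = 0.0
                row = adj[i]
                for j in range(n):
                    if row[j]:
                        s += scratch[j]
                        if types[j]:
                            s2 += 1.0 / deg[j]
                if types[i]:
                    if deg[i] > 0:
                        s += D * s2 / deg[i]
                    out[i] = s - C - deg[i] * C_link
                else:
                    out[i] = s - deg[i] * C_link
    return out


@njit(cache=True)
def fitness_from_payoffs(u, delta, out):
    """w_i = (1 + delta)**u_i, computed in log space (strictly positive)."""
    log1pd = np.log(1.0 + delta)
    for i in range(u.shape[0]):
        out[i] = np.exp(u[i] * log1pd)
    return out


@njit(cache=True)
def sample_parent(fitness, dead, u, exclude_dead):
    """Invert a uniform draw ``u`` through the cumulative fitness.

    Fitness-proportional choice among survivors (``dead`` excluded when
    ``exclude_dead``). Equivalent to sampling from the normalized
    reproduction probabilities.
    """
    n = fitness.shape[0]
    tot = 0.0
    for j in range(n):
        if exclude_dead and j == dead:
            continue
        tot += fitness[j]
    target = u * tot
    acc = 0.0
    last = -1
    for j in range(n):
        if exclude_dead and j == dead:
            continue
        acc += fitness[j]
        last = j
        if target <= acc:
            return j
    return last  # guard against floating roundoff at target ~= tot


@njit(cache=True)
def mutate_type_draw(parent_type, mu, rng):
    """Copy the parent's allele, flipping with probability mu."""
    if mu > 0.0 and rng.random() < mu:
        return 1 - parent_type
    return parent_type


@njit(cache=True)
def mutate_trait_draw(value, mu_l, sigma, rng):
    """With probability mu_l add a N(0, sigma) step, clamped to [0, 1]."""
    if mu_l > 0.0 and rng.random() < mu_l:
        value = value + rng.normal(0.0, sigma)
        if value < 0.0:
            value = 0.0
        elif value > 1.0:
            value = 1.0
    return value


@njit(cache=True)
def run_steps(
    adj,
    deg,
    types,
    pn,
    pr,
    payoff,
    fitness,
    n_steps,
    B,
    C,
    D,
    C_link,
    D_pl,
    per_link,
    delta,
    mu,
    mu_l,
    sigma_n,
    sigma_r,
    evolve_pn,
    evolve_pr,
    neutral,
    exclude_dead,
    rng,
):
    """Advance the population ``n_steps`` death–birth events in place.

    Each event: a uniformly random individual dies; a parent is drawn
    among the survivors with probability proportional to the fitness
    cached at the end of the previous event; the dead individual's edges
    are removed; the newborn (occupying the freed slot as a fresh
    individual) inherits the parent's allele and linking traits subject
    to mutation, then wires itself with its *own* traits; payoffs and
    fitness of all N individuals are recomputed and cached.

    With ``neutral`` set, parents are drawn uniformly and the payoff
    cache is left untouched (used for the burn-in and delta = 0 runs
    where payoffs are never consulted).
    """
    n = adj.shape[0]
    mask = np.empty(n, dtype=np.uint8)
    scratch = np.empty(n, dtype=np.float64)
    for _ in range(n_steps):
        dead = rng.integers(0, n)
        if neutral:
            if exclude_dead:
                k = rng.integers(0, n - 1)
                parent = k if k < dead else k + 1
            else:
                parent = rng.integers(0, n)
        else:
            parent = sample_parent(fitness, dead, rng.random(), exclude_dead)

        if parent == dead:
            # Inclusive-lottery corner: the dying individual reproduces.
            # The newborn sees its parent's pre-removal neighborhood but
            # has no parent left to link to with certainty.
            for j in range(n):
                mask[j] = adj[dead, j]
            remove_individual(adj, deg, dead)
            t = mutate_type_draw(types[dead], mu, rng)
            new_pn = mutate_trait_draw(pn[dead], mu_l, sigma_n, rng) if evolve_pn else pn[dead]
            new_pr = mutate_trait_draw(pr[dead], mu_l, sigma_r, rng) if evolve_pr else pr[dead]
            d_new = 0
            for j in range(n):
                if j == dead:
                    continue
                p = new_pn if mask[j] else new_pr
                if rng.random() < p:
                    adj[dead, j] = 1
                    adj[j, dead] = 1
                    deg[j] += 1
                    d_new += 1
            deg[dead] = d_new
        else:
            remove_individual(adj, deg, dead)
            t = mutate_type_draw(types[parent], mu, rng)
            new_pn = mutate_trait_draw(pn[parent], mu_l, sigma_n, rng) if evolve_pn else pn[parent]
            new_pr = mutate_trait_draw(pr[parent], mu_l, sigma_r, rng) if evolve_pr else pr[parent]
            link_mask(adj, parent, new_pn, new_pr, dead, rng, mask)
            d_new = 0
            for j in range(n):
                if mask[j]:
                    adj[dead, j] = 1
                    adj[j, dead] = 1
                    deg[j] += 1
                    d_new += 1
            deg[dead] = d_new
        types[dead] = t
        pn[dead] = new_pn
        pr[dead] = new_pr

        if not neutral:
            compute_payoffs(adj, deg, types, B, C, D, C_link, D_pl, per_link, payoff, scratch)
            fitness_from_payoffs(payoff, delta, fitness)
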