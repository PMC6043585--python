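"""Payoffs, fitness and the reproduction lottery.

Two payoff games are implemented. In the default *diluted-benefit* game
(a special case of the coauthor game) each cooperator spreads a fixed
total benefit B equally over its partners and pays a fixed cost C;
connected cooperators can additionally share a synergy D divided by the
product of their degrees, and every individual pays a per-edge
maintenance cost C_link:

    u_i = sum_{j != i} p_j a_ij (B/d_j + p_i D/(d_i d_j)) - p_i C - d_i C_link

with p in {0, 1} the cooperation allele, a the adjacency and d the
degrees. In the *per-link* variant (a networked prisoner's dilemma)
benefit and cost scale with the number of partners:

    u_i = sum_{j != i} a_ij (p_j B + p_i p_j D_pl) - p_i d_i C - d_i C_link

Payoff maps to fitness through w_i = (1 + delta)**u_i, and the parent of
each birth is drawn among the survivors with probability proportional to
the fitness cached from the previous time step.
"""

from __future__ import annotations

import numpy as np

from . import _kernel
from .network import degrees
from .params import GameParams, PER_LINK

__all__ = [
    "payoffs",
    "payoffs_diluted",
    "payoffs_per_link",
    "fitness",
    "reproduction_probabilities",
    "sample_parent",
]


def _validate_types(types: np.ndarray, n: int) -> np.ndarray:
    types = np.asarray(types)
    if types.shape != (n,):
        raise ValueError(f"types must have shape ({n},), got {types.shape}")
    if not np.all((types == 0) | (types == 1)):
        raise ValueError("types must be binary: 1 = cooperator, 0 = defector")
    return types.astype(np.int8)


def _payoffs(adj, types, params: GameParams, per_link: bool) -> np.ndarray:
    adj = np.ascontiguousarray(adj, dtype=np.uint8)
    n = adj.shape[0]
    types = _validate_types(types, n)
    deg = degrees(adj)
    out = np.empty(n, dtype=np.float64)
    scratch = np.empty(n, dtype=np.float64)
    _kernel.compute_payoffs(
        adj, deg, types, params.B, params.C, params.D, params.C_link,
        params.D_pl, per_link, out, scratch,
    )
    return out


def payoffs_diluted(adj, types, params: GameParams) -> np.ndarray:
    """Diluted-benefit payoffs u_i for every living individual.

    Isolated cooperators earn -C (the empty benefit sum leaves only the
    cost); isolated defectors earn 0. No division by a zero degree can
    occur because absent edges contribute nothing.
    """
    return _payoffs(adj, types, params, per_link=False)


def payoffs_per_link(adj, types, params: GameParams) -> np.ndarray:
    """Per-link (prisoner's dilemma) payoffs: constant benefit B and cost
    C per partner, optional per-link synergy ``params.D_pl``."""
    return _payoffs(adj, types, params, per_link=True)


def payoffs(adj, types, params: GameParams) -> np.ndarray:
    """Dispatch on ``params.payoff_model``."""
    return _payoffs(adj, types, params, per_link=params.payoff_model == PER_LINK)


def fitness(u: np.ndarray, delta: float) -> np.ndarray:
    """w_i = (1 + delta)**u_i, elementwise; strictly positive.

    Computed as exp(u * log1p(delta)) to stay well-defined for negative
    payoffs. delta = 0 gives w_i = 1 for everyone (neutrality).
    """
    if delta < 0:
        raise ValueError(f"selection strength delta must be >= 0, got {delta}")
    u = np.asarray(u, dtype=np.float64)
    out = np.empty_like(u)
    _kernel.fitness_from_payoffs(u, delta, out)
    return out


def reproduction_probabilities(
    w: np.ndarray, dead: int | None = None, exclude_dead: bool = True
) -> np.ndarray:
    """Fitness-proportional lottery weights over the survivors.

    Returns a full-length probability vector summing to 1; the entry of
    the dying individual is 0 when it is excluded from the lottery (the
    default reading of "another individual is selected to reproduce").
    """
    w = np.asarray(w, dtype=np.float64)
    pi = w.copy()
    if dead is not None and exclude_dead:
        pi[dead] = 0.0
    tot = pi.sum()
    if tot <= 0:
        raise ValueError("degenerate lottery: total fitness weight is zero")
    return pi / tot


def sample_parent(
    w: np.ndarray, dead: int, rng: np.random.Generator, exclude_dead: bool = True
) -> int:
    """Draw one parent by inverse transform through the cumulative fitness."""
    w = np.asarray(w, dtype=np.float64)
    return int(_kernel.sample_parent(w, dead, rng.random(), exclude_dead))
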