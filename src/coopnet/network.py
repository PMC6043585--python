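"""The dynamic, binary, undirected social network.

The network is stored as a dense symmetric uint8 adjacency matrix with a
zero diagonal; the population size is fixed, and the only structural
events are Erdős–Rényi initialization and the death–birth replacement in
which a newborn takes over the dead individual's slot as a fresh
individual and wires itself by social inheritance:

* it connects to its parent with certainty,
* to each current neighbor of the parent independently with probability
  ``p_n`` (social inheritance),
* to every other living individual independently with probability
  ``p_r`` (random linking).

The dead individual's edges are removed *before* the newborn links, so
"the parent's neighbors at the time of birth" never include the dead.
Isolated individuals (degree 0) are permitted; they can arise when a
newborn's parent later dies.
"""

from __future__ import annotations

import numpy as np

from . import _kernel

__all__ = [
    "initial_network",
    "degrees",
    "newborn_links",
    "replace_individual",
    "check_network",
    "write_edge_list",
    "write_attributes",
]


def initial_network(n: int, p0: float, rng: np.random.Generator) -> np.ndarray:
    """Erdős–Rényi G(n, p0) adjacency matrix (uint8, symmetric, no loops).

    Each unordered pair is linked independently with probability ``p0``.
    """
    if n < 3:
        raise ValueError(f"population size must be >= 3, got {n}")
    if not 0 <= p0 <= 1:
        raise ValueError(f"edge probability p0 must lie in [0, 1], got {p0}")
    upper = np.triu(rng.random((n, n)) < p0, k=1)
    adj = (upper | upper.T).astype(np.uint8)
    return adj


def degrees(adj: np.ndarray) -> np.ndarray:
    """Row sums of the adjacency matrix, as int64."""
    return adj.sum(axis=1, dtype=np.int64)


def newborn_links(
    adj: np.ndarray,
    parent: int,
    p_n: float,
    p_r: float,
    rng: np.random.Generator,
    skip: int = -1,
) -> np.ndarray:
    """Ids the newborn connects to: parent always, neighbors w.p. p_n,
    non-neighbors w.p. p_r.

    ``adj`` must already reflect the removal of the dead individual.
    ``skip`` marks the newborn's own slot when it is represented in
    ``adj`` (it never links to itself); -1 if not represented.
    """
    n = adj.shape[0]
    if not 0 <= parent < n:
        raise ValueError(f"unknown individual {parent} in a population of {n}")
    mask = np.empty(n, dtype=np.uint8)
    _kernel.link_mask(adj, parent, p_n, p_r, skip, rng, mask)
    return np.flatnonzero(mask)


def replace_individual(
    adj: np.ndarray,
    dead: int,
    parent: int,
    p_n: float,
    p_r: float,
    rng: np.random.Generator,
    deg: np.ndarray | None = None,
) -> np.ndarray:
    """Replace ``dead`` by a newborn child of ``parent``, in place.

    Removes the dead individual and all its edges first, then wires the
    newborn (reusing the freed slot as a fresh individual) via
    :func:`newborn_links`. Population size is conserved and the newborn's
    degree is at least 1 (its parent). Returns ``adj``.
    """
    n = adj.shape[0]
    if dead == parent:
        raise ValueError("an individual cannot replace itself (dead == parent)")
    for name, idx in (("dead", dead), ("parent", parent)):
        if not 0 <= idx < n:
            raise ValueError(f"unknown {name} individual {idx} in a population of {n}")
    if deg is None:
        deg = degrees(adj)
    _kernel.remove_individual(adj, deg, dead)
    links = newborn_links(adj, parent, p_n, p_r, rng, skip=dead)
    adj[dead, links] = 1
    adj[links, dead] = 1
    deg[links] += 1
    deg[dead] = links.size
    return adj


def check_network(adj: np.ndarray) -> None:
    """Assert the structural invariants: binary, symmetric, zero diagonal."""
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.all((adj == 0) | (adj == 1)):
        raise ValueError("adjacency entries must be 0 or 1")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency must have a zero diagonal (no self-loops)")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")


def write_edge_list(adj: np.ndarray, path) -> None:
    """Plain-text edge list: one ``i j`` pair per line, i < j, 0-based."""
    ii, jj = np.nonzero(np.triu(adj, k=1))
    with open(path, "w") as fh:
        for i, j in zip(ii, jj):
            fh.write(f"{i} {j}\n")


def write_attributes(path, types, p_n, p_r, adj) -> None:
    """Per-individual attribute table (CSV: id, type, p_n, p_r, degree)."""
    import pandas as pd

    deg = degrees(adj)
    pd.DataFrame(
        {
            "id": np.arange(adj.shape[0]),
            "type": np.asarray(types, dtype=int),
            "p_n": p_n,
            "p_r": p_r,
            "degree": deg,
        }
    ).to_csv(path, index=False)
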