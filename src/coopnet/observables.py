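"""Per-generation summary statistics and their aggregation.

The recorded observables mirror what the model's outcomes are judged by:
cooperation frequency, the population means of the linking traits,
degree, payoff and fitness, and two measures of cooperator assortment.

The primary assortment measure is the neighbor-frequency difference

    A = f_C|C - f_C|D,

where ``f_C|C`` is the mean over cooperators with degree >= 1 of the
fraction of their neighbors that are cooperators, and ``f_C|D`` the
analogue over defectors. A > 0 means cooperators disproportionately
neighbor cooperators — the structural condition that makes diluted
cooperation pay. A is undefined (NaN) when either class has no member
with degree >= 1. Newman's attribute assortativity of the binary type is
recorded alongside for robustness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import degrees

__all__ = [
    "cooperation_frequency",
    "mean_degree",
    "assortment",
    "attribute_assortativity",
    "record",
    "RECORD_FIELDS",
    "summarize",
]

RECORD_FIELDS = (
    "coop_freq",
    "mean_pn",
    "mean_pr",
    "mean_degree",
    "mean_payoff",
    "mean_fitness",
    "assortment",
    "assortativity",
)


def cooperation_frequency(state) -> float:
    """Exact cooperator fraction (#cooperators / N)."""
    types = np.asarray(state.types)
    return float(types.sum()) / types.shape[0]


def mean_degree(adj: np.ndarray) -> float:
    """2 x (edge count) / N, via the exact row sums."""
    return float(degrees(adj).mean())


def _neighbor_coop_fractions(adj: np.ndarray, types: np.ndarray):
    deg = adj.sum(axis=1, dtype=np.int64)
    coop_neighbors = adj @ types.astype(np.float64)
    alive = deg > 0
    frac = np.full(adj.shape[0], np.nan)
    frac[alive] = coop_neighbors[alive] / deg[alive]
    return frac, alive


def assortment(state) -> float:
    """Primary measure A = f_C|C - f_C|D; NaN when undefined.

    Degree-0 individuals are excluded from the class means (their
    neighbor fraction is undefined). Lies in [-1, 1] whenever defined.
    """
    adj = np.asarray(state.adjacency)
    types = np.asarray(state.types)
    frac, alive = _neighbor_coop_fractions(adj, types)
    coop = alive & (types == 1)
    defe = alive & (types == 0)
    if not coop.any() or not defe.any():
        return float("nan")
    return float(frac[coop].mean() - frac[defe].mean())


def attribute_assortativity(state) -> float:
    """Newman assortativity coefficient of the binary cooperation type.

    r = (tr e - sum(e @ e)) / (1 - sum(e @ e)) with e the 2x2 mixing
    matrix over directed edge ends. NaN for an empty network or when all
    edge ends carry one type (degenerate denominator).
    """
    adj = np.asarray(state.adjacency)
    types = np.asarray(state.types, dtype=np.intp)
    e = np.zeros((2, 2))
    ii, jj = np.nonzero(adj)
    if ii.size == 0:
        return float("nan")
    np.add.at(e, (types[ii], types[jj]), 1.0)
    e /= e.sum()
    s = float((e @ e).sum())
    if s == 1.0:
        return float("nan")
    return float((np.trace(e) - s) / (1.0 - s))


def record(state, generation: int) -> dict:
    """One GenerationRecord row for the time series."""
    return {
        "generation": generation,
        "coop_freq": cooperation_frequency(state),
        "mean_pn": float(np.mean(state.p_n)),
        "mean_pr": float(np.mean(state.p_r)),
        "mean_degree": mean_degree(state.adjacency),
        "mean_payoff": float(np.mean(state.payoffs)),
        "mean_fitness": float(np.mean(state.fitnesses)),
        "assortment": assortment(state),
        "assortativity": attribute_assortativity(state),
    }


def _tail_length(n_records: int, tail: int | float) -> int:
    if isinstance(tail, float):
        if not 0 < tail <= 1:
            raise ValueError(f"fractional tail must lie in (0, 1], got {tail}")
        k = max(1, int(round(tail * n_records)))
    else:
        k = int(tail)
    if k < 1:
        raise ValueError(f"tail window must be >= 1 record, got {k}")
    if k > n_records:
        raise ValueError(
            f"tail window of {k} records exceeds series length {n_records}"
        )
    return k


def summarize(series: list[pd.DataFrame], tail: int | float = 0.8) -> pd.DataFrame:
    """Trailing-window summary across replicate time series.

    ``tail`` is either a number of trailing records (int) or a trailing
    fraction of the series (float in (0, 1]). Each replicate is first
    averaged over its trailing window (NaN-aware, so undefined
    assortment records drop out), then the mean and SD across replicates
    are reported per field. All series must share the recording grid.
    """
    if not series:
        raise ValueError("summarize requires at least one series")
    grids = [tuple(s["generation"]) for s in series]
    if len(set(grids)) != 1:
        raise ValueError("all series must share the same recording grid")
    k = _tail_length(len(series[0]), tail)
    per_rep = np.array(
        [[s[f].tail(k).mean() for f in RECORD_FIELDS] for s in series]
    )
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(per_rep, axis=0)
        sd = np.nanstd(per_rep, axis=0)
    return pd.DataFrame({"field": RECORD_FIELDS, "mean": mean, "sd": sd})
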