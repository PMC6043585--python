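"""Replicate and parameter-sweep orchestration.

The figure-style experiments of the model are grids over two parameter
axes (e.g. p_n x p_r with fixed traits, or B x C_link with coevolving
traits), each cell averaged over independent replicates with a trailing
window. :func:`run_grid` executes such a grid; :func:`run_trajectories`
keeps the full per-generation series of every replicate (plus their
cross-replicate mean) for collapse-style analyses.

Replicate seeding contract: the random stream of each (cell, replicate)
pair is derived as ``SeedSequence([base_seed, cell_index, replicate])``,
so results are independent of evaluation order and could be farmed out
in parallel without shared state.

Named presets reconstruct the canonical experiments at desk scale; they
are deliberately scaled-down (fewer generations and replicates than the
reference protocol) and are documented as such.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evolution import run
from .observables import RECORD_FIELDS, summarize
from .params import EvoParams, GameParams, SimConfig

__all__ = [
    "SweepSpec",
    "run_grid",
    "run_trajectories",
    "replicate_rng",
    "apply_axis",
    "write_manifest",
    "PRESETS",
    "get_preset",
    "GRID_AXES",
]

# axis name -> (which params object, field)
GRID_AXES = {
    "B": ("game", "B"),
    "C": ("game", "C"),
    "D": ("game", "D"),
    "C_link": ("game", "C_link"),
    "delta": ("game", "delta"),
    "p_n": ("evo", "init_pn"),
    "p_r": ("evo", "init_pr"),
    "mu": ("evo", "mu"),
    "mu_l": ("evo", "mu_l"),
}


@dataclass(frozen=True)
class SweepSpec:
    """A (1- or 2-axis) parameter grid over shared base parameters."""

    config: SimConfig
    game: GameParams
    evo: EvoParams
    axis1: tuple[str, Sequence[float]]
    axis2: tuple[str, Sequence[float]] | None = None
    replicates: int = 1
    tail: int | float = 0.8

    def __post_init__(self) -> None:
        for axis in (self.axis1, self.axis2):
            if axis is not None and axis[0] not in GRID_AXES:
                raise ValueError(
                    f"unknown sweep axis {axis[0]!r}; known: {sorted(GRID_AXES)}"
                )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cells(self):
        vals2 = self.axis2[1] if self.axis2 is not None else [None]
        idx = 0
        for v1 in self.axis1[1]:
            for v2 in vals2:
                yield idx, v1, v2
                idx += 1


def apply_axis(
    game: GameParams, evo: EvoParams, name: str, value: float
) -> tuple[GameParams, EvoParams]:
    """Return copies of (game, evo) with the named axis set to ``value``."""
    target, fld = GRID_AXES[name]
    if target == "game":
        return game.replace(**{fld: value}), evo
    return game, evo.replace(**{fld: value})


def replicate_rng(base_seed: int, cell: int, rep: int) -> np.random.Generator:
    """Independent, order-invariant stream for one (cell, replicate) pair."""
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), cell, rep]))


def run_grid(spec: SweepSpec) -> pd.DataFrame:
    """Run every grid cell x replicate; one summary row per cell.

    Columns: the axis values, ``replicates``, and ``<field>_mean`` /
    ``<field>_sd`` for every recorded observable, aggregated over the
    trailing window of each replicate and then across replicates.
    """
    base_seed = spec.config.seed if spec.config.seed is not None else 0
    rows = []
    for cell, v1, v2 in spec.cells():
        game, evo = apply_axis(spec.game, spec.evo, spec.axis1[0], v1)
        if spec.axis2 is not None:
            game, evo = apply_axis(game, evo, spec.axis2[0], v2)
        series = []
        for rep in range(spec.replicates):
            cfg = spec.config.replace(replicate=rep)
            series.append(run(cfg, game, evo, rng=replicate_rng(base_seed, cell, rep)))
        summ = summarize(series, spec.tail)
        row: dict = {spec.axis1[0]: v1}
        if spec.axis2 is not None:
            row[spec.axis2[0]] = v2
        row["replicates"] = spec.replicates
        for fld, m, s in zip(summ["field"], summ["mean"], summ["sd"]):
            row[f"{fld}_mean"] = m
            row[f"{fld}_sd"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def run_trajectories(
    config: SimConfig,
    game: GameParams,
    evo: EvoParams,
    replicates: int = 1,
) -> dict:
    """Full per-generation series for each replicate plus their mean.

    Returns ``{"series": [DataFrame, ...], "mean": DataFrame}``; the
    mean trajectory averages every recorded field across replicates at
    each generation (NaN-aware for the assortment fields).
    """
    base_seed = config.seed if config.seed is not None else 0
    series = []
    for rep in range(replicates):
        cfg = config.replace(replicate=rep)
        series.append(run(cfg, game, evo, rng=replicate_rng(base_seed, 0, rep)))
    stacked = pd.concat(series)
    with np.errstate(invalid="ignore"):
        mean = (
            stacked.groupby("generation")[list(RECORD_FIELDS)]
            .mean()
            .reset_index()
        )
    return {"series": series, "mean": mean}


def write_manifest(path, config: SimConfig, game: GameParams, evo: EvoParams, **extra) -> None:
    """JSON record of the fully resolved configuration (reproducibility)."""
    doc = {
        "sim": dataclasses.asdict(config),
        "game": dataclasses.asdict(game),
        "evo": dataclasses.asdict(evo),
    }
    doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)


def _preset(config=None, game=None, evo=None, sweep=None):
    return {"config": config, "game": game, "evo": evo, "sweep": sweep}


def _fig1_smoke():
    cfg = SimConfig(n=100, generations=200, seed=0)
    game = GameParams(B=2.0, C=0.5, D=0.0, C_link=0.0, delta=0.1)
    evo = EvoParams(mu=0.001)
    sweep = SweepSpec(
        cfg, game, evo,
        axis1=("p_n", [0.1, 0.5, 0.9]),
        axis2=("p_r", [0.001, 0.01, 0.1, 0.3]),
        replicates=5, tail=0.8,
    )
    return _preset(cfg, game, evo, sweep)


def _fig2_smoke():
    base = _fig1_smoke()
    game = base["game"].replace(B=1.0, D=1.0)
    sweep = dataclasses.replace(base["sweep"], game=game)
    return _preset(base["config"], game, base["evo"], sweep)


def _fig3_smoke():
    cfg = SimConfig(n=100, generations=1000, seed=0)
    game = GameParams(B=2.0, C=0.5, D=0.0, C_link=0.0, delta=0.1)
    evo = EvoParams(
        mu=0.001, mu_l=0.01, sigma_n=0.01, sigma_r=0.01,
        evolve_pn=True, evolve_pr=True, init_pn=0.5, init_pr=0.001,
    )
    return _preset(cfg, game, evo, None)


def _fig4_smoke():
    cfg = SimConfig(n=100, generations=2000, seed=0)
    game = GameParams(B=2.0, C=0.5, D=0.0, delta=0.1)
    evo = EvoParams(
        mu=0.001, mu_l=0.001, sigma_n=0.01, sigma_r=0.01,
        evolve_pn=True, evolve_pr=True, init_pn=0.5, init_pr=0.0001,
    )
    sweep = SweepSpec(
        cfg, game, evo,
        axis1=("B", [1.0, 2.0, 4.0]),
        axis2=("C_link", [0.0, 0.2, 0.4]),
        replicates=5, tail=0.8,
    )
    return _preset(cfg, game, evo, sweep)


def _fig5_smoke():
    base = _fig4_smoke()
    game = base["game"].replace(B=1.0)
    sweep = dataclasses.replace(
        base["sweep"], game=game, axis1=("D", [0.0, 1.0, 2.0])
    )
    return _preset(base["config"], game, base["evo"], sweep)


def _fig6_smoke():
    cfg = SimConfig(n=100, generations=2000, seed=0)
    game = GameParams(B=2.0, C=0.5, D=0.0, delta=0.1)
    evo = EvoParams(
        mu=0.001, mu_l=0.001, sigma_r=0.01,
        evolve_pn=False, evolve_pr=True, init_pr=0.0001,
    )
    sweep = SweepSpec(
        cfg, game, evo,
        axis1=("p_n", [0.1, 0.5, 0.9]),
        axis2=("C_link", [0.0, 0.2, 0.4]),
        replicates=5, tail=0.8,
    )
    return _preset(cfg, game, evo, sweep)


PRESETS = {
    "fig1_smoke": _fig1_smoke,
    "fig2_smoke": _fig2_smoke,
    "fig3_smoke": _fig3_smoke,
    "fig4_smoke": _fig4_smoke,
    "fig5_smoke": _fig5_smoke,
    "fig6_smoke": _fig6_smoke,
}


def get_preset(name: str) -> dict:
    """Scaled-down named reconstruction of one canonical experiment."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None
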