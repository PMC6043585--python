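"""The death–birth evolutionary loop.

A run proceeds in three phases, with one *generation* defined as N
death–birth events:

1. Erdős–Rényi initialization of the network.
2. A selection-free burn-in (default 20 generations) of the pure
   social-inheritance process: uniform parent choice, no mutation, all
   individuals carrying the initial mean linking traits. This gives the
   network its stationary structure before selection starts, which makes
   the exact initial density immaterial.
3. Cooperation alleles are assigned independently with probability 1/2;
   evolving linking traits are drawn per individual from a normal around
   their initial means (SD = the mutational step size), clamped to
   [0, 1]. Selection then runs for the configured number of generations,
   recording summary observables on a per-generation grid.

Within each step the parent lottery uses the fitness cached at the end
of the *previous* step, and the newborn wires itself with its own
(possibly mutated) traits — which is what places the linking traits
under direct selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel, observables
from .network import check_network, degrees, initial_network
from .game import fitness as fitness_map
from .game import payoffs as compute_payoffs
from .params import EvoParams, GameParams, PER_LINK, SimConfig

__all__ = [
    "PopulationState",
    "mutate_type",
    "mutate_traits",
    "initialize",
    "step",
    "run",
    "run_to_fixation",
]


@dataclass
class PopulationState:
    """Full state of the population at one time step.

    ``payoffs`` and ``fitnesses`` are the caches from the end of the
    previous time step; they are what the next reproduction lottery
    consults.
    """

    adjacency: np.ndarray
    types: np.ndarray
    p_n: np.ndarray
    p_r: np.ndarray
    payoffs: np.ndarray
    fitnesses: np.ndarray
    degrees: np.ndarray = field(default=None)  # type: ignore[assignment]
    step_counter: int = 0

    def __post_init__(self) -> None:
        if self.degrees is None:
            self.degrees = degrees(self.adjacency)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def validate(self) -> None:
        """Assert structural and bookkeeping invariants (test hook)."""
        check_network(self.adjacency)
        n = self.n
        for name in ("types", "p_n", "p_r", "payoffs", "fitnesses", "degrees"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if not np.all((self.types == 0) | (self.types == 1)):
            raise ValueError("types must be binary")
        if np.any((self.p_n < 0) | (self.p_n > 1) | (self.p_r < 0) | (self.p_r > 1)):
            raise ValueError("linking traits must lie in [0, 1]")
        if not np.array_equal(self.degrees, degrees(self.adjacency)):
            raise ValueError("cached degrees are stale")
        if np.any(self.fitnesses <= 0):
            raise ValueError("fitness must be strictly positive")


def mutate_type(parent_type: int, mu: float, rng: np.random.Generator) -> int:
    """Offspring allele: the parent's with probability 1 - mu, else flipped."""
    if parent_type not in (0, 1):
        raise ValueError(f"parent_type must be 0 or 1, got {parent_type}")
    return int(_kernel.mutate_type_draw(np.int8(parent_type), mu, rng))


def mutate_traits(
    p_n: float, p_r: float, evo: EvoParams, rng: np.random.Generator
) -> tuple[float, float]:
    """Offspring linking traits.

    Each evolving trait independently mutates with probability ``mu_l``
    by a Gaussian step (SD ``sigma_n`` / ``sigma_r``) and is clamped to
    [0, 1]; non-evolving traits are copied verbatim. p_n is drawn before
    p_r (fixed stream order).
    """
    new_n = (
        float(_kernel.mutate_trait_draw(p_n, evo.mu_l, evo.sigma_n, rng))
        if evo.evolve_pn
        else p_n
    )
    new_r = (
        float(_kernel.mutate_trait_draw(p_r, evo.mu_l, evo.sigma_r, rng))
        if evo.evolve_pr
        else p_r
    )
    return new_n, new_r


def _refresh_caches(state: PopulationState, game: GameParams) -> None:
    state.payoffs = compute_payoffs(state.adjacency, state.types, game)
    state.fitnesses = fitness_map(state.payoffs, game.delta)


def initialize(
    config: SimConfig,
    game: GameParams,
    evo: EvoParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Build the post-burn-in initial population state.

    Runs the neutral social-inheritance process for
    ``config.burn_in_generations`` generations on a G(n, p0) seed
    network, then assigns alleles (frequency 1/2) and individual linking
    traits, and fills the payoff/fitness caches.
    """
    n = config.n
    adj = initial_network(n, config.p0, rng)
    deg = degrees(adj)
    types = np.zeros(n, dtype=np.int8)
    pn = np.full(n, float(evo.init_pn))
    pr = np.full(n, float(evo.init_pr))
    payoff = np.zeros(n)
    fit = np.ones(n)
    burn_steps = config.burn_in_generations * n
    if burn_steps:
        _kernel.run_steps(
            adj, deg, types, pn, pr, payoff, fit, burn_steps,
            game.B, game.C, game.D, game.C_link, game.D_pl,
            game.payoff_model == PER_LINK, game.delta,
            0.0, 0.0, 0.0, 0.0, False, False,
            True, config.lottery_excludes_dead, rng,
        )
    types[:] = rng.random(n) < 0.5
    if evo.evolve_pn:
        pn[:] = np.clip(rng.normal(evo.init_pn, evo.sigma_n, n), 0.0, 1.0)
    if evo.evolve_pr:
        pr[:] = np.clip(rng.normal(evo.init_pr, evo.sigma_r, n), 0.0, 1.0)
    state = PopulationState(adj, types, pn, pr, payoff, fit, deg)
    _refresh_caches(state, game)
    return state


def _advance(
    state: PopulationState,
    game: GameParams,
    evo: EvoParams,
    rng: np.random.Generator,
    n_steps: int,
    neutral: bool = False,
    exclude_dead: bool = True,
) -> None:
    _kernel.run_steps(
        state.adjacency, state.degrees, state.types, state.p_n, state.p_r,
        state.payoffs, state.fitnesses, n_steps,
        game.B, game.C, game.D, game.C_link, game.D_pl,
        game.payoff_model == PER_LINK, game.delta,
        evo.mu, evo.mu_l, evo.sigma_n, evo.sigma_r,
        evo.evolve_pn, evo.evolve_pr,
        neutral, exclude_dead, rng,
    )
    state.step_counter += n_steps


def step(
    state: PopulationState,
    game: GameParams,
    evo: EvoParams,
    rng: np.random.Generator,
    exclude_dead: bool = True,
) -> PopulationState:
    """One death–birth event, in place.

    Order of events: (1) uniform death draw; (2) parent draw among
    survivors proportional to cached fitness; (3) removal of the dead;
    (4) allele and trait inheritance with mutation; (5) wiring of the
    newborn with its own traits; (6) payoff/fitness recomputation for
    all N individuals.
    """
    _advance(state, game, evo, rng, 1, neutral=False, exclude_dead=exclude_dead)
    return state


def run(
    config: SimConfig,
    game: GameParams,
    evo: EvoParams,
    rng: np.random.Generator | None = None,
    on_record=None,
) -> pd.DataFrame:
    """Full simulation; returns the per-generation time series.

    The first row is the post-burn-in initial record (generation 0);
    thereafter one record every ``config.record_every`` generations.
    Passing ``rng`` overrides ``config.seed`` (used by the sweep driver
    to hand each replicate its own derived stream). ``on_record`` is an
    optional ``(state, generation)`` callback fired at every recording
    point, e.g. for edge-list snapshots.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = initialize(config, game, evo, rng)
    records = [observables.record(state, generation=0)]
    if on_record is not None:
        on_record(state, 0)
    gens_done = 0
    while gens_done < config.generations:
        chunk = min(config.record_every, config.generations - gens_done)
        _advance(
            state, game, evo, rng, chunk * config.n,
            neutral=False, exclude_dead=config.lottery_excludes_dead,
        )
        gens_done += chunk
        records.append(observables.record(state, generation=gens_done))
        if on_record is not None:
            on_record(state, gens_done)
    df = pd.DataFrame.from_records(records)
    df["replicate"] = config.replicate
    return df


def run_to_fixation(
    config: SimConfig,
    game: GameParams,
    evo: EvoParams,
    rng: np.random.Generator | None = None,
    max_generations: int | None = None,
) -> tuple[int, int]:
    """Run until the cooperation allele fixes or is lost (requires mu = 0).

    Returns ``(fixed_type, generations_elapsed)``; ``fixed_type`` is -1
    if ``max_generations`` elapsed without absorption. Under delta = 0
    the payoff machinery is skipped (the lottery is uniform).
    """
    if evo.mu != 0:
        raise ValueError("fixation runs require mu = 0 (no allele mutation)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = initialize(config, game, evo, rng)
    neutral = game.delta == 0
    gen = 0
    while True:
        k = int(state.types.sum())
        if k == 0 or k == state.n:
            return int(k > 0), gen
        if max_generations is not None and gen >= max_generations:
            return -1, gen
        _advance(
            state, game, evo, rng, state.n,
            neutral=neutral, exclude_dead=config.lottery_excludes_dead,
        )
        gen += 1
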