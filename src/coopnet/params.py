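"""Parameter containers for the social-inheritance cooperation model.

Three frozen dataclasses group the knobs of the model:

* :class:`GameParams` — the payoff game played on the network and the
  payoff-to-fitness map.
* :class:`EvoParams` — mutation rates and which linking traits evolve.
* :class:`SimConfig` — population size, run lengths, recording cadence
  and the seed.

All are validated on construction; invalid values raise ``ValueError``
before any simulation work starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["GameParams", "EvoParams", "SimConfig", "DILUTED", "PER_LINK"]

DILUTED = "diluted"
PER_LINK = "per_link"


@dataclass(frozen=True)
class GameParams:
    """Payoff and selection parameters.

    Parameters
    ----------
    B:
        Benefit provided by a cooperator. In the ``diluted`` model this is
        the cooperator's *total* benefit, split equally among its current
        partners (each partner receives ``B / degree``); in the
        ``per_link`` model it is a constant benefit per partner.
    C:
        Cost of cooperating. Fixed per individual in the ``diluted``
        model, paid per partner in the ``per_link`` model.
    D:
        Synergistic benefit on cooperator–cooperator edges of the diluted
        model, divided by the product of the two degrees.
    C_link:
        Per-edge maintenance cost paid by every individual regardless of
        type.
    delta:
        Selection strength δ ≥ 0 in the fitness map ``w = (1 + δ)**u``;
        δ = 0 is neutrality.
    payoff_model:
        ``"diluted"`` (fixed total benefit) or ``"per_link"`` (fixed
        benefit and cost per partner, a networked prisoner's dilemma).
    D_pl:
        Per-link synergy of the ``per_link`` model (default 0).
    """

    B: float = 2.0
    C: float = 0.5
    D: float = 0.0
    C_link: float = 0.0
    delta: float = 0.1
    payoff_model: str = DILUTED
    D_pl: float = 0.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"selection strength delta must be >= 0, got {self.delta}")
        if self.C_link < 0:
            raise ValueError(f"link cost C_link must be >= 0, got {self.C_link}")
        if self.payoff_model not in (DILUTED, PER_LINK):
            raise ValueError(
                f"payoff_model must be {DILUTED!r} or {PER_LINK!r}, got {self.payoff_model!r}"
            )

    def replace(self, **changes) -> "GameParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class EvoParams:
    """Mutation and trait-evolution parameters.

    ``mu`` is the probability that a newborn's cooperation allele flips
    relative to its parent. ``mu_l`` is the per-trait mutation
    probability of the linking traits; a mutating trait receives a
    Gaussian perturbation with standard deviation ``sigma_n`` (for p_n)
    or ``sigma_r`` (for p_r) and is clamped to [0, 1].

    The two ``evolve_*`` flags encode the scenario: (False, False) is the
    fixed-trait model, (True, True) full coevolution, (False, True)
    exogenously fixed social inheritance with evolving random linking.
    ``init_pn`` / ``init_pr`` are the population means at initialization
    (and the fixed values when a trait does not evolve).
    """

    mu: float = 0.001
    mu_l: float = 0.0
    sigma_n: float = 0.01
    sigma_r: float = 0.01
    evolve_pn: bool = False
    evolve_pr: bool = False
    init_pn: float = 0.5
    init_pr: float = 0.0001

    def __post_init__(self) -> None:
        for name in ("mu", "mu_l"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("init_pn", "init_pr"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sigma_n < 0 or self.sigma_r < 0:
            raise ValueError("mutation step standard deviations must be >= 0")

    @property
    def scenario(self) -> str:
        if self.evolve_pn and self.evolve_pr:
            return "coevolve"
        if self.evolve_pr:
            return "fixed_pn"
        if self.evolve_pn:
            return "fixed_pr"
        return "fixed_traits"

    def replace(self, **changes) -> "EvoParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SimConfig:
    """Run-shape configuration.

    One *generation* equals ``n`` death–birth events. A run consists of
    an Erdős–Rényi initialization with edge density ``p0``, a selection-
    free burn-in of ``burn_in_generations`` generations (so the network
    reaches the stationary structure of the social-inheritance process
    before alleles are assigned), and ``generations`` generations of
    selection, recorded every ``record_every`` generations.

    ``lottery_excludes_dead`` controls whether the individual selected to
    die can also be drawn as parent in the same time step (default: it
    cannot — "another individual is selected to reproduce").
    """

    n: int = 100
    p0: float = 0.1
    burn_in_generations: int = 20
    generations: int = 500
    record_every: int = 1
    seed: int | None = None
    replicate: int = 0
    lottery_excludes_dead: bool = True

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"population size n must be >= 3, got {self.n}")
        if not 0 <= self.p0 <= 1:
            raise ValueError(f"initial edge density p0 must lie in [0, 1], got {self.p0}")
        if self.burn_in_generations < 0:
            raise ValueError("burn_in_generations must be >= 0")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)
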