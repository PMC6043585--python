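# coopnet

**Evolution of cooperation on dynamic social networks with social
inheritance of ties.**

Social structure decides whether cooperation pays, but social structure
is itself a product of evolving behavior. `coopnet` is an agent-based
simulator for studying that feedback: a death–birth process on a
binary, undirected network of constant size N in which each newborn
connects to its parent with certainty, to each of its parent's
neighbors with probability *p_n* (social inheritance), and to everyone
else with probability *p_r* (random linking). Cooperators play a
diluted-benefit game on the resulting network, and both the cooperation
allele and the linking probabilities (p_n, p_r) can be made heritable,
so network structure coevolves with the behavior it selects for.

The package is for evolutionary game theorists and behavioral
ecologists who want to reproduce — or build on — the core phenomena of
this model family: cooperation is maintained under low random linking;
when linking traits coevolve, cooperative populations select for more
random linking, which collapses cooperation; per-link maintenance costs
or exogenously fixed high social inheritance can rescue it.

## Model

Payoff of individual *i* with allele *p_i* ∈ {0, 1} on adjacency
*a_ij* with degrees *d_i*:

    u_i = Σ_{j≠i} p_j a_ij ( B/d_j + p_i D/(d_i d_j) ) − p_i C − d_i C_link

(a cooperator's total benefit B is split equally over its partners; D
is a synergy on cooperator–cooperator edges; C_link a per-edge cost paid
by everyone). Fitness is w_i = (1 + δ)^{u_i}; each time step a uniform
random individual dies and a survivor reproduces with probability
∝ w(t−1). Offspring copy the parent's allele (flip probability μ) and
linking traits (per-trait Gaussian mutation with probability μ_l, SD
σ_n / σ_r, clamped to [0, 1]), and wire with their own traits. A
per-link payoff variant (networked prisoner's dilemma) is included.
See `docs/methods.md` for the full protocol, defaults, and numerical
choices.

## Worked example

`examples/02_coevolution_collapse.py` lets both linking traits evolve
from a cooperation-friendly start (p_r = 0.001):

```
replicates: 10, generations: 1500
coop_freq  early 0.859  ->  late 0.307
mean p_r   early 0.0097  ->  late 0.0764
mean p_n   early 0.5017  ->  late 0.5105
```

Cooperation establishes quickly (86% early on), but in a cooperative
population every connection is profitable, so selection drives the
random-linking probability up (0.0097 → 0.0764, an order of magnitude
above its initial 0.001) — and with it the mixing that destroys the
assortment cooperation needs, so cooperation collapses to ~31%. The
social-inheritance probability p_n only drifts (0.50 → 0.51): there is
no comparable directional selection on it.

The same machinery in library form:

```python
from coopnet import SimConfig, GameParams, EvoParams, run

df = run(
    SimConfig(n=100, generations=500, seed=1),
    GameParams(B=2.0, C=0.5, delta=0.1),
    EvoParams(mu=0.001, init_pn=0.5, init_pr=0.001),
)
print(df[["generation", "coop_freq", "mean_degree", "assortment"]].tail())
```

The other examples cover the fixed-trait p_r sweep
(`01_fixed_linking_grid.py`), the rescue of cooperation by link costs
and its fitness price (`03_link_cost_rescue.py`), and network snapshot
export for external graph tools (`04_network_snapshots.py`).

A thin CLI wraps the same functions:

```sh
coopnet run --n 100 --generations 500 --seed 1 --out out/
coopnet grid --preset fig4_smoke --seed 1 --out grid/
coopnet trajectories --preset fig3_smoke --replicates 20 --out traj/
coopnet report --records out/timeseries.csv --tail 0.8
```

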