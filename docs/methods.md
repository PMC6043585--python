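# Methods

## Model

`coopnet` simulates the evolution of a cooperation allele on a dynamic,
binary, undirected social network of constant size N, assembled by
*social inheritance*. Time advances in death–birth events; one
**generation** is N events. At each event:

1. A uniformly random individual dies (mortality is payoff-independent).
2. A parent is drawn among the N − 1 survivors with probability
   proportional to the fitness cached at the end of the previous event,
   π_i = w_i / Σ_j w_j.
3. The dead individual's edges are removed. The newborn occupies the
   freed slot as a fresh individual (no trait or edge carry-over; with a
   fixed-size adjacency matrix this is bit-equivalent to relabeling).
4. The newborn inherits its parent's cooperation allele (flipping with
   probability μ) and linking traits (each evolving trait perturbed with
   probability μ_l by a N(0, σ) step, clamped to [0, 1]).
5. The newborn wires itself **with its own, possibly mutated traits**:
   to its parent with certainty, to each of the parent's current
   neighbors independently with probability p_n, and to every other
   living individual independently with probability p_r. Using the
   offspring's traits (rather than the parent's) is what places the
   linking traits under direct selection.
6. Payoffs and fitness of all N individuals are recomputed and cached;
   the cache is what the next event's lottery consults, so a newborn can
   reproduce in the very next event with the payoff earned from its
   initial connections.

Because the dead individual is removed *before* the newborn links,
"the parent's neighbors at the time of birth" never include the dead —
its connections cannot be inherited.

### Payoffs

Two games are implemented, selected by `GameParams.payoff_model`:

* **diluted** (default): each cooperator spreads a fixed total benefit B
  equally over its d partners and pays a fixed cost C; connected
  cooperators share a synergy D divided by the product of their degrees;
  every individual pays C_link per edge:

      u_i = Σ_{j≠i} p_j a_ij (B/d_j + p_i D/(d_i d_j)) − p_i C − d_i C_link

  Absent edges contribute nothing, so no division by a zero degree can
  occur; an isolated cooperator earns −C, an isolated defector 0.

* **per_link**: benefit B and cost C are per partner (a networked
  prisoner's dilemma), with optional per-link synergy D_pl (default 0 —
  the variant is defined by per-link benefit and cost; the synergy knob
  is kept for completeness):

      u_i = Σ_{j≠i} a_ij (p_j B + p_i p_j D_pl) − p_i d_i C − d_i C_link

Fitness is w_i = (1 + δ)^{u_i}, evaluated as exp(u_i·log1p(δ)) so it is
well-defined and strictly positive for negative payoffs; δ = 0 makes
the process neutral.

### Run protocol

A run starts from an Erdős–Rényi G(N, p0) network and executes a
selection-free burn-in (default 20 generations: uniform parent choice,
no mutation, every individual at the initial mean traits) so the network
reaches the stationary structure of the social-inheritance process
before selection starts. Default p0 = 0.1 (expected degree ≈ 10 at
N = 100); a test verifies that the post-burn-in mean degree is
insensitive to p0 ∈ {0.05, 0.1, 0.5}, which is why the exact value is
immaterial. After burn-in, cooperation alleles are assigned
independently with probability 1/2, and each *evolving* linking trait is
drawn per individual from N(initial mean, σ) clamped to [0, 1];
non-evolving traits stay at their initial value for everyone. Observables
are recorded once per generation (configurable cadence), starting with
the post-burn-in state as generation 0.

### Scenarios

The `evolve_pn` / `evolve_pr` flags of `EvoParams` encode the three
study designs: fixed traits (both false), full coevolution (both true),
and exogenously fixed social inheritance with evolving random linking
(`evolve_pr` only). Default initial p_r is 0.0001, with 0.001 used by
the collapse experiments; initial values do not affect the long-run
dynamics, which the trait-neutrality tests corroborate.

## Parameters that matter

| name | meaning | default | why |
|---|---|---|---|
| N | population size | 100 | the canonical experimental size; the engine supports any N ≥ 3 |
| B, C | benefit, cost of cooperating | 2.0, 0.5 | benefit–cost ratio 4, inside the region where low p_r sustains cooperation |
| D | degree-diluted synergy | 0 | switched on for synergy experiments |
| C_link | per-edge cost | 0 | the rescue knob; 0.2–0.4 is the interesting range at B = 2 |
| δ | selection strength | 0.1 | strong enough for clear selection, weak enough that payoffs of order 1 give w ≈ 1 + δu |
| μ | allele mutation / birth | 0.001 | keeps both alleles supplied without overwhelming selection |
| μ_l | trait mutation / trait / birth | 0 (fixed) | 0.01 in fast-coevolution runs, 0.001 in long grids |
| σ_n, σ_r | trait mutation step SD | 0.01 | small-step continuous trait evolution |
| p0 | initial ER density | 0.1 | erased by burn-in (tested) |

## What the simulator emulates — and what it does not

The generator *is* the model: networks arise purely from social
inheritance plus random linking over death–birth turnover. That process
reproduces the degree heterogeneity, clustering and assortment that make
within-group cooperation selectable, and it is the regime animal social
networks appear to occupy (moderate-to-high p_n, low p_r). It does not
model active partner choice or link-breaking, edge weights or decay, age
structure, payoff-dependent mortality, migration, or group-level
selection. Passing tests therefore demonstrate the internal logic of
the coevolutionary feedback, not that any particular empirical network
will exhibit it; real systems with partner choice or reciprocity have
additional stabilizing channels the model deliberately omits.

## Numerical and design choices

* **Single stochastic code path.** All stochastic events (death draw,
  lottery, mutations, wiring) are implemented once, in numba-compiled
  kernels that consume a shared `numpy.random.Generator`. The public
  per-event API (`step`, `newborn_links`, `mutate_traits`, …) and the
  long-run driver call the same kernels, so replicates are bit-repro-
  ducible from (seed, config) alone, with a documented draw order (see
  `coopnet/_kernel.py`). Replicate streams are derived as
  `SeedSequence([base_seed, cell_index, replicate])`, making sweep
  results independent of evaluation order and trivially parallelizable.
* **Lottery.** Parent choice inverts one uniform draw through the
  cumulative fitness (inverse-transform); a guard returns the last
  survivor if floating roundoff pushes the target past the total. The
  dying individual is excluded from the lottery by default ("another
  individual reproduces"); a config switch (`lottery_excludes_dead`)
  preserves the inclusive alternative for sensitivity checks. In the
  inclusive corner where the dying individual is drawn (prob ≈ 1/N), the
  newborn wires to its parent's pre-removal neighborhood with p_n / p_r
  and has no certain parent link.
* **Adjacency** is a dense uint8 matrix; degrees are maintained
  incrementally and payoffs recomputed in O(N²) per event. At N = 100
  one event costs ~9 µs, so the million-event experiments below run in
  minutes on one core.
* **Payoffs** are double precision; the diluted benefit-conservation
  identity (Σu = B × #connected cooperators when C = D = C_link = 0)
  holds to ~1e−12 and is tested.
* **Assortment.** The primary measure is the neighbor-frequency
  difference A = f_C|C − f_C|D (mean cooperator fraction among
  cooperators' neighbors minus the same among defectors'), undefined
  (NaN) when either class has no member with degree ≥ 1; degree-0
  individuals are excluded from the class means. It directly expresses
  "cooperators benefit more from other cooperators". Newman's attribute
  assortativity is recorded alongside for robustness (verified against
  networkx).
* **Degenerate inputs.** Isolated individuals are allowed and earn only
  their costs; all-defector populations have exactly zero payoffs;
  trailing-window summaries are NaN-aware so undefined assortment
  records drop out of the averages.

## Problem sizes

The canonical long protocols (10⁵ generations with a trailing 8×10⁴
window) are supported but the package's presets and its own validation
runs use desk-scale versions: 500-generation fixed-trait grids
(trailing 400), 2000-generation coevolution runs with μ_l = 0.01 (which
reaches the collapse an order of magnitude sooner than μ_l = 0.001),
and 5000-generation rescue grids with trailing-80% averages. These
reproduce the directional phenomena — maintenance of cooperation at low
p_r, collapse under coevolution, rescue by link costs — with clear
margins; absolute long-run averages at exactly the canonical protocol
would require the full run lengths.

## Known limitations

* Dense-matrix storage costs O(N²) memory and per-event payoff work;
  fine up to a few thousand individuals, not engineered for much more.
* Payoffs are recomputed globally per event rather than incrementally;
  simplicity and exactness were preferred over the asymptotic saving.
* The inclusive-lottery variant is a sensitivity switch, not a fully
  specified alternative model (see the corner-case rule above).
* Only two strategies and time-constant games are supported; continuous
  cooperative investment, reciprocity, and partner choice are out of
  scope.
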