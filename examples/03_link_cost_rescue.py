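"""Costly social connections rescue cooperation — at a price.

Repeats the coevolution experiment with and without a per-link
maintenance cost C_link. The cost penalizes indiscriminate linking, so
p_r stays low and cooperation persists; but every individual pays for
its edges, so the rescued population is not necessarily fitter than the
collapsed one (a pyrrhic victory).
"""

from coopnet import EvoParams, GameParams, SimConfig, SweepSpec, run_grid

spec = SweepSpec(
    config=SimConfig(n=100, generations=2000, record_every=5, seed=3),
    game=GameParams(B=2.0, C=0.5, D=0.0, delta=0.1),
    evo=EvoParams(
        mu=0.001, mu_l=0.001, sigma_n=0.01, sigma_r=0.01,
        evolve_pn=True, evolve_pr=True, init_pn=0.5, init_pr=0.0001,
    ),
    axis1=("C_link", [0.0, 0.4]),
    replicates=5,
    tail=0.8,
)

table = run_grid(spec)
print(f"{'C_link':>6}  {'coop_freq':>9}  {'mean_pr':>8}  {'mean_fitness':>12}")
for _, row in table.iterrows():
    print(
        f"{row['C_link']:>6.1f}  {row['coop_freq_mean']:>9.3f}"
        f"  {row['mean_pr_mean']:>8.4f}  {row['mean_fitness_mean']:>12.4f}"
    )
print(
    "\nWith C_link = 0.4 random linking stays rare and cooperation is\n"
    "maintained; compare the mean fitness columns to see what the\n"
    "rescue costs the population."
)
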