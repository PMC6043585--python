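"""Inheritance, mutation, and the death-birth loop."""

import numpy as np
import pytest

from coopnet import (
    EvoParams,
    GameParams,
    SimConfig,
    evolution,
    initialize,
    mutate_traits,
    mutate_type,
    run,
    step,
)
from coopnet import _kernel


class TestMutateType:
    def test_degenerate_rates(self, rng):
        assert all(mutate_type(1, 0.0, rng) == 1 for _ in range(50))
        assert all(mutate_type(1, 1.0, rng) == 0 for _ in range(50))
        with pytest.raises(ValueError):
            mutate_type(2, 0.1, rng)

    def test_flip_rate(self, rng):
        mu, draws = 0.001, 1_000_000
        flips = 0
        one = np.int8(1)
        for _ in range(draws):
            flips += _kernel.mutate_type_draw(one, mu, rng) == 0
        se = np.sqrt(mu * (1 - mu) / draws)
        assert abs(flips / draws - mu) < 3 * se


class TestMutateTraits:
    def test_no_mutation_is_exact_copy(self, rng):
        evo = EvoParams(mu_l=0.0, evolve_pn=True, evolve_pr=True)
        assert mutate_traits(0.37, 0.002, evo, rng) == (0.37, 0.002)

    def test_non_evolving_traits_copied_verbatim(self, rng):
        evo = EvoParams(mu_l=1.0, sigma_n=0.5, sigma_r=0.5)
        assert mutate_traits(0.37, 0.002, evo, rng) == (0.37, 0.002)

    def test_boundary_clamp(self):
        # reproduce the exact Gaussian step with a cloned stream, then
        # verify the kernel clamps the out-of-range result to 1.0
        evo = EvoParams(mu_l=1.0, sigma_r=0.02, evolve_pr=True)
        probe = np.random.default_rng(77)
        probe.random()  # the mutate-or-not draw
        eps = probe.normal(0.0, evo.sigma_r)
        assume_out = 0.995 + eps
        rng = np.random.default_rng(77)
        _, new_r = mutate_traits(0.5, 0.995, evo, rng)
        if assume_out > 1.0:
            assert new_r == 1.0
        else:
            assert np.isclose(new_r, assume_out)
        # and clamping holds for arbitrarily large steps in both directions
        for seed in range(30):
            r = np.random.default_rng(seed)
            _, v = mutate_traits(0.5, 0.5, EvoParams(mu_l=1.0, sigma_r=10.0, evolve_pr=True), r)
            assert 0.0 <= v <= 1.0

    def test_gaussian_step_moments(self, rng):
        sigma, draws = 0.01, 100_000
        evo = EvoParams(mu_l=1.0, sigma_r=sigma, evolve_pr=True)
        steps = np.array([mutate_traits(0.5, 0.5, evo, rng)[1] - 0.5 for _ in range(draws)])
        se_sd = sigma / np.sqrt(2 * draws)
        assert abs(steps.std() - sigma) < 3 * se_sd
        assert abs(steps.mean()) < 3 * sigma / np.sqrt(draws)


class TestStep:
    def test_population_size_and_invariants(self, rng):
        cfg = SimConfig(n=30, generations=0, seed=3)
        state = initialize(cfg, GameParams(), EvoParams(), rng)
        for _ in range(200):
            step(state, GameParams(), EvoParams(), rng)
            assert state.n == 30
        state.validate()
        assert state.step_counter == 200

    def test_bit_identical_trajectories(self):
        cfg = SimConfig(n=40, generations=20, seed=99)
        game, evo = GameParams(), EvoParams(mu_l=0.01, evolve_pn=True, evolve_pr=True)
        a = run(cfg, game, evo)
        b = run(cfg, game, evo)
        assert a.equals(b)


class TestRun:
    def test_zero_generations_gives_initial_record(self):
        cfg = SimConfig(n=100, generations=0, seed=5)
        df = run(cfg, GameParams(), EvoParams())
        assert len(df) == 1
        assert df.loc[0, "generation"] == 0
        # binomial(100, 1/2) initialization
        assert abs(df.loc[0, "coop_freq"] - 0.5) < 3 * 0.05

    def test_record_grid(self):
        cfg = SimConfig(n=20, generations=10, record_every=3, seed=5)
        df = run(cfg, GameParams(), EvoParams())
        assert list(df["generation"]) == [0, 3, 6, 9, 10]

    def test_evolving_traits_individually_initialized(self):
        cfg = SimConfig(n=200, generations=0, seed=8)
        evo = EvoParams(evolve_pn=True, evolve_pr=True, sigma_n=0.05,
                        init_pn=0.5, init_pr=0.3)
        rng = np.random.default_rng(0)
        state = initialize(cfg, GameParams(), evo, rng)
        assert np.std(state.p_n) > 0.01  # drawn, not constant
        assert abs(np.mean(state.p_n) - 0.5) < 0.02
        assert ((state.p_n >= 0) & (state.p_n <= 1)).all()

    def test_fixed_traits_stay_fixed(self):
        cfg = SimConfig(n=30, generations=10, seed=2)
        df = run(cfg, GameParams(), EvoParams(init_pn=0.4, init_pr=0.02))
        assert np.allclose(df["mean_pn"], 0.4, rtol=0, atol=1e-15)
        assert np.allclose(df["mean_pr"], 0.02, rtol=0, atol=1e-15)

    def test_burn_in_density_insensitive_to_p0(self):
        """The 20-generation burn-in erases the initial ER density."""
        means = []
        for p0 in (0.05, 0.1, 0.5):
            vals = []
            for rep in range(5):
                cfg = SimConfig(n=100, p0=p0, generations=0, seed=100 + rep)
                st = initialize(cfg, GameParams(delta=0.0),
                                EvoParams(init_pn=0.5, init_pr=0.01),
                                np.random.default_rng(1000 * rep + int(p0 * 100)))
                vals.append(st.degrees.mean())
            means.append(np.mean(vals))
        spread = max(means) - min(means)
        assert spread < 0.5 * np.mean(means)

    def test_neutral_allele_martingale(self):
        """delta = 0, mu = 0: the expected change in cooperator count per
        generation is zero."""
        deltas = []
        game = GameParams(delta=0.0)
        evo = EvoParams(mu=0.0)
        for rep in range(100):
            cfg = SimConfig(n=50, generations=5, burn_in_generations=2,
                            seed=rep)
            df = run(cfg, game, evo)
            deltas.append(df["coop_freq"].iloc[-1] - df["coop_freq"].iloc[0])
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se

    def test_neutral_trait_random_walk_unbiased(self):
        """delta = 0 with evolving traits: mean p_n and p_r show no drift."""
        game = GameParams(delta=0.0)
        evo = EvoParams(mu=0.0, mu_l=0.1, sigma_n=0.05, sigma_r=0.05,
                        evolve_pn=True, evolve_pr=True,
                        init_pn=0.5, init_pr=0.5)
        dn, dr = [], []
        for rep in range(40):
            cfg = SimConfig(n=50, generations=50, burn_in_generations=2, seed=rep)
            df = run(cfg, game, evo)
            dn.append(df["mean_pn"].iloc[-1] - df["mean_pn"].iloc[0])
            dr.append(df["mean_pr"].iloc[-1] - df["mean_pr"].iloc[0])
        for d in (dn, dr):
            se = np.std(d, ddof=1) / np.sqrt(len(d))
            assert abs(np.mean(d)) < 3.5 * se


class TestRunToFixation:
    def test_requires_no_mutation(self):
        cfg = SimConfig(n=20, seed=0)
        with pytest.raises(ValueError):
            evolution.run_to_fixation(cfg, GameParams(), EvoParams(mu=0.001))

    def test_absorbs(self):
        cfg = SimConfig(n=20, seed=4)
        winner, gens = evolution.run_to_fixation(
            cfg, GameParams(delta=0.0), EvoParams(mu=0.0)
        )
        assert winner in (0, 1)
        assert gens >= 0


class TestInclusiveLottery:
    def test_runs_and_conserves(self):
        cfg = SimConfig(n=20, generations=20, seed=6, lottery_excludes_dead=False)
        df = run(cfg, GameParams(), EvoParams())
        assert len(df) == 21
        rng = np.random.default_rng(9)
        state = initialize(cfg, GameParams(), EvoParams(), rng)
        for _ in range(300):
            step(state, GameParams(), EvoParams(), rng, exclude_dead=False)
        state.validate()
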