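"""Unit and oracle tests for the K-allele Wright-Fisher engine."""

import numpy as np
import pytest
from scipy import stats

from chanevo.fitness import cliff
from chanevo.wrightfisher import (
    EvolutionConfig,
    ExtinctionError,
    LocusConfig,
    exact_transition_distribution,
    init_population,
    mutate,
    next_generation,
    phenotype,
    population_state,
    run_evolution,
    run_replicates,
)

NA = LocusConfig("g_na", 5.0, 12)
K = LocusConfig("g_k", 2.0, 9)


def config(loci=(NA,), fitness=None, n=100, gens=10, seed=7, **kw):
    return EvolutionConfig(
        loci=tuple(loci), fitness=fitness, n_individuals=n, generations=gens, seed=seed, **kw
    )


class TestInitPopulation:
    def test_centered_binomial_spread(self, rng):
        pop = init_population(config(n=20000), rng)
        # allele = 12 - 3 + Binomial(6, 1/2): mean 12, variance 1.5
        assert pop.shape == (1, 20000, 2)
        assert pop.mean() == pytest.approx(12.0, abs=0.05)
        assert pop.var() == pytest.approx(1.5, abs=0.05)

    def test_homozygote_phenotype_mapping(self):
        # potassium allele 18 on both copies -> 2 * (18+18) = 72? no:
        # step 2 mS/cm^2 per allele unit, summed over the two copies
        ph = phenotype(np.array([18, 18]), K, with_noise=False)
        assert ph == pytest.approx(72.0)
        ph_na = phenotype(np.array([12, 12]), NA, with_noise=False)
        assert ph_na == pytest.approx(120.0)

    def test_zero_spread_is_monomorphic(self, rng):
        locus = LocusConfig("g_na", 5.0, 12, init_spread_n=0)
        pop = init_population(config(loci=(locus,)), rng)
        assert np.all(pop == 12)

    def test_low_mean_clamps_at_zero(self, rng):
        locus = LocusConfig("g_na", 5.0, 1)
        pop = init_population(config(loci=(locus,), n=5000), rng)
        assert pop.min() >= 0


class TestMutate:
    def test_zero_rate_is_identity(self, rng):
        a = rng.integers(0, 20, size=(1000, 2))
        np.testing.assert_array_equal(mutate(a, 1e-12, 0.9, rng), a)

    def test_expected_displacement_matches_bias(self, rng):
        # E[step] = mu * (0.1 - 0.9) = -0.008 per allele per generation
        a = np.full(2_000_000, 10, dtype=np.int64)
        displacement = (mutate(a, 1e-2, 0.9, rng) - a).mean()
        se = np.sqrt(1e-2 / len(a))  # SD of one allele's step is ~sqrt(mu)
        assert displacement == pytest.approx(-0.008, abs=4 * se)

    def test_floor_is_absorbing(self, rng):
        a = np.zeros(200_000, dtype=np.int64)
        mutated = mutate(a, 0.5, 1.0 - 1e-12, rng)
        assert mutated.min() == 0


class TestPhenotype:
    def test_noise_standard_deviations(self, rng):
        # Na: 5 * sqrt(28/4) = 13.2; K: 2 * sqrt(16/4) = 4.0 mS/cm^2
        na = LocusConfig("g_na", 5.0, 12, noise_n=28)
        k = LocusConfig("g_k", 2.0, 9, noise_n=16)
        assert na.noise_sd == pytest.approx(13.2, abs=0.03)
        assert k.noise_sd == pytest.approx(4.0)
        alleles = np.full((200_000, 2), 12)
        ph = phenotype(alleles, na, rng)
        assert ph.std() == pytest.approx(13.2, abs=0.1)
        assert ph.mean() == pytest.approx(120.0, abs=0.15)

    def test_noise_clamps_at_zero(self, rng):
        locus = LocusConfig("g_na", 5.0, 0, noise_n=28)
        ph = phenotype(np.zeros((50_000, 2), dtype=int), locus, rng)
        assert ph.min() == 0.0

    def test_odd_noise_rejected(self):
        with pytest.raises(ValueError):
            LocusConfig("g_na", 5.0, 12, noise_n=7)


class TestNextGeneration:
    def test_population_size_and_allele_count_conserved(self, rng):
        cfg = config(n=500)
        pop = init_population(cfg, rng)
        new = next_generation(pop, cfg, rng)
        assert new.shape == pop.shape
        assert new.min() >= 0
        # 2N allele copies per locus, every generation
        assert new[0].size == 2 * cfg.n_individuals

    def test_neutral_mean_is_a_martingale(self):
        # without mutation or selection the mean phenotype drifts but its
        # expectation is constant: average over replicates stays put
        locus = LocusConfig("g_na", 5.0, 12)
        finals = []
        for seed in range(40):
            cfg = config(loci=(locus,), n=60, gens=30, seed=seed, mu=1e-9)
            finals.append(run_evolution(cfg).final_mean[0])
        finals = np.array(finals)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert finals.mean() == pytest.approx(120.0, abs=3.5 * se)

    def test_mutation_pressure_initial_decline(self):
        # with f = 1 each allele declines by ~mu(0.9-0.1) = 0.008 steps/gen;
        # the diploid sodium phenotype therefore falls by 5 * 2 * 0.008 =
        # 0.08 mS/cm^2 per generation
        cfg = config(n=5000, gens=200, seed=3)
        traj = run_evolution(cfg)
        slope = np.polyfit(np.arange(201), traj.mean[:, 0], 1)[0]
        assert slope == pytest.approx(-0.08, rel=0.15)

    def test_two_loci_inherited_independently(self, rng):
        # selection acting only on the sodium locus must not shift the
        # potassium locus beyond its neutral mutation pressure
        loci = (NA, K)
        f = lambda g_na, g_k: (g_na >= 100.0).astype(float)
        cfg_sel = config(loci=loci, fitness=f, n=2000, gens=100, seed=11)
        cfg_neutral = config(loci=loci, fitness=None, n=2000, gens=100, seed=11)
        final_sel = run_evolution(cfg_sel).final_mean
        final_neutral = run_evolution(cfg_neutral).final_mean
        assert final_sel[0] > final_neutral[0]  # selection holds Na up
        assert final_sel[1] == pytest.approx(final_neutral[1], abs=1.5)

    def test_extinction_raises(self, rng):
        cfg = config(n=4, fitness=lambda g: np.zeros_like(g))
        pop = init_population(cfg, rng)
        with pytest.raises(ExtinctionError):
            next_generation(pop, cfg, rng)


class TestRunEvolution:
    def test_seed_determinism(self):
        cfg = config(n=200, gens=50, fitness=cliff(81.0))
        a, b = run_evolution(cfg), run_evolution(cfg)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.final_population, b.final_population)

    def test_trajectory_length(self):
        traj = run_evolution(config(n=50, gens=25))
        assert traj.mean.shape == (26, 1)
        frame = traj.to_frame()
        assert list(frame.columns) == ["generation", "mean_g_na", "sd_g_na"]

    def test_replicates_use_distinct_seeds(self):
        cfg = config(n=100, gens=20)
        trajs = run_replicates(cfg, 3)
        finals = {t.final_mean[0] for t in trajs}
        assert len(finals) == 3


class TestCliffNoiseComposition:
    def test_survival_matches_binomial_tail(self, rng):
        # a genotype d conductance-units above a cliff survives noise with
        # probability P(Binom(N,1/2) >= N/2 - d/step): exact binomial tail
        locus = LocusConfig("g_na", 5.0, 12, noise_n=28)
        f = cliff(81.0)
        alleles = np.full((400_000, 2), 10)  # genotypic phenotype 100
        ph = phenotype(alleles, locus, rng)
        survival = f(ph).mean()
        d_steps = (100.0 - 81.0) / 5.0
        expected = stats.binom.sf(np.ceil(14.0 - d_steps) - 1, 28, 0.5)
        assert survival == pytest.approx(expected, abs=3e-3)


def _mc_vs_exact(counts, fitness, mu, bias, n_rep, seed, n=3):
    locus = LocusConfig("g_na", 5.0, 2)
    cfg = EvolutionConfig(
        loci=(locus,),
        fitness=fitness,
        n_individuals=n,
        mu=mu,
        down_bias=bias,
        generations=1,
        seed=seed,
    )
    exact = exact_transition_distribution(counts, cfg)
    pop = np.repeat(
        [v for v, c in sorted(counts.items()) for _ in range(c)], 1
    ).reshape(1, n, 2)
    rng = np.random.default_rng(seed)
    tally: dict = {}
    for _ in range(n_rep):
        new = next_generation(pop, cfg, rng)
        key = population_state(new[0])
        tally[key] = tally.get(key, 0) + 1
    for state, p in exact.items():
        freq = tally.get(state, 0) / n_rep
        se = np.sqrt(p * (1 - p) / n_rep)
        assert abs(freq - p) <= 3.0 * se + 2e-4, (state, freq, p)
    # no mass outside the exact support
    assert set(tally) <= set(exact)


class TestExactTransitionOracle:
    """The enumerated one-generation Markov transition is the oracle for the
    Monte-Carlo simulator at small population size."""

    def test_distribution_normalized(self):
        cfg = EvolutionConfig(loci=(NA,), fitness=None, n_individuals=3, seed=0)
        dist = exact_transition_distribution({1: 3, 2: 3}, cfg)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        # every state conserves the 2N allele copies
        assert all(sum(c for _, c in s) == 6 for s in dist)

    def test_neutral_no_mutation_reduces_to_pair_sampling(self):
        cfg = EvolutionConfig(
            loci=(NA,), fitness=None, n_individuals=2, mu=1e-15, seed=0
        )
        dist = exact_transition_distribution({0: 2, 1: 2}, cfg)
        # alleles can only be 0 or 1; the without-replacement pair draw has
        # the closed form P((0,0)) = (2/4)(1/3) = 1/6, P((1,1)) = 1/6,
        # P(mixed) = 2/3; two offspring convolve independently
        brute = {(0, 0): 1 / 6, (1, 1): 1 / 6, (0, 1): 2 / 3}
        conv = {}
        for p1, q1 in brute.items():
            for p2, q2 in brute.items():
                counts = {}
                for v in p1 + p2:
                    counts[v] = counts.get(v, 0) + 1
                key = tuple(sorted(counts.items()))
                conv[key] = conv.get(key, 0.0) + q1 * q2
        for state, p in conv.items():
            assert dist.get(state, 0.0) == pytest.approx(p, abs=1e-9)

    @pytest.mark.parametrize(
        "counts,fitness,mu,bias",
        [
            ({1: 3, 2: 3}, None, 1e-10, 0.9),  # neutral, no mutation
            ({1: 3, 2: 3}, None, 0.3, 0.9),  # strong biased mutation
            ({0: 2, 1: 4}, None, 0.3, 0.51), # floor behaviour at allele 0
            ({1: 3, 2: 3}, cliff(15.0), 0.2, 0.9),  # fitness cliff
            (
                {1: 2, 2: 2, 3: 2},
                lambda g: np.clip(np.asarray(g) / 40.0, 0, 1),
                0.2,
                0.8,
            ),  # graded fitness, three allele types
        ],
    )
    def test_monte_carlo_matches_enumeration(self, counts, fitness, mu, bias):
        _mc_vs_exact(counts, fitness, mu, bias, n_rep=100_000, seed=5)

    def test_impossible_fitness_raises(self):
        cfg = EvolutionConfig(
            loci=(NA,), fitness=lambda g: np.zeros_like(g), n_individuals=3, seed=0
        )
        with pytest.raises(ExtinctionError):
            exact_transition_distribution({1: 3, 2: 3}, cfg)
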