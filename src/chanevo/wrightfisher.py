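"""Diploid K-allele Wright-Fisher engine with biased stepwise mutation,
fitness-based rejection selection and binomial phenotypic noise.

Each locus summarizes the combined promoter/CRM strength of one channel gene
as a non-negative integer allele; a homozygote of allele ``n`` expresses
``2 n step`` mS/cm^2 of peak conductance (step = 5 for sodium, 2 for
potassium).  Generations are non-overlapping: each offspring draws two
distinct allele copies from the parental gamete pool (the pool is restored
between offspring), each copy mutates one step with probability ``mu``
(downward with probability ``down_bias``, floored at zero), the phenotype is
the summed allele strength times the step plus an optional zero-centered
binomial noise term, and the offspring survives with probability
``fitness(phenotype)``.  Rejected candidates are discarded entirely and the
draw repeats until N survivors are found.

Mutation is applied immediately before selection; because the pool is
restored between offspring this is equivalent to mutating during gamete
formation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LocusConfig",
    "EvolutionConfig",
    "Trajectory",
    "ExtinctionError",
    "init_population",
    "mutate",
    "phenotype",
    "next_generation",
    "run_evolution",
    "run_replicates",
    "exact_transition_distribution",
]

NA_ALLELE_STEP = 5.0  # mS/cm^2 of G_Na per sodium allele unit
K_ALLELE_STEP = 2.0  # mS/cm^2 of G_K per potassium allele unit


class ExtinctionError(RuntimeError):
    """The fitness function rejects essentially every reachable phenotype."""


@dataclass(frozen=True)
class LocusConfig:
    """One channel-expression locus.

    ``noise_n`` is the number of trials of the zero-centered binomial
    phenotypic-noise term (0 disables noise); it must be even so the noise
    is integer-centered.  The noise standard deviation in conductance units
    is ``step * sqrt(noise_n / 4)``.
    """

    name: str
    allele_step: float
    init_mean_allele: int
    noise_n: int = 0
    init_spread_n: int = 6  # Binomial(6, 0.5) initial allelic variation

    def __post_init__(self) -> None:
        if self.allele_step <= 0:
            raise ValueError("allele_step must be positive")
        if self.noise_n < 0 or self.noise_n % 2:
            raise ValueError("noise_n must be a non-negative even integer")
        if self.init_mean_allele < 0:
            raise ValueError("init_mean_allele must be non-negative")

    @property
    def noise_sd(self) -> float:
        """Phenotypic-noise S.D. in conductance units (mS/cm^2)."""
        return self.allele_step * np.sqrt(self.noise_n / 4.0)


@dataclass(frozen=True)
class EvolutionConfig:
    """Mutation/noise/selection settings governing one evolutionary run.

    ``fitness`` maps per-locus phenotype arrays to survival probabilities in
    [0, 1]: one array argument per locus, e.g. ``f(g_na)`` for a single-locus
    run or ``f(g_na, g_k)`` for a concurrent two-locus run.  ``None`` means
    no selection (f = 1).
    """

    loci: tuple[LocusConfig, ...]
    fitness: Callable[..., np.ndarray] | None = None
    n_individuals: int = 5000
    mu: float = 1e-2
    down_bias: float = 0.9
    generations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("at least one locus required")
        if not (0.0 < self.mu < 1.0):
            raise ValueError("mutation rate must lie in (0, 1)")
        if not (0.5 < self.down_bias < 1.0):
            raise ValueError("mutational bias must lie in (0.5, 1)")
        if self.n_individuals < 2:
            raise ValueError("population size must be at least 2")


@dataclass
class Trajectory:
    """Per-generation phenotype statistics of one run.

    ``mean`` and ``sd`` have shape (generations + 1, n_loci) and describe the
    genotypic phenotype (no noise; the noise term is zero-centered so the
    means coincide in expectation).
    """

    mean: np.ndarray
    sd: np.ndarray
    final_population: np.ndarray  # (n_loci, N, 2) allele values
    config: EvolutionConfig = field(repr=False, default=None)

    @property
    def final_mean(self) -> np.ndarray:
        return self.mean[-1]

    def equilibrium_mean(self, window: int = 1000) -> np.ndarray:
        """Time-averaged phenotype mean over the last ``window`` generations.

        At mutation-selection balance the population mean performs a slow
        random walk around the balance point (the restoring selection
        gradient is shallow), so a single-generation snapshot is a noisy
        estimator; averaging over the tail of the run is the stable one.
        """
        if window >= self.mean.shape[0]:
            raise ValueError("window longer than the recorded trajectory")
        return self.mean[-window:].mean(axis=0)

    def to_frame(self):
        import pandas as pd

        data = {"generation": np.arange(self.mean.shape[0])}
        for j, locus in enumerate(self.config.loci):
            data[f"mean_{locus.name}"] = self.mean[:, j]
            data[f"sd_{locus.name}"] = self.sd[:, j]
        return pd.DataFrame(data)


def init_population(config: EvolutionConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial diploid population, shape (n_loci, N, 2).

    Each allele is ``init_mean_allele - spread/2 + Binomial(spread, 0.5)``,
    clamped at zero, modelling pre-existing allelic variation centered on
    the starting mean.
    """
    n = config.n_individuals
    pop = np.empty((len(config.loci), n, 2), dtype=np.int64)
    for j, locus in enumerate(config.loci):
        s = locus.init_spread_n
        draws = rng.binomial(s, 0.5, size=(n, 2)) if s > 0 else np.full((n, 2), s // 2)
        pop[j] = np.maximum(locus.init_mean_allele - s // 2 + draws, 0)
    return pop


def mutate(
    alleles: np.ndarray, mu: float, down_bias: float, rng: np.random.Generator
) -> np.ndarray:
    """Mutate each allele independently: one step, biased downward.

    A down-mutation at allele 0 leaves 0 (absorbing floor); returns a new
    array.
    """
    hit = rng.random(alleles.shape) < mu
    down = rng.random(alleles.shape) < down_bias
    step = np.where(down, -1, 1)
    return np.where(hit, np.maximum(alleles + step, 0), alleles)


def phenotype(
    alleles: np.ndarray,
    locus: LocusConfig,
    rng: np.random.Generator | None = None,
    with_noise: bool = True,
) -> np.ndarray:
    """Conductance phenotype of diploid allele pairs, shape (..., 2) -> (...).

    ``step * (a1 + a2)`` plus, when the locus has noise and ``with_noise``,
    the zero-centered binomial term ``step * (Binomial(noise_n, 1/2) -
    noise_n/2)``; clamped at zero.
    """
    base = locus.allele_step * alleles.sum(axis=-1).astype(float)
    if with_noise and locus.noise_n:
        if rng is None:
            raise ValueError("rng required for noisy phenotypes")
        noise = rng.binomial(locus.noise_n, 0.5, size=base.shape) - locus.noise_n / 2.0
        base = base + locus.allele_step * noise
    return np.maximum(base, 0.0)


def _candidate_batch(
    pool: np.ndarray, m: int, config: EvolutionConfig, rng: np.random.Generator
):
    """Draw, mutate and phenotype ``m`` candidate offspring."""
    n_loci, two_n = pool.shape
    cand = np.empty((n_loci, m, 2), dtype=np.int64)
    for j in range(n_loci):
        i1 = rng.integers(0, two_n, size=m)
        i2 = rng.integers(0, two_n - 1, size=m)
        i2 = i2 + (i2 >= i1)  # second copy distinct from the first
        cand[j, :, 0] = pool[j, i1]
        cand[j, :, 1] = pool[j, i2]
    cand = mutate(cand, config.mu, config.down_bias, rng)
    phens = [
        phenotype(cand[j], locus, rng, with_noise=True)
        for j, locus in enumerate(config.loci)
    ]
    return cand, phens


def next_generation(
    pop: np.ndarray, config: EvolutionConfig, rng: np.random.Generator
) -> np.ndarray:
    """One full cycle: pair sampling, mutation, noisy phenotype, survival test.

    Candidates are drawn in vectorized batches; rejected candidates are
    discarded entirely and noise is redrawn on every retry.
    """
    n_loci, n, _ = pop.shape
    pool = pop.reshape(n_loci, 2 * n)
    out = np.empty_like(pop)
    filled = 0
    tried = 0
    accepted_total = 0
    while filled < n:
        m = max(256, int(1.25 * (n - filled)))
        cand, phens = _candidate_batch(pool, m, config, rng)
        if config.fitness is None:
            acc = np.ones(m, dtype=bool)
        else:
            f = np.asarray(config.fitness(*phens), dtype=float)
            acc = rng.random(m) < f
        idx = np.flatnonzero(acc)
        accepted_total += idx.size
        tried += m
        take = idx[: n - filled]
        out[:, filled : filled + take.size, :] = cand[:, take, :]
        filled += take.size
        if accepted_total == 0 and tried >= 1_000_000:
            raise ExtinctionError(
                "fewer than ~1e-6 of candidate offspring pass the fitness "
                "test; the fitness function is incompatible with reachable "
                "phenotypes"
            )
    return out


def _genotypic_stats(pop: np.ndarray, config: EvolutionConfig):
    means = np.empty(len(config.loci))
    sds = np.empty(len(config.loci))
    for j, locus in enumerate(config.loci):
        ph = phenotype(pop[j], locus, with_noise=False)
        means[j] = ph.mean()
        sds[j] = ph.std()
    return means, sds


def run_evolution(config: EvolutionConfig) -> Trajectory:
    """Iterate ``next_generation`` for the configured number of generations.

    Deterministic for a given config and seed.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng)
    g = config.generations
    mean = np.empty((g + 1, len(config.loci)))
    sd = np.empty_like(mean)
    mean[0], sd[0] = _genotypic_stats(pop, config)
    for t in range(1, g + 1):
        pop = next_generation(pop, config, rng)
        mean[t], sd[t] = _genotypic_stats(pop, config)
    return Trajectory(mean=mean, sd=sd, final_population=pop, config=config)


def run_replicates(
    config: EvolutionConfig, n_replicates: int, base_seed: int | None = None
) -> list[Trajectory]:
    """Independent replicate runs; replicate ``r`` uses seed ``base + r``."""
    base = config.seed if base_seed is None else base_seed
    out = []
    for r in range(n_replicates):
        cfg = EvolutionConfig(
            loci=config.loci,
            fitness=config.fitness,
            n_individuals=config.n_individuals,
            mu=config.mu,
            down_bias=config.down_bias,
            generations=config.generations,
            seed=base + r,
        )
        out.append(run_evolution(cfg))
    return out


# ---------------------------------------------------------------------------
# Exact one-generation transition distribution (small-population oracle)
# ---------------------------------------------------------------------------


def _mutation_outcomes(a: int, mu: float, bias: float):
    """Possible post-mutation values of allele ``a`` with probabilities."""
    down = max(a - 1, 0)
    out = {a: 1.0 - mu}
    out[down] = out.get(down, 0.0) + mu * bias
    out[a + 1] = out.get(a + 1, 0.0) + mu * (1.0 - bias)
    return out


def exact_transition_distribution(
    counts: dict[int, int],
    config: EvolutionConfig,
) -> dict[tuple[tuple[int, int], ...], float]:
    """Exact next-generation distribution for one locus, no noise.

    ``counts`` maps allele value -> copy count (summing to 2N).  Enumerates
    every ordered parental pair draw (two distinct copies, i != j), both
    mutation outcomes and the fitness acceptance, conditions on acceptance,
    and convolves N independent offspring into a distribution over
    allele-count states.  Keys are canonical sorted tuples of
    ``(allele_value, count)`` pairs; values sum to 1.

    Intended as the oracle for :func:`next_generation` at enumeration-
    tractable sizes (N <= 4, a handful of allele values).
    """
    if len(config.loci) != 1:
        raise ValueError("the exact oracle is defined for a single locus")
    locus = config.loci[0]
    if locus.noise_n:
        raise ValueError("the exact oracle assumes no phenotypic noise")
    n = config.n_individuals
    two_n = sum(counts.values())
    if two_n != 2 * n:
        raise ValueError("counts must sum to 2N")
    if n > 4 or len(counts) > 6:
        raise ValueError("state too large for exact enumeration")

    f = config.fitness or (lambda x: np.ones_like(np.asarray(x, dtype=float)))

    # Distribution of a single accepted offspring over unordered allele pairs.
    pair_prob: dict[tuple[int, int], float] = {}
    total = 0.0
    for i, mi in counts.items():
        for j, mj in counts.items():
            p_draw = (mi / two_n) * ((mj - (i == j)) / (two_n - 1))
            if p_draw <= 0:
                continue
            for i2, pi in _mutation_outcomes(i, config.mu, config.down_bias).items():
                for j2, pj in _mutation_outcomes(j, config.mu, config.down_bias).items():
                    w = float(f(np.array([locus.allele_step * (i2 + j2)]))[0])
                    p = p_draw * pi * pj * w
                    if p > 0:
                        key = (min(i2, j2), max(i2, j2))
                        pair_prob[key] = pair_prob.get(key, 0.0) + p
                        total += p
    if total <= 0:
        raise ExtinctionError("no candidate offspring can pass the fitness test")
    pair_prob = {k: v / total for k, v in pair_prob.items()}

    # Convolve N accepted offspring into allele-count states.
    states: dict[tuple[tuple[int, int], ...], float] = {(): 1.0}
    for _ in range(n):
        new: dict[tuple[tuple[int, int], ...], float] = {}
        for state, ps in states.items():
            acc = dict(state)
            for (a, b), pp in pair_prob.items():
                nxt = dict(acc)
                nxt[a] = nxt.get(a, 0) + 1
                nxt[b] = nxt.get(b, 0) + 1
                key = tuple(sorted(nxt.items()))
                new[key] = new.get(key, 0.0) + ps * pp
        states = new
    return states


def population_state(pop_locus: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Canonical allele-count state of one locus, comparable with the oracle."""
    vals, cnts = np.unique(pop_locus, return_counts=True)
    return tuple(sorted(zip(vals.tolist(), cnts.tolist())))
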