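"""Target-independent generation of candidate virtual binding sites.

For one miRNA, a genetic algorithm evolves length-N nucleotide strings
("virtual sites") under a duplex-energetics fitness function.  Individuals
are plain sequences; gaps and bulges arise only inside the duplex dynamic
program, never as explicit characters.  Three fitness variants are
available (lower = better, energies are negative):

* ``fitness0 = E_seed + E_13-16``
* ``fitness1 = E_duplex / (alpha*BU_seed + BU_out-seed + 1)``
* ``fitness2 = alpha*E_seed/(BU_seed+1) + E_out-seed/(BU_out-seed+1)``

Each generation produces 100 offspring by single-point crossover fixed at
position N-8 (so the seed-binding 3' block is inherited intact) followed
by per-position mutation at probability 0.2; the next parents are the
truncation-best of parents plus offspring (elitist), and evolution stops
once the best fitness has not improved for a couple of generations.  The
per-generation best sequences that beat the fitness of a reference
"complementary-seed" site form the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mirevo.core_seq import MiRNA, reverse_complement
from mirevo.duplex import DuplexResult, EnergyModel, hybridize

BASES = "ACGU"


@dataclass
class GAConfig:
    population_size: int = 10
    offspring_per_generation: int = 100
    mutation_prob: float = 0.2
    alpha: float = 2.0
    fitness_variant: int = 1
    stall_patience: int = 2
    max_generations: int = 200
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("mutation_prob must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.fitness_variant not in (0, 1, 2):
            raise ValueError("fitness_variant must be 0, 1 or 2")


@dataclass(frozen=True)
class VirtualSite:
    """A GA individual: a candidate mRNA-side binding sequence."""

    sequence: str
    fitness: float
    generation: int = 0


def fitness0(d: DuplexResult, alpha: float = 2.0) -> float:
    """Seed plus 13-16 energy contribution (alpha unused)."""
    return d.energy_seed + d.energy_13_16


def fitness1(d: DuplexResult, alpha: float = 2.0) -> float:
    """Duplex energy over the seed-weighted unpaired-base count."""
    return d.energy_duplex / (alpha * d.bu_seed + d.bu_out_seed + 1)


def fitness2(d: DuplexResult, alpha: float = 2.0) -> float:
    """Seed and out-seed energies, each over its own unpaired count."""
    return alpha * d.energy_seed / (d.bu_seed + 1) + d.energy_out_seed / (d.bu_out_seed + 1)


_FITNESS = {0: fitness0, 1: fitness1, 2: fitness2}


def evaluate_fitness(d: DuplexResult, cfg: GAConfig) -> float:
    return _FITNESS[cfg.fitness_variant](d, cfg.alpha)


def mutate(seq: str, mutation_prob: float, rng: np.random.Generator) -> str:
    """Per-position mutation: with probability p replace by a *different* base."""
    if mutation_prob == 0.0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < mutation_prob
    for i in np.flatnonzero(hits):
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def crossover(p1: str, p2: str) -> str:
    """Single-point crossover at position N-8: child keeps p2's 3' seed block."""
    if len(p1) != len(p2):
        raise ValueError("parents must have equal length")
    cut = len(p1) - 8
    return p1[:cut] + p2[cut:]


def truncation_select(pool: list[VirtualSite], k: int) -> list[VirtualSite]:
    """The k lowest-fitness individuals; ties broken by sequence then generation."""
    if not pool or k > len(pool):
        raise ValueError(f"cannot select {k} from pool of {len(pool)}")
    return sorted(pool, key=lambda v: (v.fitness, v.sequence, v.generation))[:k]


def reference_site(mirna: MiRNA) -> str:
    """The "complementary-seed" reference: perfect seed complement, inert filler.

    The seed-binding 3' block (last 8 nt) is the exact reverse complement of
    the miRNA seed; the out-seed block copies the miRNA's own out-seed bases
    (reversed to keep the alignment geometry), which cannot Watson-Crick
    pair with themselves.
    """
    return mirna.sequence[8:][::-1] + reverse_complement(mirna.sequence[:8])


def reference_fitness(mirna: MiRNA, model: EnergyModel, cfg: GAConfig) -> float:
    """Fitness of the complementary-seed reference site under cfg's variant."""
    d = hybridize(mirna, reference_site(mirna), model)
    return evaluate_fitness(d, cfg)


def run_ga(
    mirna: MiRNA,
    model: EnergyModel | None = None,
    cfg: GAConfig | None = None,
    initial_population: list[str] | None = None,
    return_history: bool = False,
) -> list[VirtualSite]:
    """Evolve the candidate virtual binding sites for one miRNA.

    Returns the deduplicated per-generation best sequences whose fitness is
    strictly better (lower) than the complementary-seed reference fitness,
    sorted by fitness.  Fully deterministic given ``cfg.rng_seed``.  With
    ``return_history`` the per-generation best fitness trace is returned as
    a second value.
    """
    model = model or EnergyModel()
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    n = mirna.n
    cache: dict[str, float] = {}

    def fit(seq: str) -> float:
        if seq not in cache:
            cache[seq] = evaluate_fitness(hybridize(mirna, seq, model), cfg)
        return cache[seq]

    if initial_population is None:
        pop_seqs = [
            "".join(BASES[b] for b in rng.integers(4, size=n))
            for _ in range(cfg.population_size)
        ]
    else:
        pop_seqs = list(initial_population)
    population = [VirtualSite(s, fit(s), 0) for s in pop_seqs]

    ref = reference_fitness(mirna, model, cfg)
    candidates: dict[str, VirtualSite] = {}
    best_so_far = INF = float("inf")
    stall = 0
    history = []
    for gen in range(1, cfg.max_generations + 1):
        offspring = []
        for _ in range(cfg.offspring_per_generation):
            i, j = rng.choice(len(population), size=2, replace=False)
            child = mutate(
                crossover(population[i].sequence, population[j].sequence),
                cfg.mutation_prob,
                rng,
            )
            offspring.append(VirtualSite(child, fit(child), gen))
        pool = population + offspring
        population = truncation_select(pool, cfg.population_size)
        gen_best = population[0]
        history.append(gen_best.fitness)
        if gen_best.sequence not in candidates:
            candidates[gen_best.sequence] = gen_best
        if gen_best.fitness < best_so_far:
            best_so_far = gen_best.fitness
            stall = 0
        else:
            stall += 1
            if stall >= cfg.stall_patience:
                break
    out = [v for v in candidates.values() if v.fitness < ref]
    out = sorted(out, key=lambda v: (v.fitness, v.sequence))
    if return_history:
        return out, history
    return out
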