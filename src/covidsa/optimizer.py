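"""Binary COVIDOA population search with simulated-annealing refinement.

COVIDOA is a population metaheuristic modelled on coronavirus replication:
a parent solution ("protein sequence") spawns frameshifted copies, which are
recombined into a new candidate ("virion") and mutated.  Here the algorithm
operates on bit-vectors (feature masks) and minimises a wrapper objective.
A simulated-annealing stage then refines the population optimum with
single-bit-flip moves under a geometric cooling schedule, which lets the
search escape local optima the elitist population update cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CovidoaParams",
    "SaParams",
    "Individual",
    "HybridResult",
    "sigmoid_transfer",
    "binarize",
    "repair",
    "roulette_select",
    "frameshift_replicate",
    "combine_proteins",
    "mutate",
    "covidoa_run",
    "cool_temperature",
    "sa_accept",
    "sa_neighbor",
    "sa_refine",
    "hybrid_run",
    "stage_rngs",
]

# Fitness callback contract: mask (uint8 array of 0/1) -> object with
# .fitness, .epsilon, .s_size attributes (see covidsa.fitness.FitnessBreakdown).
FitnessFn = Callable[[np.ndarray], object]

ROULETTE_DELTA = 1e-9  # keeps roulette weights positive when all fitnesses tie


@dataclass(frozen=True)
class CovidoaParams:
    """Configuration of the binary COVIDOA stage.

    Parameters
    ----------
    d : problem dimension (number of features).
    n_pop : population size.
    max_iter : number of generations.
    nop : number of frameshifted protein copies generated per parent before
        crossover merges them into one offspring.
    mr : per-position mutation rate, constrained to [0.005, 0.5].
    lb, ub : bounds for the real-valued seeding vectors that are binarized
        into the initial population; unused after initialization.
    invert_transfer : use the conventional binarization direction
        P(bit=1) = S(x) instead of the printed rule bit=1 iff rand >= S(x).
    """

    d: int
    n_pop: int = 20
    max_iter: int = 50
    nop: int = 2
    mr: float = 0.1
    lb: float = -1.0
    ub: float = 1.0
    invert_transfer: bool = False

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.n_pop < 1:
            raise ValueError(f"n_pop must be >= 1, got {self.n_pop}")
        if self.max_iter < 0:
            raise ValueError(f"max_iter must be >= 0, got {self.max_iter}")
        if self.nop < 1:
            raise ValueError(f"nop must be >= 1, got {self.nop}")
        if not 0.005 <= self.mr <= 0.5:
            raise ValueError(f"mr must lie in [0.005, 0.5], got {self.mr}")
        if not self.lb < self.ub:
            raise ValueError(f"lb must be < ub, got lb={self.lb}, ub={self.ub}")


@dataclass(frozen=True)
class SaParams:
    """Geometric cooling schedule: t <- t * cooling until t <= t_end.

    t0 <= t_end yields an empty schedule (zero refinement steps), which is a
    supported degenerate case used to disable the annealing stage.
    """

    t0: float = 1.0
    t_end: float = 1e-4
    cooling: float = 0.99

    def __post_init__(self) -> None:
        if self.t0 <= 0 or self.t_end <= 0:
            raise ValueError("temperatures must be positive")
        if not 0.0 < self.cooling < 1.0:
            raise ValueError(f"cooling rate must lie in (0, 1), got {self.cooling}")

    @property
    def n_steps(self) -> int:
        """Number of temperature steps before t falls to or below t_end."""
        if self.t0 <= self.t_end:
            return 0
        return math.ceil(math.log(self.t_end / self.t0) / math.log(self.cooling))


@dataclass(frozen=True, eq=False)
class Individual:
    """A candidate feature subset with its cached fitness breakdown."""

    bits: np.ndarray
    fitness: float
    error_rate: float
    subset_size: int

    def __post_init__(self) -> None:
        bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        if bits.ndim != 1 or not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must be a 1-D 0/1 vector")
        if int(bits.sum()) != self.subset_size:
            raise ValueError("subset_size does not match the number of set bits")

    @classmethod
    def evaluated(cls, bits: np.ndarray, fitness_fn: FitnessFn) -> "Individual":
        bits = np.ascontiguousarray(bits, dtype=np.uint8)
        bd = fitness_fn(bits)
        return cls(
            bits=bits,
            fitness=float(bd.fitness),
            error_rate=float(bd.epsilon),
            subset_size=int(bd.s_size),
        )


@dataclass(frozen=True)
class HybridResult:
    """Outcome of a COVIDOA run followed by SA refinement.

    ``covidoa_stage_best`` records the best fitness at the stage boundary, so
    the SA improvement is always ``covidoa_stage_best - best.fitness >= 0``.
    """

    best: Individual
    covidoa_trace: np.ndarray
    sa_trace: np.ndarray
    covidoa_stage_best: float
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def full_trace(self) -> np.ndarray:
        """Concatenated best-so-far trace across both stages."""
        return np.concatenate([self.covidoa_trace, self.sa_trace])

    def to_dict(self) -> dict:
        return {
            "best": {
                "bits": self.best.bits.tolist(),
                "fitness": self.best.fitness,
                "error_rate": self.best.error_rate,
                "subset_size": self.best.subset_size,
            },
            "covidoa_trace": [float(x) for x in self.covidoa_trace],
            "sa_trace": [float(x) for x in self.sa_trace],
            "covidoa_stage_best": self.covidoa_stage_best,
            "seed": self.seed,
            "config": self.config,
        }


def sigmoid_transfer(x):
    """Logistic transfer function S(x) = 1 / (1 + exp(-x)).

    Maps a real-valued solution component to a probability used for
    stochastic binarization.  Accepts scalars or arrays; rejects non-finite
    input.
    """
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("sigmoid_transfer requires finite input")
    out = 1.0 / (1.0 + np.exp(-arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def binarize(real_vector: np.ndarray, rng: np.random.Generator, invert: bool = False) -> np.ndarray:
    """Stochastically binarize a real vector through the logistic transfer.

    The default rule sets bit=1 when a fresh uniform draw is >= S(x), i.e.
    P(bit=1) = 1 - S(x).  With ``invert=True`` the conventional direction
    P(bit=1) = S(x) is used instead.  Only used to seed the initial binary
    population from uniform draws in [lb, ub].
    """
    s = sigmoid_transfer(np.asarray(real_vector, dtype=float))
    u = rng.random(np.shape(s))
    bits = (u < s) if invert else (u >= s)
    return bits.astype(np.uint8)


def repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ensure at least one set bit: empty masks get one uniformly chosen bit."""
    bits = np.ascontiguousarray(bits, dtype=np.uint8)
    if bits.sum() == 0:
        bits = bits.copy()
        bits[rng.integers(0, bits.size)] = 1
    return bits


def roulette_select(
    population: Sequence[Individual], rng: np.random.Generator, delta: float = ROULETTE_DELTA
) -> Individual:
    """Fitness-proportionate parent selection for a minimization objective.

    Weights are w_i = (f_max - f_i) + delta, so the lowest-fitness individual
    carries the largest weight and ties degrade to uniform sampling.
    """
    if len(population) == 0:
        raise ValueError("cannot select from an empty population")
    f = np.array([ind.fitness for ind in population], dtype=float)
    if not np.isfinite(f).all():
        raise ValueError("population contains non-finite fitness")
    w = (f.max() - f) + delta
    idx = rng.choice(len(population), p=w / w.sum())
    return population[idx]


def frameshift_replicate(
    parent: np.ndarray | Individual, nop: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Generate ``nop`` frameshifted protein copies of a parent mask.

    Each copy carries a fresh random bit in position 0 and the parent's
    positions 0..D-2 shifted one step to the right — the one-step frameshift
    in binary space.
    """
    if nop < 1:
        raise ValueError(f"nop must be >= 1, got {nop}")
    bits = parent.bits if isinstance(parent, Individual) else np.asarray(parent, dtype=np.uint8)
    proteins = []
    for _ in range(nop):
        p = np.empty_like(bits)
        p[0] = rng.integers(0, 2)
        p[1:] = bits[:-1]
        proteins.append(p)
    return proteins


def combine_proteins(proteins: Sequence[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    """Merge protein copies into one virion by pairwise uniform crossover.

    A single protein is returned as-is; otherwise proteins are folded
    left-to-right, each position drawn from either operand with
    probability 1/2.
    """
    if len(proteins) == 0:
        raise ValueError("no proteins to combine")
    d = len(proteins[0])
    if any(len(p) != d for p in proteins):
        raise ValueError("proteins must share a common length")
    out = np.asarray(proteins[0], dtype=np.uint8)
    for other in proteins[1:]:
        take = rng.random(d) < 0.5
        out = np.where(take, out, np.asarray(other, dtype=np.uint8)).astype(np.uint8)
    return out


def mutate(solution: np.ndarray, mr: float, rng: np.random.Generator) -> np.ndarray:
    """Replace each position with a fresh random bit with probability ``mr``."""
    if not 0.0 <= mr <= 1.0:
        raise ValueError(f"mutation rate must lie in [0, 1], got {mr}")
    bits = np.asarray(solution, dtype=np.uint8)
    hit = rng.random(bits.size) < mr
    fresh = rng.integers(0, 2, size=bits.size, dtype=np.uint8)
    return np.where(hit, fresh, bits).astype(np.uint8)


def _sorted_population(individuals: Sequence[Individual]) -> list[Individual]:
    # stable sort on fitness: insertion order breaks ties deterministically
    return sorted(individuals, key=lambda ind: ind.fitness)


def _init_population(
    params: CovidoaParams, fitness_fn: FitnessFn, rng: np.random.Generator
) -> list[Individual]:
    pop = []
    for _ in range(params.n_pop):
        x = rng.uniform(params.lb, params.ub, size=params.d)
        bits = repair(binarize(x, rng, invert=params.invert_transfer), rng)
        pop.append(Individual.evaluated(bits, fitness_fn))
    return _sorted_population(pop)


def covidoa_run(
    params: CovidoaParams, fitness_fn: FitnessFn, rng: np.random.Generator
) -> tuple[Individual, np.ndarray]:
    """Run the COVIDOA population loop.

    Each generation builds ``n_pop`` offspring (roulette parent -> frameshift
    replication -> protein crossover -> mutation -> empty-mask repair) and
    keeps the best ``n_pop`` of parents plus offspring, so the best-fitness
    trace is non-increasing.

    Returns the best individual and the per-iteration best-fitness trace
    (length ``max_iter``).
    """
    pop = _init_population(params, fitness_fn, rng)
    trace = np.empty(params.max_iter, dtype=float)
    for it in range(params.max_iter):
        offspring = []
        for _ in range(params.n_pop):
            parent = roulette_select(pop, rng)
            proteins = frameshift_replicate(parent, params.nop, rng)
            child = combine_proteins(proteins, rng)
            child = repair(mutate(child, params.mr, rng), rng)
            offspring.append(Individual.evaluated(child, fitness_fn))
        pop = _sorted_population(pop + offspring)[: params.n_pop]
        trace[it] = pop[0].fitness
    return pop[0], trace


def cool_temperature(t: float, cooling: float) -> float:
    """One geometric cooling step: returns t * cooling (< t)."""
    if t <= 0:
        raise ValueError(f"temperature must be positive, got {t}")
    if not 0.0 < cooling < 1.0:
        raise ValueError(f"cooling rate must lie in (0, 1), got {cooling}")
    return t * cooling


def sa_accept(delta_f: float, t: float, rng: np.random.Generator) -> bool:
    """Metropolis acceptance for minimization.

    A move that does not worsen the objective (delta_f <= 0) is always
    accepted; a worsening move is accepted with probability exp(-delta_f/t).
    """
    if t <= 0:
        raise ValueError(f"temperature must be positive, got {t}")
    if delta_f <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_f / t))


def sa_neighbor(solution: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flip one uniformly chosen bit, then repair an emptied mask."""
    bits = np.asarray(solution, dtype=np.uint8).copy()
    pos = rng.integers(0, bits.size)
    bits[pos] ^= 1
    return repair(bits, rng)


def sa_refine(
    initial: Individual, params: SaParams, fitness_fn: FitnessFn, rng: np.random.Generator
) -> tuple[Individual, np.ndarray]:
    """Simulated-annealing refinement of an already-evaluated solution.

    Current and best-so-far solutions are tracked separately so the walk can
    accept worsening moves without losing the optimum.  The trace records the
    best-so-far fitness at every temperature step and is non-increasing; the
    returned best never exceeds the initial fitness.
    """
    current = best = initial
    trace = []
    t = params.t0
    while t > params.t_end:
        cand_bits = sa_neighbor(current.bits, rng)
        cand = Individual.evaluated(cand_bits, fitness_fn)
        if sa_accept(cand.fitness - current.fitness, t, rng):
            current = cand
        if current.fitness < best.fitness:
            best = current
        t = cool_temperature(t, params.cooling)
        trace.append(best.fitness)
    return best, np.asarray(trace, dtype=float)


def stage_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Derive the per-stage random streams used by :func:`hybrid_run`.

    The COVIDOA and SA stages consume independent child streams of one seed
    sequence, so a COVIDOA-only run with the first stream is bit-identical to
    the COVIDOA stage inside the hybrid — enabling paired comparisons.
    """
    covid_ss, sa_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(covid_ss), np.random.default_rng(sa_ss)


def hybrid_run(
    c_params: CovidoaParams,
    s_params: SaParams,
    fitness_fn: FitnessFn,
    seed: int = 0,
) -> HybridResult:
    """COVIDOA global search followed by SA refinement of its optimum.

    The SA stage starts from the COVIDOA best instead of a random solution,
    so the final fitness can only match or improve the stage-boundary value.
    """
    covid_rng, sa_rng = stage_rngs(seed)
    covid_best, covid_trace = covidoa_run(c_params, fitness_fn, covid_rng)
    sa_best, sa_trace = sa_refine(covid_best, s_params, fitness_fn, sa_rng)
    return HybridResult(
        best=sa_best,
        covidoa_trace=covid_trace,
        sa_trace=sa_trace,
        covidoa_stage_best=covid_best.fitness,
        seed=int(seed),
        config={"covidoa": asdict(c_params), "sa": asdict(s_params)},
    )
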