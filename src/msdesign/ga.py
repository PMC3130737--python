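"""Elitist genetic algorithm over entity sequences.

Each generation carries the elite half of the population forward unchanged
and fills the rest with proposals: point mutants of uniformly chosen elite
parents (98% of proposals by default) and uniform per-position crossovers
of two distinct members of the previous population (2%).  Fitness is
memoised by sequence text; because packer seeds depend only on the sequence
text (not on evaluation order or count), the cache is semantics-preserving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fitness import FitnessProgram, evaluate_fitness
from .states import EntitySequence, StateSpec, evaluate_state
from .packing import InteractionGraph
from .util import rng_from

__all__ = ["GAParams", "GAHistory", "next_generation", "run_ga",
           "MultistateEvaluator"]

logger = logging.getLogger(__name__)

MUTATION_RETRIES = 100


@dataclass
class GAParams:
    population: int = 100
    elite: int = 50
    p_point: float = 0.98
    p_cross: float = 0.02
    generations: int | None = None      # None -> 15 * L
    allowed_aas: dict[int, str] | str = "ACDEFGHIKLMNPQRSTVWY"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.elite < self.population:
            raise ValueError("elite must be smaller than population")
        if abs(self.p_point + self.p_cross - 1.0) > 1e-12:
            raise ValueError("p_point + p_cross must equal 1")
        if self.generations is not None and self.generations < 1:
            raise ValueError("generations must be >= 1")

    def alphabet(self, position: int) -> str:
        """Allowed letters at a 1-based entity position."""
        if isinstance(self.allowed_aas, str):
            return self.allowed_aas
        return self.allowed_aas[position]

    def n_generations(self, L: int) -> int:
        return self.generations if self.generations is not None else 15 * L


@dataclass
class GAHistory:
    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_sequence: list[EntitySequence] = field(default_factory=list)
    cache_hits: int = 0
    cache_misses: int = 0


def _point_mutant(seq: EntitySequence, params: GAParams,
                  rng: np.random.Generator) -> EntitySequence:
    L = len(seq)
    for _ in range(MUTATION_RETRIES):
        pos = int(rng.integers(L)) + 1
        alphabet = [a for a in params.alphabet(pos) if a != seq[pos - 1]]
        if not alphabet:
            continue       # single-allowed-aa position: resample
        aa = alphabet[int(rng.integers(len(alphabet)))]
        return EntitySequence(seq[:pos - 1] + aa + seq[pos:])
    raise RuntimeError("no mutatable position found after bounded retries")


def _crossover(a: EntitySequence, b: EntitySequence,
               rng: np.random.Generator) -> EntitySequence:
    mask = rng.random(len(a)) < 0.5
    return EntitySequence("".join(x if m else y for x, y, m in zip(a, b, mask)))


def next_generation(population: list[tuple[EntitySequence, float]],
                    params: GAParams,
                    rng: np.random.Generator) -> list[EntitySequence]:
    """Propagate the elite unchanged; propose the rest by mutation/crossover."""
    if len(population) != params.population:
        raise ValueError("population size mismatch")
    ranked = sorted(population, key=lambda t: t[1])
    elite = [seq for seq, _ in ranked[:params.elite]]
    everyone = [seq for seq, _ in population]
    children: list[EntitySequence] = []
    while len(children) < params.population - params.elite:
        if rng.random() < params.p_point:
            parent = elite[int(rng.integers(len(elite)))]
            children.append(_point_mutant(parent, params, rng))
        else:
            i = int(rng.integers(len(everyone)))
            j = int(rng.integers(len(everyone) - 1))
            if j >= i:
                j += 1      # two distinct members
            children.append(_crossover(everyone[i], everyone[j], rng))
    return elite + children


def run_ga(evaluate: Callable[[EntitySequence], tuple[float, dict]],
           L: int, params: GAParams,
           initial: list[EntitySequence] | None = None,
           use_cache: bool = True,
           ) -> tuple[GAHistory, list[tuple[EntitySequence, float, dict]]]:
    """Run the GA; returns (history, final population ranked by fitness).

    ``evaluate`` maps a sequence to (fitness, details); details are carried
    into the final ranked population so per-state energies can be reported.
    """
    rng = rng_from(params.seed, "ga")
    history = GAHistory()
    cache: dict[str, tuple[float, dict]] = {}

    def fitness_of(seq: EntitySequence) -> tuple[float, dict]:
        key = str(seq)
        if use_cache and key in cache:
            history.cache_hits += 1
            return cache[key]
        history.cache_misses += 1
        value = evaluate(seq)
        if use_cache:
            cache[key] = value
        return value

    if initial is None:
        initial = []
    population_seqs = list(initial[:params.population])
    while len(population_seqs) < params.population:
        seq = "".join(
            params.alphabet(p)[int(rng.integers(len(params.alphabet(p))))]
            for p in range(1, L + 1))
        population_seqs.append(EntitySequence(seq))

    population = [(s, fitness_of(s)[0]) for s in population_seqs]
    n_gen = params.n_generations(L)
    for gen in range(n_gen):
        ranked = sorted(population, key=lambda t: t[1])
        history.best_fitness.append(ranked[0][1])
        history.mean_fitness.append(float(np.mean([f for _, f in population])))
        history.best_sequence.append(ranked[0][0])
        logger.debug("generation %d: best %.3f mean %.3f (%s)", gen,
                     history.best_fitness[-1], history.mean_fitness[-1],
                     ranked[0][0])
        seqs = next_generation(population, params, rng)
        population = [(s, fitness_of(s)[0]) for s in seqs]

    ranked = sorted(population, key=lambda t: t[1])
    history.best_fitness.append(ranked[0][1])
    history.mean_fitness.append(float(np.mean([f for _, f in population])))
    history.best_sequence.append(ranked[0][0])
    final = [(s, f, fitness_of(s)[1]) for s, f in ranked]
    return history, final


class MultistateEvaluator:
    """Bridges the GA to the states and the fitness program.

    Each fitness-program state variable is bound to one state (scalar) or a
    list of states (vector ensemble); every state of every variable is
    packed for each sequence and the energies fed to the program.  One
    interaction graph per state persists across sequences, so amino-acid
    pair submatrices are reused rather than recomputed.
    """

    def __init__(self, program: FitnessProgram,
                 bindings: dict[str, StateSpec | list[StateSpec]],
                 packer, global_seed: int, params=None,
                 memory_ceiling: int | None = None):
        self.program = program
        self.bindings = {
            name: [specs] if isinstance(specs, StateSpec) else list(specs)
            for name, specs in bindings.items()}
        self.packer = packer
        self.global_seed = global_seed
        self.params = params
        self._graphs: dict[int, InteractionGraph] = {}
        self._ceiling = memory_ceiling
        missing = (set(program.state_vars) - set(self.bindings))
        if missing:
            raise KeyError(f"unbound state variables: {sorted(missing)}")

    def _graph_for(self, spec: StateSpec) -> InteractionGraph:
        key = id(spec)
        if key not in self._graphs:
            self._graphs[key] = InteractionGraph.for_structure(
                spec.get_structure(), self.params, memory_ceiling=self._ceiling)
        return self._graphs[key]

    def graph_stats(self) -> dict[str, int]:
        return {
            "computed": sum(g.computed_count for g in self._graphs.values()),
            "accesses": sum(g.access_counter for g in self._graphs.values()),
            "evictions": sum(g.eviction_count for g in self._graphs.values()),
        }

    def __call__(self, seq: EntitySequence) -> tuple[float, dict]:
        energies: dict[str, object] = {}
        per_state: dict[str, float] = {}
        for var, specs in self.bindings.items():
            vals = []
            for spec in specs:
                e, _ = evaluate_state(spec, seq, spec.get_structure(),
                                      self.packer, self.global_seed,
                                      params=self.params,
                                      graph=self._graph_for(spec))
                vals.append(e)
                per_state[spec.name] = e
            energies[var] = vals if self.program.state_vars.get(var) == "vector" \
                else vals[0]
        fitness = evaluate_fitness(self.program, energies, seq)
        return fitness, {"state_energies": per_state,
                         "vector_energies": {k: list(np.atleast_1d(v))
                                             for k, v in energies.items()}}
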