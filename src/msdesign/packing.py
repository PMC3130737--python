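"""The packing problem and the lazily-computed interaction graph.

A :class:`PackingProblem` is what every rotamer optimizer consumes: an
ordered list of packable positions, one rotamer set per position (all of a
single amino acid, since the sequence is fixed during packing), one-body
energies against the fixed backbone, and a sparse symmetric pair-energy
provider.  Residues that are neither designable nor repackable contribute
only their backbone sphere: to the one-body energies of packable rotamers
and to a constant background energy.

Pair-energy submatrices are computed on first access and cached in an
:class:`InteractionGraph` keyed by (position, amino acid) pairs, so a
genetic-algorithm trajectory only ever pays for the amino-acid pairs its
sequences actually co-locate.  An optional memory ceiling is honoured by
evicting the submatrix whose most recent access is furthest in the past
(tracked with a binary heap); eviction is semantically invisible because
evicted submatrices are recomputed bit-identically on demand.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .energy import (
    Rotamer,
    ToyEnergyParams,
    backbone_pair_energy_matrix,
    build_rotamers,
    pair_energy_arrays,
)
from .structure import Structure

__all__ = [
    "PackingProblem",
    "RotamerAssignment",
    "InteractionGraph",
    "build_packing_problem",
    "total_energy",
    "random_problem",
    "dump_problem",
]

PosKey = tuple[str, int]

#: exact size accounting: 8 bytes per stored pair energy
BYTES_PER_ENTRY = 8


@dataclass
class RotamerAssignment:
    """One rotamer index per position, with its cached total energy."""

    choice: np.ndarray          # int array, one index per position
    energy: float

    def copy(self) -> "RotamerAssignment":
        return RotamerAssignment(self.choice.copy(), self.energy)


class InteractionGraph:
    """Lazy, memory-capped cache of amino-acid-pair energy submatrices.

    Keys are canonicalised so that ``submatrix(i, a, j, b)`` and
    ``submatrix(j, b, i, a)`` hit the same storage (the latter returns the
    transpose).  ``memory_ceiling`` is in bytes (8 per entry); ``None``
    means unlimited.
    """

    def __init__(self,
                 compute: Callable[[PosKey, str, PosKey, str], np.ndarray],
                 memory_ceiling: int | None = None):
        self._compute = compute
        self.memory_ceiling = memory_ceiling
        self._store: dict[tuple, np.ndarray] = {}
        self._last_access: dict[tuple, int] = {}
        self._heap: list[tuple[int, tuple]] = []
        self.access_counter = 0
        self.computed_count = 0
        self.eviction_count = 0
        self.stored_bytes = 0

    @classmethod
    def for_structure(cls, structure: Structure,
                      params: ToyEnergyParams | None = None,
                      memory_ceiling: int | None = None) -> "InteractionGraph":
        params = params or ToyEnergyParams()

        def compute(key_i: PosKey, aa_i: str, key_j: PosKey, aa_j: str) -> np.ndarray:
            rots_i = build_rotamers(structure, key_i, {aa_i}, params=params)
            rots_j = build_rotamers(structure, key_j, {aa_j}, params=params)
            return pair_energy_arrays(
                np.array([r.center for r in rots_i]),
                np.array([r.radius for r in rots_i]),
                np.array([r.hydrophobicity for r in rots_i]),
                np.array([r.center for r in rots_j]),
                np.array([r.radius for r in rots_j]),
                np.array([r.hydrophobicity for r in rots_j]),
                params,
            )

        return cls(compute, memory_ceiling=memory_ceiling)

    def submatrix(self, key_i: PosKey, aa_i: str, key_j: PosKey, aa_j: str) -> np.ndarray:
        """Pair-energy matrix, rows indexed by rotamers of (key_i, aa_i)."""
        if (key_j, aa_j) < (key_i, aa_i):
            return self.submatrix(key_j, aa_j, key_i, aa_i).T
        key = (key_i, aa_i, key_j, aa_j)
        self.access_counter += 1
        m = self._store.get(key)
        if m is None:
            m = np.ascontiguousarray(self._compute(key_i, aa_i, key_j, aa_j))
            self.computed_count += 1
            self._store[key] = m
            self.stored_bytes += m.size * BYTES_PER_ENTRY
        self._last_access[key] = self.access_counter
        heapq.heappush(self._heap, (self.access_counter, key))
        if self.memory_ceiling is not None:
            self._evict_to_ceiling(protect=key)
        return m

    def _evict_to_ceiling(self, protect: tuple) -> None:
        while self.stored_bytes > self.memory_ceiling:
            # least-recently-accessed live entry
            while self._heap:
                counter, key = heapq.heappop(self._heap)
                if self._last_access.get(key) == counter and key in self._store:
                    break
            else:
                return
            if key == protect:
                # never evict the matrix being handed to the caller
                heapq.heappush(self._heap, (counter, key))
                return
            m = self._store.pop(key)
            del self._last_access[key]
            self.stored_bytes -= m.size * BYTES_PER_ENTRY
            self.eviction_count += 1

    def __contains__(self, key: tuple) -> bool:
        return key in self._store


@dataclass
class PackingProblem:
    """Everything a rotamer optimizer needs, for one (state, sequence)."""

    positions: list[PosKey]
    rotamers: list[list[Rotamer]]
    one_body: list[np.ndarray]
    neighbor_pairs: set[tuple[int, int]]          # index pairs, i < j
    pair_lookup: Callable[[int, int], np.ndarray]  # (R_i, R_j) matrix
    background_energy: float = 0.0
    aas: list[str] = field(default_factory=list)   # amino acid at each position
    _pair_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if any(len(r) == 0 for r in self.rotamers):
            raise ValueError("every packable position needs at least one rotamer")
        if not self.aas:
            self.aas = [rots[0].aa for rots in self.rotamers]

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def rotamer_counts(self) -> list[int]:
        return [len(r) for r in self.rotamers]

    @property
    def total_rotamers(self) -> int:
        return sum(self.rotamer_counts)

    def pair(self, i: int, j: int) -> np.ndarray:
        """Pair matrix for position indices i, j (rows follow i's rotamers)."""
        if i < j:
            key = (i, j)
            m = self._pair_cache.get(key)
            if m is None:
                m = self.pair_lookup(i, j)
                self._pair_cache[key] = m
            return m
        return self.pair(j, i).T

    def neighbors_of(self, i: int) -> list[int]:
        out = []
        for a, b in self.neighbor_pairs:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)


def total_energy(problem: PackingProblem, assignment: RotamerAssignment) -> float:
    """Recompute the assignment's energy from scratch (the audit oracle)."""
    c = assignment.choice
    if len(c) != problem.n_positions:
        raise ValueError("assignment length mismatch")
    e = problem.background_energy
    for i, rots in enumerate(problem.rotamers):
        if not 0 <= c[i] < len(rots):
            raise ValueError(f"rotamer index {c[i]} out of range at position {i}")
        e += float(problem.one_body[i][c[i]])
    for i, j in problem.neighbor_pairs:
        e += float(problem.pair(i, j)[c[i], c[j]])
    return e


def build_packing_problem(spec, seq, structure: Structure,
                          params: ToyEnergyParams | None = None,
                          graph: InteractionGraph | None = None) -> PackingProblem:
    """Thread a sequence onto a state and assemble its packing problem.

    Correspondence-mapped residues carry rotamers only of the assigned amino
    acid; secondary-resfile residues repack at their wild-type identity; all
    other residues are reduced to fixed backbone spheres whose interactions
    are folded into the one-body terms and the background constant.
    """
    from .states import thread_sequence   # deferred: states imports packing

    params = params or ToyEnergyParams()
    if graph is None:
        graph = InteractionGraph.for_structure(structure, params)

    assigned, _ = thread_sequence(spec, seq, structure)
    packable: list[tuple[PosKey, str]] = []
    for res in structure.residues:
        if res.key in assigned:
            packable.append((res.key, assigned[res.key]))
        elif res.key in spec.secondary_repack:
            packable.append((res.key, res.wildtype_aa))

    positions = [key for key, _ in packable]
    aas = [aa for _, aa in packable]
    rotamers = [build_rotamers(structure, key, {aa}, params=params)
                for key, aa in packable]
    one_body = [backbone_pair_energy_matrix(rots, structure, params, exclude=key)
                for (key, _), rots in zip(packable, rotamers)]

    # neighbour pairs: rotamer spheres can only reach cutoff + both offsets
    anchors = np.array([structure.residue(key).anchor for key in positions]) \
        if positions else np.zeros((0, 3))
    reach = params.pair_cutoff + 2 * params.max_offset
    neighbor_pairs: set[tuple[int, int]] = set()
    for i in range(len(positions)):
        d = np.linalg.norm(anchors[i + 1:] - anchors[i], axis=1)
        for off in np.nonzero(d <= reach)[0]:
            neighbor_pairs.add((i, i + 1 + int(off)))

    background = _backbone_background_energy(structure, params)

    def pair_lookup(i: int, j: int) -> np.ndarray:
        return graph.submatrix(positions[i], aas[i], positions[j], aas[j])

    return PackingProblem(positions=positions, rotamers=rotamers,
                          one_body=one_body, neighbor_pairs=neighbor_pairs,
                          pair_lookup=pair_lookup, background_energy=background,
                          aas=aas)


def _backbone_background_energy(structure: Structure,
                                params: ToyEnergyParams) -> float:
    """Backbone-sphere / backbone-sphere energy summed over residue pairs.

    Backbone spheres act on each other as excluded volume only (the
    repulsive branch of the well); giving the fixed backbone an attractive
    tail would create a large sequence-independent association funnel that
    swamps the side-chain energetics every design decision rides on.
    """
    anchors = structure.anchors()
    n = len(anchors)
    if n < 2:
        return 0.0
    diff = anchors[:, None, :] - anchors[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2))
    np.fill_diagonal(d, np.inf)
    sigma = 2.0 * params.backbone_sphere_radius
    with np.errstate(over="ignore"):
        sd6 = (sigma / d) ** 6
        e = params.epsilon0 * (sd6 * sd6 - 2.0 * sd6)
    e[d > params.pair_cutoff] = 0.0
    np.maximum(e, 0.0, out=e)      # repulsive branch only
    return float(np.triu(e, k=1).sum())


def random_problem(n_positions: int, n_rotamers: int, seed: int,
                   neighbor_prob: float = 0.8, clash_prob: float = 0.08,
                   clash_energy: float = 25.0) -> PackingProblem:
    """A random abstract packing instance for optimizer benchmarking.

    One-body terms are Gaussian; pair matrices are Gaussian with sparse
    large positive entries emulating side-chain clashes, which is what makes
    the landscape rugged enough to separate the optimizers.
    """
    rng = np.random.default_rng(seed)
    positions = [("X", i + 1) for i in range(n_positions)]
    # placeholder geometry: energies come from the tables, not the spheres
    rotamers = [[Rotamer("A", k, np.array([1e6 * i, k, 0.0]), 1.0, 0.0)
                 for k in range(n_rotamers)] for i in range(n_positions)]
    one_body = [rng.normal(0.0, 2.0, n_rotamers) for _ in range(n_positions)]
    neighbor_pairs: set[tuple[int, int]] = set()
    matrices: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n_positions):
        for j in range(i + 1, n_positions):
            if rng.random() < neighbor_prob:
                m = rng.normal(0.0, 1.0, (n_rotamers, n_rotamers))
                clashes = rng.random((n_rotamers, n_rotamers)) < clash_prob
                m[clashes] += clash_energy
                neighbor_pairs.add((i, j))
                matrices[(i, j)] = m
    return PackingProblem(positions=positions, rotamers=rotamers,
                          one_body=one_body, neighbor_pairs=neighbor_pairs,
                          pair_lookup=lambda i, j: matrices[(i, j)])


def dump_problem(problem: PackingProblem) -> str:
    """Plain-text table of a problem (for golden tests and debugging)."""
    lines = [f"# background {problem.background_energy:.6f}",
             "# chain resnum aa n_rotamers one_body..."]
    for key, aa, rots, ob in zip(problem.positions, problem.aas,
                                 problem.rotamers, problem.one_body):
        obs = " ".join(f"{v:.6f}" for v in ob)
        lines.append(f"{key[0]} {key[1]} {aa} {len(rots)} {obs}")
    lines.append(f"# neighbor_pairs {sorted(problem.neighbor_pairs)}")
    return "\n".join(lines) + "\n"
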