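"""Rotamer-optimization algorithms.

Implements the full benchmark pool: the backbone-minimum-energy start
(BMEC), zero-temperature quenching, FASTER-style single-residue
perturbation/relaxation (sPR), the standard geometric-cooling annealer with
reheat-on-plateau, the multi-cool annealer with quench-and-restore
operations, hybrid shortened-annealing + sPR variants with restarts, and an
exhaustive enumeration oracle that returns the exact GMEC on small
instances.

All stochastic packers are deterministic given (problem, seed); every
packer's returned energy is its trace minimum and can never undercut the
exhaustive oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .packing import PackingProblem, RotamerAssignment
from .util import stable_mix

__all__ = [
    "AnnealSchedule",
    "PackerResult",
    "bmec",
    "quench",
    "pack_faster",
    "pack_standard_anneal",
    "pack_multicool",
    "pack_hybrid",
    "pack_exhaustive",
    "metropolis_accept",
    "get_packer",
    "PACKER_VARIANTS",
]

#: incremental-energy audit interval (substitutions between recomputations)
AUDIT_INTERVAL = 10_000

#: sPR relaxes at most this many neighbours of the perturbed residue
SPR_NEIGHBOR_LIMIT = 10
SPR_RELAX_PASSES = 10
SPR_MAX_SWEEPS = 30

EXHAUSTIVE_LIMIT = 10_000_000


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule for the standard annealer."""

    kT_high: float = 100.0
    kT_low: float = 0.3
    n_temps: int = 19
    moves_per_temp: int | None = None   # None -> 5 * total rotamer count

    def __post_init__(self) -> None:
        if not (self.kT_high > self.kT_low > 0):
            raise ValueError("need kT_high > kT_low > 0")
        if self.n_temps < 2:
            raise ValueError("need at least two temperatures")
        if self.moves_per_temp is not None and self.moves_per_temp < 1:
            raise ValueError("moves_per_temp must be >= 1")

    @property
    def factor(self) -> float:
        return (self.kT_low / self.kT_high) ** (1.0 / (self.n_temps - 1))

    def moves(self, problem: PackingProblem) -> int:
        if self.moves_per_temp is not None:
            return self.moves_per_temp
        return 5 * problem.total_rotamers


@dataclass
class PackerResult:
    assignment: RotamerAssignment
    energy: float
    moves_attempted: int = 0
    quench_restores: int = 0
    best_trace: list[tuple[int, float]] = field(default_factory=list)
    stats: dict = field(default_factory=dict)


def metropolis_accept(delta_e: float, kT: float, u: float) -> bool:
    """Metropolis criterion: accept downhill, else with prob exp(-dE/kT)."""
    if delta_e <= 0.0:
        return True
    return u < math.exp(-delta_e / kT)


class _View:
    """Dense per-problem working arrays for the optimizers."""

    def __init__(self, problem: PackingProblem):
        self.problem = problem
        self.n = problem.n_positions
        self.one_body = [np.asarray(ob, float) for ob in problem.one_body]
        self.nrot = problem.rotamer_counts
        # neighbors[i] = list of (j, M) with M shape (R_i, R_j)
        self.neighbors: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(self.n)]
        for i, j in sorted(problem.neighbor_pairs):
            m = problem.pair(i, j)
            self.neighbors[i].append((j, m))
            self.neighbors[j].append((i, m.T))
        # flattened rotamer index -> (position, rotamer) for random moves
        self.flat = [(i, r) for i in range(self.n) for r in range(self.nrot[i])]
        self.substitutions = 0

    def local_vector(self, i: int, choice: np.ndarray) -> np.ndarray:
        """Energy of every rotamer at i against the current context."""
        v = self.one_body[i].copy()
        for j, m in self.neighbors[i]:
            v += m[:, choice[j]]
        return v

    def energy(self, choice: np.ndarray) -> float:
        e = self.problem.background_energy
        for i in range(self.n):
            e += float(self.one_body[i][choice[i]])
        for i, j in self.problem.neighbor_pairs:
            e += float(self.problem.pair(i, j)[choice[i], choice[j]])
        return e

    def maybe_audit(self, choice: np.ndarray, energy: float) -> float:
        """Periodically replace the incrementally-tracked energy."""
        if self.substitutions and self.substitutions % AUDIT_INTERVAL == 0:
            return self.energy(choice)
        return energy


def bmec(problem: PackingProblem) -> RotamerAssignment:
    """Backbone-minimum-energy conformation: per-position argmin one-body.

    Ties break to the lowest rotamer index.
    """
    view = _View(problem)
    choice = np.array([int(np.argmin(ob)) for ob in view.one_body], dtype=int)
    return RotamerAssignment(choice, view.energy(choice))


def _quench(view: _View, choice: np.ndarray, energy: float) -> float:
    """In-place zero-temperature sweeps; returns the new energy."""
    while True:
        accepted = False
        for i in range(view.n):
            v = view.local_vector(i, choice)
            best = int(np.argmin(v))
            if v[best] < v[choice[i]]:
                energy += float(v[best] - v[choice[i]])
                choice[i] = best
                accepted = True
                view.substitutions += 1
                energy = view.maybe_audit(choice, energy)
        if not accepted:
            return energy


def quench(problem: PackingProblem, start: RotamerAssignment) -> RotamerAssignment:
    """Accept only strictly energy-lowering single substitutions until none remain."""
    view = _View(problem)
    choice = start.choice.copy()
    energy = _quench(view, choice, view.energy(choice))
    return RotamerAssignment(choice, energy)


def _spr_sweeps(view: _View, choice: np.ndarray, energy: float,
                max_sweeps: int = SPR_MAX_SWEEPS) -> tuple[float, int]:
    """FASTER single-residue perturbation/relaxation until convergence.

    For each (position, rotamer): tentatively fix the rotamer, relax the
    <=10 neighbours with the greatest-magnitude interaction with the
    perturbed rotamer (repeated single-residue optimal passes), and accept
    the whole perturbation only if the net energy strictly decreases.
    """
    moves = 0
    for _ in range(max_sweeps):
        accepted_any = False
        for i in range(view.n):
            for r in range(view.nrot[i]):
                if r == choice[i]:
                    continue
                moves += 1
                saved_choice = choice.copy()
                saved_energy = energy
                v = view.local_vector(i, choice)
                energy += float(v[r] - v[choice[i]])
                choice[i] = r
                # neighbours with greatest |interaction| with the new rotamer
                strengths = [(abs(float(m[r, choice[j]])), j)
                             for j, m in view.neighbors[i]]
                strengths.sort(key=lambda t: (-t[0], t[1]))
                relax_set = [j for _, j in strengths[:SPR_NEIGHBOR_LIMIT]]
                for _ in range(SPR_RELAX_PASSES):
                    changed = False
                    for j in relax_set:
                        vj = view.local_vector(j, choice)
                        best = int(np.argmin(vj))
                        if vj[best] < vj[choice[j]]:
                            energy += float(vj[best] - vj[choice[j]])
                            choice[j] = best
                            changed = True
                    if not changed:
                        break
                if energy < saved_energy:
                    accepted_any = True
                    view.substitutions += 1
                    energy = view.maybe_audit(choice, energy)
                else:
                    choice[:] = saved_choice
                    energy = saved_energy
        if not accepted_any:
            break
    return energy, moves


def pack_faster(problem: PackingProblem, seed: int | None = None) -> PackerResult:
    """BMEC start followed by iterative sPR until convergence (deterministic)."""
    view = _View(problem)
    start = bmec(problem)
    choice = start.choice.copy()
    energy, moves = _spr_sweeps(view, choice, start.energy)
    trace = [(0, start.energy), (moves, energy)]
    return PackerResult(RotamerAssignment(choice, energy), energy,
                        moves_attempted=moves, best_trace=trace)


def _anneal_core(view: _View, choice: np.ndarray, energy: float,
                 rng: np.random.Generator, schedule: AnnealSchedule,
                 moves_per_temp: int, best: RotamerAssignment,
                 trace: list[tuple[int, float]], move_offset: int = 0,
                 ) -> tuple[float, int]:
    """Standard-annealer temperature loop with reheat-on-plateau."""
    kT = schedule.kT_high
    finals: list[float] = []
    moves = 0
    for _ in range(schedule.n_temps):
        for _ in range(moves_per_temp):
            moves += 1
            i, r = view.flat[rng.integers(len(view.flat))]
            if r == choice[i]:
                continue
            v = view.local_vector(i, choice)
            de = float(v[r] - v[choice[i]])
            if metropolis_accept(de, kT, float(rng.random())):
                energy += de
                choice[i] = r
                view.substitutions += 1
                energy = view.maybe_audit(choice, energy)
                if energy < best.energy:
                    best.choice[:] = choice
                    best.energy = energy
                    trace.append((move_offset + moves, energy))
        finals.append(energy)
        if len(finals) >= 4 and finals[-1] > np.mean(finals[-4:-1]) - 1.0:
            kT = schedule.kT_high      # plateau: reheat and cool again
        else:
            kT *= schedule.factor
    return energy, moves


def pack_standard_anneal(problem: PackingProblem, seed: int,
                         schedule: AnnealSchedule | None = None) -> PackerResult:
    """Geometric cooling kT 100 -> 0.3 over 19 temperature iterations.

    A plateau in the per-iteration final energies (not more than 1 REU
    below the mean of the previous three) triggers a reheat to the top
    temperature.  After the loop the best-so-far assignment is restored and
    quenched; the overall best is returned.
    """
    schedule = schedule or AnnealSchedule()
    view = _View(problem)
    rng = np.random.default_rng(seed)
    choice = np.array([int(rng.integers(n)) for n in view.nrot], dtype=int)
    energy = view.energy(choice)
    best = RotamerAssignment(choice.copy(), energy)
    trace = [(0, energy)]
    moves_per_temp = schedule.moves(problem)
    energy, moves = _anneal_core(view, choice, energy, rng, schedule,
                                 moves_per_temp, best, trace)
    # restore best-so-far, then quench
    choice[:] = best.choice
    energy = _quench(view, choice, best.energy)
    if energy < best.energy:
        best = RotamerAssignment(choice.copy(), energy)
        trace.append((moves, energy))
    return PackerResult(best, best.energy, moves_attempted=moves, best_trace=trace)


def pack_multicool(problem: PackingProblem, seed: int,
                   moves_per_temp: int | None = None) -> PackerResult:
    """The multi-cool annealer.

    Phase 1 cools geometrically kT 10 -> 0.2 over 20 iterations, performing
    quench-and-restore three times inside each fixed-temperature block
    (sixty in total) and remembering the 10 lowest-energy quenched
    assignments.  Phase 2 runs six cooling trajectories kT 0.25 -> 0.05
    (10 temperatures, quench-and-restore after each) started from the best
    six saved assignments in energy order.
    """
    import logging

    view = _View(problem)
    rng = np.random.default_rng(seed)
    M = moves_per_temp if moves_per_temp is not None else 5 * problem.total_rotamers
    choice = np.array([int(rng.integers(n)) for n in view.nrot], dtype=int)
    energy = view.energy(choice)
    best = RotamerAssignment(choice.copy(), energy)
    trace = [(0, energy)]
    moves = 0
    quench_restores = 0
    saved: list[tuple[float, np.ndarray]] = []   # 10 lowest-energy quenched

    def quench_and_restore(cur_energy: float) -> float:
        """Quench a copy of the current assignment, save it, restore."""
        nonlocal quench_restores
        quench_restores += 1
        pre = choice.copy()
        q_energy = _quench(view, choice, cur_energy)
        if q_energy < best.energy:
            best.choice[:] = choice
            best.energy = q_energy
            trace.append((moves, q_energy))
        saved.append((q_energy, choice.copy()))
        saved.sort(key=lambda t: t[0])
        del saved[10:]
        choice[:] = pre
        return cur_energy

    def metropolis_block(kT: float, n_moves: int, quench_marks: set[int]) -> None:
        nonlocal energy, moves
        for m in range(n_moves):
            if m in quench_marks:
                energy = quench_and_restore(energy)
            moves += 1
            i, r = view.flat[rng.integers(len(view.flat))]
            if r == choice[i]:
                continue
            v = view.local_vector(i, choice)
            de = float(v[r] - v[choice[i]])
            if metropolis_accept(de, kT, float(rng.random())):
                energy += de
                choice[i] = r
                view.substitutions += 1
                energy = view.maybe_audit(choice, energy)
                if energy < best.energy:
                    best.choice[:] = choice
                    best.energy = energy
                    trace.append((moves, energy))

    # phase 1: kT 10 -> 0.2 over 20 iterations, 3 quench-and-restores each
    factor1 = (0.2 / 10.0) ** (1.0 / 19.0)
    kT = 10.0
    marks = {M // 4, M // 2, (3 * M) // 4}
    for _ in range(20):
        metropolis_block(kT, M, marks)
        kT *= factor1
    phase1_quench_restores = quench_restores
    starts = [(e, c.copy()) for e, c in saved]   # phase-1 snapshot

    # phase 2: six trajectories kT 0.25 -> 0.05, from the best six saved
    if len(starts) < 6:
        logging.getLogger(__name__).warning(
            "multicool: only %d quenched assignments saved; reusing the best",
            len(starts))
    factor2 = (0.05 / 0.25) ** (1.0 / 9.0)
    for t in range(6):
        start_energy, start_choice = starts[min(t, len(starts) - 1)] if starts \
            else (best.energy, best.choice)
        choice[:] = start_choice
        energy = start_energy
        kT = 0.25
        for _ in range(10):
            metropolis_block(kT, M, set())
            energy = quench_and_restore(energy)
            kT *= factor2

    result = RotamerAssignment(best.choice.copy(), best.energy)
    return PackerResult(result, best.energy, moves_attempted=moves,
                        quench_restores=quench_restores, best_trace=trace,
                        stats={"phase1_quench_restores": phase1_quench_restores})


def pack_hybrid(problem: PackingProblem, seed: int, fraction: float = 0.05,
                restarts: int = 1,
                schedule: AnnealSchedule | None = None) -> PackerResult:
    """N x (p% SimA + sPR): shortened annealing then sPR, best over restarts.

    Restart r runs the standard-annealer schedule with moves_per_temp scaled
    by ``fraction`` under seed ``stable_mix(seed, r)``, then sPR sweeps to
    convergence.
    """
    if not (0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    schedule = schedule or AnnealSchedule()
    base_moves = schedule.moves(problem)
    scaled = AnnealSchedule(schedule.kT_high, schedule.kT_low, schedule.n_temps,
                            max(1, round(fraction * base_moves)))
    best: PackerResult | None = None
    total_moves = 0
    trace: list[tuple[int, float]] = []
    for r in range(restarts):
        sub_seed = stable_mix(seed, r)
        res = pack_standard_anneal(problem, sub_seed, scaled)
        view = _View(problem)
        choice = res.assignment.choice.copy()
        energy, spr_moves = _spr_sweeps(view, choice, res.assignment.energy)
        total_moves += res.moves_attempted + spr_moves
        if best is None or energy < best.energy:
            best = PackerResult(RotamerAssignment(choice, energy), energy)
            trace.append((total_moves, energy))
    assert best is not None
    best.moves_attempted = total_moves
    best.best_trace = trace
    return best


def pack_exhaustive(problem: PackingProblem) -> RotamerAssignment:
    """Exact GMEC by full enumeration (broadcast over the assignment tensor).

    Ties break lexicographically on the choice vector.  Raises if the state
    space exceeds 10^7 assignments.
    """
    counts = problem.rotamer_counts
    size = math.prod(counts)
    if size > EXHAUSTIVE_LIMIT:
        raise ValueError(f"state space too large for enumeration: {size}")
    n = problem.n_positions
    energy = np.full(counts, problem.background_energy)
    for i, ob in enumerate(problem.one_body):
        shape = [1] * n
        shape[i] = counts[i]
        energy = energy + np.asarray(ob).reshape(shape)
    for i, j in sorted(problem.neighbor_pairs):
        m = problem.pair(i, j)
        shape = [1] * n
        shape[i] = counts[i]
        shape[j] = counts[j]
        energy = energy + m.reshape(shape)
    flat_idx = int(np.argmin(energy))      # C order -> lexicographic tie-break
    choice = np.array(np.unravel_index(flat_idx, counts), dtype=int)
    return RotamerAssignment(choice, float(energy.flat[flat_idx]))


def _variant(fraction: float, restarts: int):
    def run(problem: PackingProblem, seed: int) -> PackerResult:
        return pack_hybrid(problem, seed, fraction=fraction, restarts=restarts)
    return run


#: the fifteen benchmark algorithm variants, by their conventional names
PACKER_VARIANTS: dict[str, object] = {
    "standard_annealer": lambda p, s: pack_standard_anneal(p, s),
    "multicool_annealer": lambda p, s: pack_multicool(p, s),
    "100%SimA+sPR": _variant(1.0, 1),
    "50%SimA+sPR": _variant(0.5, 1),
    "20%SimA+sPR": _variant(0.2, 1),
    "10%SimA+sPR": _variant(0.1, 1),
    "8x(5%SimA+sPR)": _variant(0.05, 8),
    "4x(5%SimA+sPR)": _variant(0.05, 4),
    "2x(5%SimA+sPR)": _variant(0.05, 2),
    "5%SimA+sPR": _variant(0.05, 1),
    "8x(2.5%SimA+sPR)": _variant(0.025, 8),
    "4x(2.5%SimA+sPR)": _variant(0.025, 4),
    "2x(2.5%SimA+sPR)": _variant(0.025, 2),
    "2.5%SimA+sPR": _variant(0.025, 1),
    "BMEC+sPR": lambda p, s: pack_faster(p, s),
}


def get_packer(name: str):
    """Look up a packer by name (any PACKER_VARIANTS key, or 'exhaustive')."""
    if name == "exhaustive":
        def run(problem: PackingProblem, seed: int) -> PackerResult:
            a = pack_exhaustive(problem)
            return PackerResult(a, a.energy)
        return run
    try:
        return PACKER_VARIANTS[name]
    except KeyError:
        raise KeyError(f"unknown packer {name!r}; known: "
                       f"{sorted(PACKER_VARIANTS)} + ['exhaustive']") from None
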