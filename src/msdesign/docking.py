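"""Toy rigid-body redocking and matched-backbone binding energies.

The docking protocol mirrors the perturb-then-refine scheme used to relax
designed complexes: each trajectory starts from the input conformation,
splits and repacks the chains separately, applies a small random rigid-body
perturbation to the mobile chain, and runs Monte-Carlo refinement cycles
(smaller perturbation, interface repack, Metropolis acceptance).  The best
of ``n_traj`` trajectories by total energy is returned along with its
binding energy.

Binding energies are always matched-backbone: the monomer energies are
computed on chains extracted from the very dimer conformation being scored,
so the difference isolates the interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .energy import ToyEnergyParams
from .optimizers import metropolis_accept, pack_faster
from .packing import build_packing_problem
from .states import CorrespondenceMap, EntitySequence, StateSpec
from .structure import Structure, rms_no_superposition
from .util import rng_from

__all__ = ["RigidTransform", "DockResult", "dock_pert", "binding_energy",
           "filter_conformations", "split_state_spec"]

logger = logging.getLogger(__name__)

DEFAULT_TRANS_SD = 3.0     # Angstrom
DEFAULT_ROT_SD = 8.0       # degrees
REFINE_CYCLES = 50
REFINE_SCALE = 0.2
REFINE_KT = 0.8


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation, applied about a pivot."""

    rotation: np.ndarray       # (3, 3), det +1
    translation: np.ndarray    # (3,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(cls, rng: np.random.Generator, trans_sd: float,
               rot_sd_deg: float) -> "RigidTransform":
        """Per-axis normal translation; random-axis rotation of normal magnitude."""
        translation = rng.normal(0.0, trans_sd, 3) if trans_sd > 0 else np.zeros(3)
        if rot_sd_deg > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.normal(0.0, rot_sd_deg))
            rotation = Rotation.from_rotvec(angle * axis).as_matrix()
        else:
            rotation = np.eye(3)
        return cls(rotation, translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self applied after other (about the same pivot)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass
class DockResult:
    transform: RigidTransform
    total_energy: float
    binding_energy: float
    conformation: Structure


def split_state_spec(spec: StateSpec, chain_id: str) -> StateSpec:
    """Restrict a dimer state to one chain (for matched-backbone monomers)."""
    entries = tuple(e for e in spec.correspondence.entries if e[1] == chain_id)
    corr = CorrespondenceMap(entries, spec.correspondence.entity_length)
    secondary = {k for k in spec.secondary_repack if k[0] == chain_id}
    return StateSpec(f"{spec.name}/{chain_id}", corr, secondary,
                     replicates=spec.replicates)


def _packed_energy(spec: StateSpec, seq: EntitySequence, structure: Structure,
                   packer, seed: int, params: ToyEnergyParams | None) -> float:
    problem = build_packing_problem(spec, seq, structure, params=params)
    if problem.n_positions == 0:
        return problem.background_energy
    return packer(problem, seed).energy


def binding_energy(spec: StateSpec, seq: EntitySequence, dimer: Structure,
                   packer=pack_faster, seed: int = 0,
                   params: ToyEnergyParams | None = None) -> float:
    """Matched-backbone binding energy of a two-chain complex.

    dG = E(bound, packed) - E(chain 1 alone, packed) - E(chain 2 alone,
    packed); the monomer backbones are extracted from the dimer itself and
    all three species carry the same threaded sequence.
    """
    if len(dimer.chains) != 2:
        raise ValueError(f"need exactly 2 chains, got {dimer.chains}")
    c1, c2 = dimer.chains
    e_bound = _packed_energy(spec, seq, dimer, packer, seed, params)
    e1 = _packed_energy(split_state_spec(spec, c1), seq,
                        dimer.subset_chains([c1], name=f"{dimer.name}/{c1}"),
                        packer, seed, params)
    e2 = _packed_energy(split_state_spec(spec, c2), seq,
                        dimer.subset_chains([c2], name=f"{dimer.name}/{c2}"),
                        packer, seed, params)
    return e_bound - e1 - e2


def _apply(dimer: Structure, transform: RigidTransform, mobile: str,
           pivot: np.ndarray) -> Structure:
    return dimer.transformed(transform.rotation, transform.translation,
                             chain_ids=[mobile], pivot=pivot)


def dock_pert(spec: StateSpec, seq: EntitySequence, dimer: Structure,
              n_traj: int = 50, seed: int = 0,
              perturb: tuple[float, float] = (DEFAULT_TRANS_SD, DEFAULT_ROT_SD),
              cycles: int = REFINE_CYCLES, kT: float = REFINE_KT,
              packer=pack_faster,
              params: ToyEnergyParams | None = None) -> DockResult:
    """Perturb-and-refine rigid-body docking; best of ``n_traj`` trajectories.

    The second chain is mobile by convention; the receptor frame stays
    fixed, which keeps mutual RMS without superposition meaningful across
    docked conformations.
    """
    if len(dimer.chains) != 2:
        raise ValueError(f"need exactly 2 chains, got {dimer.chains}")
    mobile = dimer.chains[1]
    trans_sd, rot_sd = perturb

    def centroid(struct: Structure) -> np.ndarray:
        return np.mean([r.anchor for r in struct.chain_residues(mobile)], axis=0)

    def energy_of(transform: RigidTransform, pack_seed: int) -> float:
        conf = _apply(dimer, transform, mobile, pivot)
        return _packed_energy(spec, seq, conf, packer, pack_seed, params)

    pivot = centroid(dimer)
    best_transform = RigidTransform.identity()
    best_energy = np.inf
    for t in range(n_traj):
        rng = rng_from(seed, "dock_pert", spec.name, str(seq), t)
        # split / repack chains separately / concatenate: in this model the
        # conformation is unchanged (rotamers are re-optimised from scratch
        # at every energy evaluation), so the step is implicit
        current = RigidTransform.random(rng, trans_sd, rot_sd)
        current_e = energy_of(current, seed)
        if current_e < best_energy:
            best_energy, best_transform = current_e, current
        for _ in range(cycles):
            proposal = RigidTransform.random(
                rng, trans_sd * REFINE_SCALE, rot_sd * REFINE_SCALE
            ).compose(current)
            e = energy_of(proposal, seed)
            if metropolis_accept(e - current_e, kT, float(rng.random())):
                current, current_e = proposal, e
                if e < best_energy:
                    best_energy, best_transform = e, proposal
    conformation = _apply(dimer, best_transform, mobile, pivot)
    dg = binding_energy(spec, seq, conformation, packer=packer, seed=seed,
                        params=params)
    return DockResult(best_transform, best_energy, dg, conformation)


def filter_conformations(confs: list[DockResult], dG_keep: float = -1.0,
                         rms_min: float = 0.5) -> list[Structure]:
    """Energy filter then greedy diversity filter.

    Keep conformations whose binding energy passes ``dG_keep``; then walk
    them in ascending binding-energy order, keeping each one only if its
    C-alpha RMS (without superposition) to every already-kept conformation
    is at least ``rms_min``.  Idempotent by construction.
    """
    passing = sorted((c for c in confs if c.binding_energy <= dG_keep),
                     key=lambda c: c.binding_energy)
    kept: list[Structure] = []
    for c in passing:
        coords = c.conformation.anchors()
        if all(rms_no_superposition(coords, k.anchors()) >= rms_min for k in kept):
            kept.append(c.conformation)
    return kept
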