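"""Bead-rotamer energetics.

Each rotamer is a single side-chain sphere placed along one of up to six
axes of the residue's local frame.  Sphere radius and offset from the
anchor grow with the side chain's heavy-atom count; the interaction is a
12-6 well whose depth is modulated by the product of the two partners'
Kyte-Doolittle hydrophobicities.  This preserves the combinatorial shape of
an all-atom packing problem (one-body terms, sparse pairwise terms, clashes,
burial-dependent contact counts) while being exactly specified and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HYDROPHOBICITY, SIDECHAIN_HEAVY_ATOMS
from .structure import Structure

__all__ = [
    "ToyEnergyParams",
    "Rotamer",
    "pair_energy",
    "pair_energy_arrays",
    "rotamer_geometry",
    "build_rotamers",
    "backbone_pair_energy_matrix",
]

#: bump-check threshold used when the backbone-collision filter is on, REU
BUMP_THRESHOLD = 5.0

#: single-state extra-rotamer rule: full orientation set only at residues
#: with more than this many C-alpha neighbours within NEIGHBOR_RADIUS
NEIGHBOR_COUNT_THRESHOLD = 18
NEIGHBOR_RADIUS = 10.0


@dataclass(frozen=True)
class ToyEnergyParams:
    """Parameters of the toy score function (all Angstrom except epsilon0)."""

    epsilon0: float = 0.5          # base well depth, REU
    pair_cutoff: float = 6.0       # interactions are exactly 0 beyond this
    backbone_sphere_radius: float = 1.7
    radius_base: float = 1.0
    radius_scale: float = 0.25
    offset_base: float = 0.5
    offset_scale: float = 0.35

    def __post_init__(self) -> None:
        for name in ("epsilon0", "pair_cutoff", "backbone_sphere_radius",
                     "radius_base", "radius_scale", "offset_base", "offset_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # largest sphere: W with 10 heavy atoms
        if self.pair_cutoff <= 2 * (self.radius_base + self.radius_scale * 10 ** (1 / 3)):
            raise ValueError("pair_cutoff too small relative to the largest sphere")

    @property
    def max_offset(self) -> float:
        return self.offset_base + self.offset_scale * np.sqrt(10)


@dataclass(frozen=True, eq=False)
class Rotamer:
    """One discrete side-chain placement: a sphere in space."""

    aa: str
    orientation_index: int
    center: np.ndarray     # (3,), Angstrom
    radius: float
    hydrophobicity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not np.all(np.isfinite(self.center)):
            raise ValueError("non-finite rotamer center")

    def astuple(self) -> tuple:
        """Hashable summary, for set comparisons across states."""
        return (self.aa, self.orientation_index,
                tuple(np.round(self.center, 9)), round(self.radius, 9),
                round(self.hydrophobicity, 9))


def pair_energy(rot_i: Rotamer, rot_j: Rotamer, params: ToyEnergyParams) -> float:
    """12-6 interaction between two rotamer spheres, REU.

    E = eps_ij * [(sigma/d)^12 - 2 (sigma/d)^6] for d <= cutoff, else 0,
    with sigma = r_i + r_j and eps_ij = epsilon0 * (1 + h_i * h_j).
    The well minimum is exactly -eps_ij at d = sigma.
    """
    d = float(np.linalg.norm(rot_i.center - rot_j.center))
    if d == 0.0:
        raise ValueError("coincident rotamer spheres (d = 0)")
    if d > params.pair_cutoff:
        return 0.0
    sigma = rot_i.radius + rot_j.radius
    eps = params.epsilon0 * (1.0 + rot_i.hydrophobicity * rot_j.hydrophobicity)
    sd6 = (sigma / d) ** 6
    return eps * (sd6 * sd6 - 2.0 * sd6)


def pair_energy_arrays(centers_a: np.ndarray, radii_a: np.ndarray, h_a: np.ndarray,
                       centers_b: np.ndarray, radii_b: np.ndarray, h_b: np.ndarray,
                       params: ToyEnergyParams) -> np.ndarray:
    """Vectorised pair energies: (len(a), len(b)) matrix."""
    diff = centers_a[:, None, :] - centers_b[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2))
    if np.any(d == 0.0):
        raise ValueError("coincident spheres (d = 0)")
    sigma = radii_a[:, None] + radii_b[None, :]
    eps = params.epsilon0 * (1.0 + h_a[:, None] * h_b[None, :])
    with np.errstate(over="ignore"):
        sd6 = (sigma / d) ** 6
        e = eps * (sd6 * sd6 - 2.0 * sd6)
    e[d > params.pair_cutoff] = 0.0
    return e


def rotamer_geometry(aa: str, params: ToyEnergyParams) -> tuple[float, float, float]:
    """(radius, offset, hydrophobicity) of the amino acid's sphere."""
    if aa not in SIDECHAIN_HEAVY_ATOMS:
        raise ValueError(f"unknown amino acid {aa!r}")
    c = SIDECHAIN_HEAVY_ATOMS[aa]
    radius = params.radius_base + params.radius_scale * c ** (1 / 3)
    offset = params.offset_base + params.offset_scale * c ** 0.5
    return radius, offset, HYDROPHOBICITY[aa]


#: cone half-angle of the tilted orientations about the C-beta axis.
#: Side chains emanate from the backbone on the C-beta side; letting them
#: point backwards or fully sideways would let a side chain vacate an
#: interface at no cost, which real side-chain volume forbids.
CONE_ANGLE_DEG = 60.0


def _orientation_axes(frame: np.ndarray, full: bool) -> list[np.ndarray]:
    """Six directions: straight along C-beta plus five on a 60-degree cone."""
    a1, a2, a3 = frame
    cone = np.deg2rad(CONE_ANGLE_DEG)
    axes = [a1]
    for k in range(5):
        phi = 2.0 * np.pi * k / 5.0
        axes.append(np.cos(cone) * a1
                    + np.sin(cone) * (np.cos(phi) * a2 + np.sin(phi) * a3))
    return axes if full else axes[:3]


def _neighbor_count(structure: Structure, key: tuple[str, int]) -> int:
    anchors = structure.anchors()
    anchor = structure.residue(key).anchor
    d = np.linalg.norm(anchors - anchor, axis=1)
    return int(np.sum(d <= NEIGHBOR_RADIUS)) - 1


def build_rotamers(structure: Structure, position: tuple[str, int],
                   allowed_aas: set[str] | str,
                   params: ToyEnergyParams | None = None,
                   bump_check: bool = False,
                   bump_threshold: float = BUMP_THRESHOLD,
                   multistate_mode: bool = True) -> list[Rotamer]:
    """Build the rotamer set at one residue.

    In multistate mode the bump check is forced off and the full six-axis
    orientation set is built regardless of burial, so the rotamer set for a
    given (amino acid, local geometry) is identical in every state that
    shares the backbone geometry -- the missing-rotamer safeguard.  In
    single-state mode the extended orientation set is only built at buried
    residues, and rotamers whose summed backbone interaction exceeds
    ``bump_threshold`` are pruned.
    """
    params = params or ToyEnergyParams()
    res = structure.residue(position)
    if multistate_mode:
        bump_check = False
        full = True
    else:
        full = _neighbor_count(structure, position) > NEIGHBOR_COUNT_THRESHOLD
    rotamers: list[Rotamer] = []
    for aa in sorted(allowed_aas):
        radius, offset, h = rotamer_geometry(aa, params)
        if SIDECHAIN_HEAVY_ATOMS[aa] == 0:
            candidates = [Rotamer(aa, 0, res.anchor.copy(), radius, h)]
        else:
            candidates = [
                Rotamer(aa, k, res.anchor + offset * axis, radius, h)
                for k, axis in enumerate(_orientation_axes(res.frame, full))
            ]
        if bump_check:
            candidates = [
                r for r in candidates
                if backbone_energy(r, structure, params, exclude=position) <= bump_threshold
            ]
        rotamers.extend(candidates)
    return rotamers


def backbone_pair_energy_matrix(rots: list[Rotamer], structure: Structure,
                                params: ToyEnergyParams,
                                exclude: tuple[str, int]) -> np.ndarray:
    """Per-rotamer summed interaction with the fixed backbone spheres.

    Backbone spheres (radius ``backbone_sphere_radius``, neutral
    hydrophobicity) sit at every residue anchor except the rotamer's own.
    Spheres on the rotamer's own chain interact through the full well (the
    burial term that makes the BMEC nontrivial); spheres on other chains
    act as excluded volume only (repulsive branch), so that cross-chain
    association is carried by side-chain contacts, not by a
    sequence-independent backbone funnel.
    """
    if len(rots) == 0:
        return np.zeros(0)
    own_chain = exclude[0]
    others = [r for r in structure.residues if r.key != exclude]
    if not others:
        return np.zeros(len(rots))
    anchors = np.array([r.anchor for r in others])
    cross = np.array([r.chain_id != own_chain for r in others])
    e = pair_energy_arrays(
        np.array([r.center for r in rots]),
        np.array([r.radius for r in rots]),
        np.array([r.hydrophobicity for r in rots]),
        anchors, np.full(len(anchors), params.backbone_sphere_radius),
        np.zeros(len(anchors)), params,
    )
    e[:, cross] = np.maximum(e[:, cross], 0.0)
    return e.sum(axis=1)


def backbone_energy(rot: Rotamer, structure: Structure,
                    params: ToyEnergyParams, exclude: tuple[str, int]) -> float:
    """Summed backbone interaction of a single rotamer (see the matrix form)."""
    return float(backbone_pair_energy_matrix([rot], structure, params, exclude)[0])
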