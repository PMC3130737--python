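"""Synthetic scaffolds and design systems.

Everything here is generated programmatically so the whole design protocol
is exercisable with no external structures.  Scaffolds are arcs of anchor
points; dimers are two arcs placed face to face across a parameterised gap,
which gives a controllable number of cross-chain residue pairs inside the
interaction cutoff.  Monomer species reuse the backbone coordinates of
their chains inside the dimers, so matched-backbone binding energies are
well defined by construction.

Three kinds of system are generated:

``heterodimer_task``
    The five-species setup for redesigning an obligate homodimer into an
    obligate heterodimer: monomers A and B, the AB heterodimer, and the AA
    and BB homodimers, all sharing one backbone.  Entity-sequence positions
    interleave the two chemical species (odd -> A, even -> B).

``orthogonal_task``
    A promiscuous protein A bound by three partners: dimers AB, AC, AD,
    per-backbone copies of the A monomer, and the partner monomers.

``packing_instance``
    A single dense arc used to build rotamer-packing benchmark instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import ToyEnergyParams
from .states import CorrespondenceMap, EntitySequence, StateSpec
from .structure import Residue, Structure
from .util import rng_from

__all__ = ["SyntheticSystem", "generate_synthetic_system"]

#: wild-type letters cycled onto designable interface positions; chosen
#: with a wide spread of side-chain sizes so the wildtype groove is bumpy
#: and size complementarity carries real information
WILDTYPE_CYCLE = "WA"

#: default design alphabet for the synthetic tasks: every letter has a
#: distinct sphere size (size-duplicate letters would make homodimer
#: sequences indistinguishable from heterodimer ones in this model)
DEFAULT_ALLOWED = "AGW"

ARC_RADIUS = 15.0
ARC_SPACING = 3.0          # Angstrom between consecutive anchors; close
                           # enough that side chains cannot interdigitate
                           # between the partner chain's side chains
BACKBONE_GAP = 3.6         # cross-chain anchor gap at backbone-only pairs
CURVATURE = 0.015          # z bowing of the interface, 1/Angstrom
JITTER = 0.15              # per-coordinate uniform jitter amplitude

#: energy parameters used by the dimer design tasks.  The well depth is
#: deeper than the unit-scale default because the sequence-constraint
#: penalties (5 REU per identical pair, 1 REU per extra mutation) were
#: written for interfaces whose binding energies sit in the tens of REU.
#: The interaction cutoff is shorter than the default so that binding is
#: carried by actual sphere contacts (separations of at most ~3 Angstrom)
#: rather than by sums of long-range tails, which would reward any dense
#: arrangement of chains regardless of sequence.
TASK_EPSILON = 2.0
TASK_CUTOFF = 4.5


@dataclass
class SyntheticSystem:
    """A ready-to-design set of states over synthetic scaffolds."""

    kind: str
    structures: dict[str, Structure]
    states: dict[str, StateSpec]
    designable: dict[str, list[tuple[str, int]]]    # per structure name
    entity_length: int
    wildtype_sequence: EntitySequence
    allowed_aas: str = DEFAULT_ALLOWED
    params: ToyEnergyParams = field(default_factory=ToyEnergyParams)

    #: species name -> positive (True) or negative (False) design role
    positive_species: tuple[str, ...] = ()
    negative_species: tuple[str, ...] = ()


def _arc_residue(chain: str, resnum: int, aa: str, theta: float, z: float,
                 up: bool, jitter: np.ndarray) -> Residue:
    anchor = np.array([ARC_RADIUS * np.cos(theta) + jitter[0],
                       ARC_RADIUS * np.sin(theta) + jitter[1],
                       z])
    a1 = np.array([0.0, 0.0, 1.0 if up else -1.0])
    a2 = np.array([np.cos(theta), np.sin(theta), 0.0])
    a3 = np.cross(a1, a2)
    return Residue(chain, resnum, aa, anchor, np.vstack([a1, a2, a3]))


def _chain_letters(n_core: int, n_flank: int, core_wildtypes: str,
                   flank_aa: str = "A", boundary_aa: str = "L",
                   ) -> list[tuple[str, str]]:
    """Per-residue (wildtype aa, role) with role in core|boundary|flank."""
    out = []
    n_total = n_core + 2 * n_flank
    for i in range(n_total):
        if n_flank <= i < n_flank + n_core:
            out.append((core_wildtypes[(i - n_flank) % len(core_wildtypes)], "core"))
        elif i in (n_flank - 1, n_flank + n_core):
            out.append((boundary_aa, "boundary"))
        else:
            out.append((flank_aa, "flank"))
    return out


def _contact_gap(aa_1: str, aa_2: str, params: ToyEnergyParams) -> float:
    """Cross-chain anchor distance putting the two wildtype side chains at
    their pair-energy minimum (sphere separation sigma); backbone-only
    pairs sit at the backbone excluded-volume contact distance."""
    from .energy import rotamer_geometry
    r1, o1, _ = rotamer_geometry(aa_1, params)
    r2, o2, _ = rotamer_geometry(aa_2, params)
    return o1 + o2 + r1 + r2


def _chain(chain_id: str, letters: list[tuple[str, str]], z_profile: np.ndarray,
           up: bool, rng: np.random.Generator,
           ) -> tuple[list[Residue], list[tuple[str, int]], list[tuple[str, int]]]:
    """One arc chain; returns (residues, designable keys, boundary keys)."""
    n_total = len(letters)
    dtheta = ARC_SPACING / ARC_RADIUS
    residues, designable, boundary = [], [], []
    for i, (aa, role) in enumerate(letters):
        theta = (i - (n_total - 1) / 2) * dtheta
        resnum = i + 1
        jitter = rng.uniform(-JITTER, JITTER, 2)
        residues.append(_arc_residue(chain_id, resnum, aa, theta,
                                     float(z_profile[i]), up, jitter))
        key = (chain_id, resnum)
        if role == "core":
            designable.append(key)
        elif role == "boundary":
            boundary.append(key)
    return residues, designable, boundary


def generate_synthetic_system(kind: str, n_interface: int, seed: int,
                              n_flank: int = 3,
                              allowed_aas: str = DEFAULT_ALLOWED,
                              params: ToyEnergyParams | None = None,
                              ) -> SyntheticSystem:
    """Deterministically generate a synthetic design system.

    ``n_interface`` is the number of designable residues per chain; the
    cross-chain anchor gap is small enough that every designable pair of
    facing residues lies inside the interaction cutoff.
    """
    if n_interface < 1:
        raise ValueError("n_interface must be >= 1")
    if params is None:
        params = ToyEnergyParams() if kind == "packing_instance" \
            else ToyEnergyParams(epsilon0=TASK_EPSILON, pair_cutoff=TASK_CUTOFF)
    if kind == "heterodimer_task":
        return _heterodimer_system(n_interface, seed, n_flank, allowed_aas, params)
    if kind == "orthogonal_task":
        return _orthogonal_system(n_interface, seed, n_flank, allowed_aas, params)
    if kind == "packing_instance":
        return _packing_instance(n_interface, seed, allowed_aas, params)
    raise ValueError(f"unknown system kind {kind!r}")


def _dimer(chain_ids: tuple[str, str], n_core: int, n_flank: int,
           rng: np.random.Generator, params: ToyEnergyParams,
           wildtypes: tuple[str, str] = (WILDTYPE_CYCLE,) * 2,
           gap_shift: float = 0.0,
           ) -> tuple[Structure, dict[str, list], dict[str, list]]:
    """Two face-to-face arcs with a wildtype-complementary gap.

    The interface bows gently in z (shape complementarity against rigid
    slides) and the cross-chain anchor gap at each residue pair is set so
    that the two wildtype side-chain spheres meet at their interaction
    minimum -- the input conformation is a genuine rigid-body optimum for
    the wildtype sequence, the way a crystal structure is.
    """
    letters1 = _chain_letters(n_core, n_flank, wildtypes[0])
    letters2 = _chain_letters(n_core, n_flank, wildtypes[1])
    n_total = len(letters1)
    s = (np.arange(n_total) - (n_total - 1) / 2) * ARC_SPACING
    z1 = CURVATURE * s ** 2
    # packable residues (core and boundary) carry side chains; flanks are
    # backbone-only in the energy model
    gaps = np.array([
        _contact_gap(a1, a2, params) if r1 != "flank" and r2 != "flank"
        else BACKBONE_GAP
        for (a1, r1), (a2, r2) in zip(letters1, letters2)])
    gaps = gaps + gap_shift + rng.uniform(-JITTER, JITTER, n_total)
    res1, des1, bnd1 = _chain(chain_ids[0], letters1, z1, True, rng)
    res2, des2, bnd2 = _chain(chain_ids[1], letters2, z1 + gaps, False, rng)
    struct = Structure(res1 + res2)
    return struct, {chain_ids[0]: des1, chain_ids[1]: des2}, \
        {chain_ids[0]: bnd1, chain_ids[1]: bnd2}


def _heterodimer_system(n: int, seed: int, n_flank: int, allowed: str,
                        params: ToyEnergyParams) -> SyntheticSystem:
    rng = rng_from("synthetic", "heterodimer_task", n, seed)
    dimer, des, bnd = _dimer(("A", "B"), n, n_flank, rng, params)
    dimer.name = "AB"

    # all five species share this one backbone; only correspondences differ
    structures = {
        "AB": dimer,
        "AA": Structure(dimer.residues, name="AA"),
        "BB": Structure(dimer.residues, name="BB"),
        "A": dimer.subset_chains(["A"], name="A"),
        "B": dimer.subset_chains(["B"], name="B"),
    }

    odd = [2 * k + 1 for k in range(n)]      # entity positions for species A
    even = [2 * k + 2 for k in range(n)]     # entity positions for species B
    resnums = [r for _, r in des["A"]]       # same numbering on both chains
    L = 2 * n

    def corr(chain_pos: list[tuple[str, list[int]]]) -> CorrespondenceMap:
        entries = []
        for chain, positions in chain_pos:
            entries += [(pos, chain, rn) for pos, rn in zip(positions, resnums)]
        return CorrespondenceMap(tuple(entries), L)

    secondary_dimer = set(bnd["A"]) | set(bnd["B"])
    states = {
        "AB": StateSpec("AB", corr([("A", odd), ("B", even)]),
                        secondary_dimer, structure=structures["AB"]),
        "AA": StateSpec("AA", corr([("A", odd), ("B", odd)]),
                        secondary_dimer, structure=structures["AA"]),
        "BB": StateSpec("BB", corr([("A", even), ("B", even)]),
                        secondary_dimer, structure=structures["BB"]),
        "A": StateSpec("A", corr([("A", odd)]), set(bnd["A"]),
                       structure=structures["A"]),
        "B": StateSpec("B", corr([("B", even)]), set(bnd["B"]),
                       structure=structures["B"]),
    }

    wt_letters = [WILDTYPE_CYCLE[k % len(WILDTYPE_CYCLE)] for k in range(n)]
    wildtype = EntitySequence("".join(w + w for w in wt_letters))

    return SyntheticSystem(
        kind="heterodimer_task", structures=structures, states=states,
        designable={name: sorted(s.correspondence.targets)
                    for name, s in states.items()},
        entity_length=L, wildtype_sequence=wildtype, allowed_aas=allowed,
        params=params, positive_species=("AB",), negative_species=("AA", "BB"),
    )


#: partner wild-type motifs for the orthogonal task (B, C, D differ so that
#: sequence changes on A can separate them energetically)
PARTNER_WILDTYPES = {"B": "LMLMLMLM", "C": "FWFWFWFW", "D": "VAVAVAVA"}
PARTNER_GAP_SHIFTS = {"B": -0.1, "C": 0.0, "D": 0.1}


def _orthogonal_system(n: int, seed: int, n_flank: int, allowed: str,
                       params: ToyEnergyParams) -> SyntheticSystem:
    structures: dict[str, Structure] = {}
    states: dict[str, StateSpec] = {}
    resnums = None
    L = n
    positions = list(range(1, n + 1))
    for partner in ("B", "C", "D"):
        rng = rng_from("synthetic", "orthogonal_task", n, seed, partner)
        dimer, des, bnd = _dimer(("A", partner), n, n_flank, rng, params,
                                 wildtypes=(WILDTYPE_CYCLE, PARTNER_WILDTYPES[partner]),
                                 gap_shift=PARTNER_GAP_SHIFTS[partner])
        name = f"A{partner}"
        dimer.name = name
        structures[name] = dimer
        # per-backbone monomer copies: the A backbone from this very dimer
        structures[f"A_{name}"] = dimer.subset_chains(["A"], name=f"A_{name}")
        structures[partner] = dimer.subset_chains([partner], name=partner)
        resnums = [r for _, r in des["A"]]
        entries = tuple((pos, "A", rn) for pos, rn in zip(positions, resnums))
        corr = CorrespondenceMap(entries, L)
        secondary = set(bnd["A"]) | set(des[partner]) | set(bnd[partner])
        states[name] = StateSpec(name, corr, secondary, structure=dimer)
        states[f"A_{name}"] = StateSpec(f"A_{name}", corr, set(bnd["A"]),
                                        structure=structures[f"A_{name}"])
        # the partner monomer carries no entity positions: repack its interface
        states[partner] = StateSpec(
            partner, CorrespondenceMap((), L),
            set(des[partner]) | set(bnd[partner]),
            structure=structures[partner])

    wildtype = EntitySequence("".join(
        WILDTYPE_CYCLE[k % len(WILDTYPE_CYCLE)] for k in range(n)))

    return SyntheticSystem(
        kind="orthogonal_task", structures=structures, states=states,
        designable={name: sorted(s.correspondence.targets)
                    for name, s in states.items()},
        entity_length=L, wildtype_sequence=wildtype, allowed_aas=allowed,
        params=params, positive_species=("AB",), negative_species=("AC", "AD"),
    )


def _packing_instance(n: int, seed: int, allowed: str,
                      params: ToyEnergyParams) -> SyntheticSystem:
    rng = rng_from("synthetic", "packing_instance", n, seed)
    # dense single arc so consecutive side chains genuinely interact
    spacing = 3.0
    dtheta = spacing / ARC_RADIUS
    residues = []
    for i in range(n):
        theta = (i - (n - 1) / 2) * dtheta
        aa = allowed[int(rng.integers(len(allowed)))]
        jitter = rng.uniform(-JITTER, JITTER, 2)
        residues.append(_arc_residue("A", i + 1, aa, theta, 0.0, True, jitter))
    struct = Structure(residues, name="packing_instance")
    keys = [("A", i + 1) for i in range(n)]
    corr = CorrespondenceMap(tuple((i + 1, "A", i + 1) for i in range(n)), n)
    spec = StateSpec("packing_instance", corr, set(), structure=struct)
    wildtype = EntitySequence("".join(r.wildtype_aa for r in residues))
    return SyntheticSystem(
        kind="packing_instance", structures={"packing_instance": struct},
        states={"packing_instance": spec}, designable={"packing_instance": keys},
        entity_length=n, wildtype_sequence=wildtype, allowed_aas=allowed,
        params=params,
    )
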