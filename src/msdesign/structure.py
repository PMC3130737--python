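"""Fixed-backbone scaffolds for the bead-rotamer model.

A :class:`Structure` is an ordered list of residues, each carrying a chain
id, a 1-based residue number, a wild-type amino acid, an anchor point (the
C-alpha position) and an orthonormal local frame whose first axis plays the
role of the C-alpha -> C-beta direction.  Structures are read and written
either as a PDB subset (ATOM records, CA + optional CB) or as a native
one-residue-per-line text format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .constants import AMINO_ACIDS, ONE_TO_THREE, THREE_TO_ONE

__all__ = [
    "Residue",
    "Structure",
    "rms_no_superposition",
    "read_toy_structure",
    "write_toy_structure",
    "read_pdb_subset",
    "write_pdb_subset",
]

#: length of the pseudo C-beta bond used when writing PDB files, Angstrom
CB_BOND_LENGTH = 1.5


@dataclass(frozen=True)
class Residue:
    """One residue: identity plus rigid local geometry."""

    chain_id: str
    residue_number: int
    wildtype_aa: str
    anchor: np.ndarray          # shape (3,), Angstrom
    frame: np.ndarray           # shape (3, 3), rows are orthonormal axes

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))
        object.__setattr__(self, "frame", np.asarray(self.frame, dtype=float))
        if len(self.chain_id) != 1:
            raise ValueError(f"chain id must be a single character: {self.chain_id!r}")
        if self.residue_number < 1:
            raise ValueError("residue numbers are 1-based")
        if self.wildtype_aa not in AMINO_ACIDS:
            raise ValueError(f"unknown amino acid {self.wildtype_aa!r}")
        if not np.all(np.isfinite(self.anchor)) or not np.all(np.isfinite(self.frame)):
            raise ValueError("non-finite coordinates")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


class Structure:
    """An ordered collection of residues grouped into chains."""

    def __init__(self, residues: list[Residue], name: str = ""):
        self.name = name
        self.residues: list[Residue] = list(residues)
        seen: set[tuple[str, int]] = set()
        chains: list[str] = []
        for r in self.residues:
            if r.key in seen:
                raise ValueError(f"duplicate residue {r.key}")
            seen.add(r.key)
            if r.chain_id not in chains:
                chains.append(r.chain_id)
        self.chains: list[str] = chains
        self._index: dict[tuple[str, int], Residue] = {r.key: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._index

    def residue(self, key: tuple[str, int]) -> Residue:
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"residue {key} not in structure {self.name!r}") from None

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def anchors(self) -> np.ndarray:
        return np.array([r.anchor for r in self.residues])

    def subset_chains(self, chain_ids: list[str], name: str = "") -> "Structure":
        """Extract the given chains (backbone coordinates unchanged)."""
        res = [r for r in self.residues if r.chain_id in chain_ids]
        if not res:
            raise ValueError(f"no residues on chains {chain_ids}")
        return Structure(res, name=name or self.name)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_ids: list[str] | None = None,
                    pivot: np.ndarray | None = None) -> "Structure":
        """Rigidly move (a subset of) the structure.

        Anchors are rotated about ``pivot`` (default: origin) and translated;
        frames rotate with the body so rotamers move rigidly with the chain.
        """
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        pivot = np.zeros(3) if pivot is None else np.asarray(pivot, float)
        out = []
        for r in self.residues:
            if chain_ids is not None and r.chain_id not in chain_ids:
                out.append(r)
                continue
            anchor = rotation @ (r.anchor - pivot) + pivot + translation
            frame = r.frame @ rotation.T   # row vectors
            out.append(Residue(r.chain_id, r.residue_number, r.wildtype_aa, anchor, frame))
        return Structure(out, name=self.name)


def rms_no_superposition(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square distance between paired points, with no alignment.

    The mutual-RMS diversity measure for docked conformations: structures are
    compared in a common fixed frame, so rigid-body displacement counts.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 1:
        raise ValueError(f"coordinate shapes differ or invalid: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# local frames

def _frame_from_axis1(axis1: np.ndarray) -> np.ndarray:
    """Complete a right-handed orthonormal frame from its first axis."""
    a1 = np.asarray(axis1, float)
    a1 = a1 / np.linalg.norm(a1)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(a1 @ ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    a2 = np.cross(ref, a1)
    a2 /= np.linalg.norm(a2)
    a3 = np.cross(a1, a2)
    return np.vstack([a1, a2, a3])


def pseudo_cb_direction(ca: np.ndarray, i: int) -> np.ndarray:
    """Deterministic C-beta-like direction for residue i of a chain.

    Points perpendicular to the local chain direction, alternating is not
    needed: the rule uses only neighbouring C-alpha positions so the same
    backbone always gives the same frame.
    """
    n = len(ca)
    if n == 1:
        return np.array([0.0, 0.0, 1.0])
    lo = max(i - 1, 0)
    hi = min(i + 1, n - 1)
    t = ca[hi] - ca[lo]
    norm = np.linalg.norm(t)
    if norm == 0:
        return np.array([0.0, 0.0, 1.0])
    t = t / norm
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(t @ ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    d = np.cross(t, ref)
    return d / np.linalg.norm(d)


# ---------------------------------------------------------------------------
# native toy-structure format: "chain resnum aa x y z" per line

def write_toy_structure(structure: Structure) -> str:
    """Serialize to the native text format (frame's first axis appended)."""
    lines = ["# chain resnum aa x y z ax ay az"]
    for r in structure.residues:
        x, y, z = r.anchor
        ax, ay, az = r.frame[0]
        lines.append(
            f"{r.chain_id} {r.residue_number} {r.wildtype_aa} "
            f"{x:.6f} {y:.6f} {z:.6f} {ax:.6f} {ay:.6f} {az:.6f}"
        )
    return "\n".join(lines) + "\n"


def read_toy_structure(text: str, name: str = "") -> Structure:
    residues = []
    per_chain_ca: dict[str, list[np.ndarray]] = {}
    raw = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (6, 9):
            raise ValueError(f"line {lineno}: expected 6 or 9 fields, got {len(parts)}")
        chain, resnum, aa = parts[0], int(parts[1]), parts[2].upper()
        anchor = np.array([float(v) for v in parts[3:6]])
        axis1 = np.array([float(v) for v in parts[6:9]]) if len(parts) == 9 else None
        chain_ca = per_chain_ca.setdefault(chain, [])
        raw.append((chain, resnum, aa, anchor, axis1, len(chain_ca)))
        chain_ca.append(anchor)
    for chain, resnum, aa, anchor, axis1, idx in raw:
        if axis1 is None:
            axis1 = pseudo_cb_direction(np.array(per_chain_ca[chain]), idx)
        residues.append(Residue(chain, resnum, aa, anchor, _frame_from_axis1(axis1)))
    return Structure(residues, name=name)


# ---------------------------------------------------------------------------
# PDB subset: CA anchors, optional CB defining the frame's first axis

def write_pdb_subset(structure: Structure) -> str:
    n_atoms = 2 * len(structure)
    atoms = bst.AtomArray(n_atoms)
    k = 0
    for r in structure.residues:
        for atom_name, coord in (
            ("CA", r.anchor),
            ("CB", r.anchor + CB_BOND_LENGTH * r.frame[0]),
        ):
            atoms.chain_id[k] = r.chain_id
            atoms.res_id[k] = r.residue_number
            atoms.res_name[k] = ONE_TO_THREE[r.wildtype_aa]
            atoms.atom_name[k] = atom_name
            atoms.element[k] = "C"
            atoms.coord[k] = coord
            k += 1
    pdb = bpdb.PDBFile()
    pdb.set_structure(atoms)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def read_pdb_subset(text: str, name: str = "") -> Structure:
    pdb = bpdb.PDBFile.read(io.StringIO(text))
    atoms = pdb.get_structure(model=1)
    ca = atoms[atoms.atom_name == "CA"]
    cb = atoms[atoms.atom_name == "CB"]
    cb_index = {(c, int(r)): xyz for c, r, xyz in zip(cb.chain_id, cb.res_id, cb.coord)}
    per_chain: dict[str, list[tuple[int, str, np.ndarray]]] = {}
    order: list[str] = []
    for c, rid, rname, xyz in zip(ca.chain_id, ca.res_id, ca.res_name, ca.coord):
        if c not in per_chain:
            per_chain[c] = []
            order.append(c)
        per_chain[c].append((int(rid), THREE_TO_ONE[rname], np.asarray(xyz, float)))
    residues = []
    for c in order:
        entries = per_chain[c]
        ca_coords = np.array([e[2] for e in entries])
        for i, (rid, aa, anchor) in enumerate(entries):
            cb_xyz = cb_index.get((c, rid))
            if cb_xyz is not None:
                axis1 = np.asarray(cb_xyz, float) - anchor
            else:
                axis1 = pseudo_cb_direction(ca_coords, i)
            residues.append(Residue(str(c), rid, aa, anchor, _frame_from_axis1(axis1)))
    return Structure(residues, name=name)
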