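"""State definition and sequence threading.

A *state* is a fixed-backbone structure plus a correspondence map (which
residues take their identity from which positions of the designed entity
sequence) and a secondary repack set (residues repacked at wild-type
identity but never designed).  One entity position may map to several
residues -- that is how homodimer states thread the same half of the
sequence onto both chains.

There is no distributed runtime here: the replacement for MPI work
distribution is a seed contract.  ``evaluate_state`` derives every random
stream from (global seed, state name, sequence text, replicate index)
through a stable mixing function, so any partitioning or ordering of the
work yields bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .constants import AMINO_ACIDS
from .optimizers import PackerResult
from .packing import InteractionGraph, build_packing_problem
from .structure import Structure
from .energy import ToyEnergyParams
from .util import stable_mix

__all__ = [
    "EntitySequence",
    "CorrespondenceMap",
    "StateSpec",
    "parse_correspondence",
    "parse_secondary_resfile",
    "parse_state_list",
    "thread_sequence",
    "evaluate_state",
]

logger = logging.getLogger(__name__)


class EntitySequence(str):
    """The amino-acid string the genetic algorithm optimizes.

    Input is case-insensitive (the field's display convention writes
    wild-type positions in lower case); stored canonically in upper case.
    """

    def __new__(cls, letters: str) -> "EntitySequence":
        canonical = str(letters).upper()
        bad = set(canonical) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"not amino-acid letters: {sorted(bad)}")
        return super().__new__(cls, canonical)

    @property
    def length(self) -> int:
        return len(self)


@dataclass(frozen=True)
class CorrespondenceMap:
    """entity position -> structure residue(s) mapping for one state."""

    entries: tuple[tuple[int, str, int], ...]   # (entity_pos, chain_id, resnum)
    entity_length: int

    def __post_init__(self) -> None:
        targets = [(c, r) for _, c, r in self.entries]
        if len(targets) != len(set(targets)):
            raise ValueError("a residue is targeted by two correspondence entries")
        for pos, _, _ in self.entries:
            if not 1 <= pos <= self.entity_length:
                raise ValueError(f"entity position {pos} outside [1, {self.entity_length}]")

    @property
    def targets(self) -> set[tuple[str, int]]:
        return {(c, r) for _, c, r in self.entries}


def parse_correspondence(text: str) -> CorrespondenceMap:
    """Parse the correspondence-file dialect.

    One entry per line: ``entity_pos resnum chain``; ``#`` starts a comment;
    an optional ``ENTITY_LENGTH n`` line declares the length (otherwise the
    maximum entity position is used).
    """
    entries: list[tuple[int, str, int]] = []
    declared_length: int | None = None
    seen: set[tuple[str, int]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0].upper() == "ENTITY_LENGTH":
            declared_length = int(parts[1])
            continue
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 'entity_pos resnum chain'")
        try:
            pos, resnum = int(parts[0]), int(parts[1])
        except ValueError:
            raise ValueError(f"line {lineno}: non-integer field in {line!r}") from None
        chain = parts[2]
        if (chain, resnum) in seen:
            raise ValueError(f"line {lineno}: residue {chain}{resnum} targeted twice")
        seen.add((chain, resnum))
        entries.append((pos, chain, resnum))
    if not entries:
        raise ValueError("empty correspondence file")
    length = declared_length if declared_length is not None \
        else max(pos for pos, _, _ in entries)
    return CorrespondenceMap(tuple(entries), length)


def parse_secondary_resfile(text: str) -> set[tuple[str, int]]:
    """Secondary resfile: lines ``chain resnum`` = repack at wild type."""
    out: set[tuple[str, int]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'chain resnum'")
        out.add((parts[0], int(parts[1])))
    return out


@dataclass
class StateSpec:
    """Structure + correspondence + secondary repack set + replicate count."""

    name: str
    correspondence: CorrespondenceMap
    secondary_repack: set[tuple[str, int]] = field(default_factory=set)
    replicates: int = 1
    structure_source: str | None = None     # file path, when file-driven
    structure: Structure | None = None      # in-memory scaffold

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        overlap = self.secondary_repack & self.correspondence.targets
        if overlap:
            raise ValueError(f"secondary resfile overlaps correspondence targets: {overlap}")

    def get_structure(self) -> Structure:
        if self.structure is not None:
            return self.structure
        if self.structure_source is None:
            raise ValueError(f"state {self.name!r} has no structure")
        from .structure import read_pdb_subset, read_toy_structure
        with open(self.structure_source) as fh:
            text = fh.read()
        if self.structure_source.endswith(".pdb"):
            return read_pdb_subset(text, name=self.name)
        return read_toy_structure(text, name=self.name)


def parse_state_list(text: str, base_dir: str | None = None,
                     ) -> list[StateSpec]:
    """State-vector list file: one state per line,
    ``structure_file correspondence_file secondary_resfile``."""
    import pathlib

    base = pathlib.Path(base_dir) if base_dir else pathlib.Path(".")
    specs: list[StateSpec] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(
                f"line {lineno}: expected 'structure correspondence secondary'")
        struct_file, corr_file, secondary_file = parts
        corr = parse_correspondence((base / corr_file).read_text())
        secondary = parse_secondary_resfile((base / secondary_file).read_text())
        specs.append(StateSpec(
            name=pathlib.Path(struct_file).stem, correspondence=corr,
            secondary_repack=secondary - corr.targets,
            structure_source=str(base / struct_file)))
    return specs


def thread_sequence(spec: StateSpec, seq: EntitySequence, structure: Structure,
                    ) -> tuple[dict[tuple[str, int], str],
                               list[tuple[str, int, str, str]]]:
    """Assign entity-sequence letters to correspondence-target residues.

    Returns (residue key -> assigned amino acid, mutation list); each
    mutation is (chain, resnum, wildtype aa, assigned aa).
    """
    if len(seq) != spec.correspondence.entity_length:
        raise ValueError(
            f"sequence length {len(seq)} != entity length "
            f"{spec.correspondence.entity_length} of state {spec.name!r}")
    assigned: dict[tuple[str, int], str] = {}
    mutations: list[tuple[str, int, str, str]] = []
    for pos, chain, resnum in spec.correspondence.entries:
        key = (chain, resnum)
        if key not in structure:
            raise KeyError(
                f"correspondence of state {spec.name!r} references residue "
                f"{chain}{resnum}, absent from structure {structure.name!r}")
        aa = seq[pos - 1]
        assigned[key] = aa
        wt = structure.residue(key).wildtype_aa
        if aa != wt:
            mutations.append((chain, resnum, wt, aa))
    return assigned, mutations


def format_vs_wildtype(spec: StateSpec, seq: EntitySequence,
                       structure: Structure) -> str:
    """Entity sequence with wild-type positions lower-cased (display only)."""
    wt_at: dict[int, str] = {}
    for pos, chain, resnum in spec.correspondence.entries:
        wt_at.setdefault(pos, structure.residue((chain, resnum)).wildtype_aa)
    out = []
    for i, aa in enumerate(seq, start=1):
        out.append(aa.lower() if wt_at.get(i) == aa else aa)
    return "".join(out)


def evaluate_state(spec: StateSpec, seq: EntitySequence, structure: Structure,
                   packer, global_seed: int,
                   params: ToyEnergyParams | None = None,
                   graph: InteractionGraph | None = None,
                   ) -> tuple[float, PackerResult | None]:
    """Pack one sequence on one state; the state's energy is the replicate minimum.

    The packer is any callable (problem, seed) -> PackerResult.  Replicate
    seeds are ``stable_mix(global_seed, state name, sequence, replicate)``,
    which makes the result a pure function of its arguments, independent of
    evaluation order.
    """
    problem = build_packing_problem(spec, seq, structure, params=params, graph=graph)
    if problem.n_positions == 0:
        logger.warning("state %s: no packable positions; returning background energy",
                       spec.name)
        return problem.background_energy, None
    best: PackerResult | None = None
    for rep in range(spec.replicates):
        seed = stable_mix(global_seed, spec.name, str(seq), rep)
        res = packer(problem, seed)
        if best is None or res.energy < best.energy:
            best = res
    assert best is not None
    return best.energy, best
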