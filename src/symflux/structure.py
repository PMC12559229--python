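"""Flat structure container and PDB input/output.

The in-memory model is a flat, ordered list of atoms — deliberately not a
hierarchy — because every downstream consumer (superposition, pore
profiling, consolidation) works on coordinate arrays selected by
(chain, residue, atom name) keys. The reader is a strict fixed-column
ATOM/HETATM parser that reports the offending line number on malformed
input and enforces the keying invariants (first altloc kept, insertion
codes rejected) that the rest of the pipeline relies on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "RecordClass",
    "AtomRecord",
    "Structure",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "consolidate_chains",
    "BACKBONE_ATOMS",
    "AMINO_ACIDS_3",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

AMINO_ACIDS_3 = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        # common histidine protonation-state aliases from MD topologies
        "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
    }
)

_WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "TIP", "SPC"})


class RecordClass(enum.Enum):
    PROTEIN = "protein"
    LIGAND = "ligand"
    SOLVENT = "solvent"
    OTHER = "other"


class PDBParseError(ValueError):
    """Raised for malformed PDB records; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) Å
    record_class: RecordClass = RecordClass.OTHER

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class Structure:
    """Ordered atom list with unique (chain, residue, atom name) keys."""

    atoms: list[AtomRecord]
    id: str = ""
    # consolidated-residue -> (original chain, original residue) map,
    # populated by consolidate_chains so restraints in original numbering
    # can still be resolved.
    residue_map: dict[int, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for atom in self.atoms:
            if atom.key in seen:
                raise ValueError(f"duplicate atom key {atom.key} in structure {self.id!r}")
            seen.add(atom.key)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, id=self.id, residue_map=dict(self.residue_map))

    def select(self, predicate: Callable[[AtomRecord], bool]) -> "Structure":
        return Structure([a for a in self.atoms if predicate(a)], id=self.id)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def chain_coords(self, chain_id: str) -> np.ndarray:
        sel = [a.position for a in self.atoms if a.chain_id == chain_id]
        if not sel:
            raise KeyError(f"chain {chain_id!r} not present")
        return np.array(sel)

    def backbone(self) -> "Structure":
        return self.select(
            lambda a: a.record_class is RecordClass.PROTEIN and a.atom_name in BACKBONE_ATOMS
        )


def _classify(record_type: str, residue_name: str) -> RecordClass:
    if residue_name in _WATER_NAMES:
        return RecordClass.SOLVENT
    if residue_name in AMINO_ACIDS_3:
        return RecordClass.PROTEIN
    if record_type == "HETATM":
        return RecordClass.LIGAND
    return RecordClass.OTHER


def _parse_float(text: str, what: str, line_number: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(f"non-numeric {what} field {text.strip()!r}", line_number) from None


def read_pdb(path: str | Path, structure_id: str | None = None) -> Structure:
    """Read ATOM/HETATM records from a PDB file into a :class:`Structure`.

    First altloc ('A' or blank) is kept; insertion codes are rejected;
    other record types are ignored. Raises :class:`PDBParseError` with the
    line number on malformed coordinate fields and on empty structures.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    seen_altloc: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record_type = line[:6].strip()
            if record_type not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError("truncated ATOM/HETATM record", lineno)
            atom_name = line[12:16].strip()
            altloc = line[16].strip()
            residue_name = line[17:20].strip()
            chain_id = line[21].strip() or " "
            icode = line[26].strip()
            if icode:
                raise PDBParseError(
                    f"insertion code {icode!r} not supported (renumber the structure)",
                    lineno,
                )
            try:
                residue_number = int(line[22:26])
            except ValueError:
                raise PDBParseError(
                    f"non-integer residue number {line[22:26].strip()!r}", lineno
                ) from None
            x = _parse_float(line[30:38], "x", lineno)
            y = _parse_float(line[38:46], "y", lineno)
            z = _parse_float(line[46:54], "z", lineno)
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = atom_name[:1]
            key = (chain_id, residue_number, atom_name)
            if altloc:
                if key in seen_altloc:
                    continue  # keep first altloc only
                seen_altloc.add(key)
            atoms.append(
                AtomRecord(
                    chain_id=chain_id,
                    residue_number=residue_number,
                    residue_name=residue_name,
                    atom_name=atom_name,
                    element=element,
                    position=np.array([x, y, z]),
                    record_class=_classify(record_type, residue_name),
                )
            )
    if not atoms:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")
    return Structure(atoms, id=structure_id if structure_id is not None else path.stem)


def write_pdb(
    structure: Structure,
    path: str | Path,
    remarks: Iterable[str] = (),
) -> None:
    """Write a structure as PDB text; ``remarks`` become leading REMARK lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for remark in remarks:
            fh.write(f"REMARK {remark}\n")
        for serial, atom in enumerate(structure.atoms, start=1):
            record = "ATOM" if atom.record_class is RecordClass.PROTEIN else "HETATM"
            name = atom.atom_name
            # PDB convention: 1-3 character names start in column 14
            name_field = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = atom.position
            fh.write(
                f"{record:<6s}{serial % 100000:>5d} {name_field:<4s} "
                f"{atom.residue_name:<3s} {atom.chain_id:1s}"
                f"{atom.residue_number:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{atom.element:>2s}\n"
            )
        fh.write("END\n")


def consolidate_chains(structure: Structure, offset: int = 1000) -> Structure:
    """Merge all chains into one, renumbering chain k (0-based) by ``+ k*offset``.

    The reverse map (consolidated residue -> original chain/residue) is
    stored on the returned structure's ``residue_map`` so restraint tables
    written against the original numbering remain resolvable.
    """
    if offset < 1:
        raise ValueError("offset must be a positive integer")
    chains = structure.chains()
    if len(chains) > 99999 // offset:
        raise ValueError(f"too many chains ({len(chains)}) for offset {offset}")
    if len(chains) <= 1:
        return Structure(list(structure.atoms), id=structure.id,
                         residue_map=dict(structure.residue_map))
    chain_index = {c: k for k, c in enumerate(chains)}
    target_chain = chains[0]
    atoms: list[AtomRecord] = []
    residue_map: dict[int, tuple[str, int]] = {}
    for atom in structure.atoms:
        new_resnum = atom.residue_number + chain_index[atom.chain_id] * offset
        prev = residue_map.get(new_resnum)
        if prev is not None and prev != (atom.chain_id, atom.residue_number):
            raise ValueError(
                f"renumbering collision at residue {new_resnum}: "
                f"{prev} vs ({atom.chain_id!r}, {atom.residue_number})"
            )
        residue_map[new_resnum] = (atom.chain_id, atom.residue_number)
        atoms.append(replace(atom, chain_id=target_chain, residue_number=new_resnum))
    return Structure(atoms, id=structure.id, residue_map=residue_map)
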