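"""Docking-model containers and ensemble input/output.

A docking model is one rigid pose of a two-partner complex together with
the energy components printed by the docking engine. Energies are read,
never recomputed; a missing component is recorded as absent (``None``),
not silently zeroed.

The native on-disk layout is a directory of PDB files each carrying a
``REMARK energies key=value ...`` header; a sidecar TSV
(model_id, hs, e_vdw, e_elec, e_desolv, e_air, bsa) is accepted as an
alternative for engines whose header layout differs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure import AtomRecord, RecordClass, Structure, read_pdb, write_pdb

__all__ = [
    "EnergyComponents",
    "DockingModel",
    "read_docking_ensemble",
    "write_docking_ensemble",
    "ENERGY_FIELDS",
]

ENERGY_FIELDS = ("hs", "e_vdw", "e_elec", "e_desolv", "e_air", "bsa")

#: maps common docking-output header spellings onto our field names
DEFAULT_HEADER_DIALECT: dict[str, str] = {
    "hs": "hs",
    "haddock-score": "hs",
    "score": "hs",
    "e_vdw": "e_vdw",
    "evdw": "e_vdw",
    "vdw": "e_vdw",
    "e_elec": "e_elec",
    "eelec": "e_elec",
    "elec": "e_elec",
    "es": "e_elec",
    "e_desolv": "e_desolv",
    "edesolv": "e_desolv",
    "desolv": "e_desolv",
    "ds": "e_desolv",
    "e_air": "e_air",
    "eair": "e_air",
    "air": "e_air",
    "bsa": "bsa",
}


@dataclass(frozen=True)
class EnergyComponents:
    """Energy terms of one docking model; ``None`` marks an absent field.

    ``hs`` is the engine's composite score, ``e_vdw``/``e_elec``/``e_desolv``
    the van der Waals, electrostatics and desolvation terms, ``e_air`` the
    restraint-violation energy and ``bsa`` the buried surface area (Å²).
    """

    hs: float | None = None
    e_vdw: float | None = None
    e_elec: float | None = None
    e_desolv: float | None = None
    e_air: float | None = None
    bsa: float | None = None

    def __post_init__(self) -> None:
        for name in ENERGY_FIELDS:
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"energy component {name} is not finite: {v}")
        if self.bsa is not None and self.bsa < 0:
            raise ValueError(f"bsa must be >= 0, got {self.bsa}")

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in ENERGY_FIELDS}

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(n for n in ENERGY_FIELDS if getattr(self, n) is None)


@dataclass
class DockingModel:
    """One docking pose: structure, parsed energies and partner selections.

    ``receptor_chains`` / ``ligand_chains`` name the chains of the two
    partners; they must be disjoint and non-empty. Coordinate accessors
    return atoms ordered chain-by-chain in the given chain order, atoms
    within a chain in file order, so two models with identical topology
    have a positional atom correspondence.
    """

    structure: Structure
    energies: EnergyComponents
    model_id: int
    receptor_chains: tuple[str, ...]
    ligand_chains: tuple[str, ...]

    def __post_init__(self) -> None:
        rec = set(self.receptor_chains)
        lig = set(self.ligand_chains)
        if not rec or not lig:
            raise ValueError("receptor and ligand selections must be non-empty")
        if rec & lig:
            raise ValueError(f"receptor/ligand chains overlap: {sorted(rec & lig)}")
        present = set(self.structure.chains())
        missing = (rec | lig) - present
        if missing:
            raise ValueError(f"model {self.model_id}: chains absent from structure: {sorted(missing)}")

    def _chain_coords(self, chains: Sequence[str], atom_set: str) -> np.ndarray:
        blocks = []
        for c in chains:
            atoms = [a for a in self.structure.atoms if a.chain_id == c]
            if atom_set == "CA":
                atoms = [a for a in atoms if a.atom_name == "CA"]
            elif atom_set == "backbone":
                atoms = [a for a in atoms if a.atom_name in ("N", "CA", "C", "O")]
            elif atom_set != "all":
                raise ValueError(f"unknown atom set {atom_set!r}")
            if not atoms:
                raise ValueError(
                    f"model {self.model_id}: chain {c!r} has no atoms under set {atom_set!r}"
                )
            blocks.append(np.array([a.position for a in atoms]))
        return np.vstack(blocks)

    def receptor_coords(self, atom_set: str = "CA") -> np.ndarray:
        return self._chain_coords(self.receptor_chains, atom_set)

    def ligand_coords(self, atom_set: str = "CA", flipped: bool = False) -> np.ndarray:
        chains = tuple(reversed(self.ligand_chains)) if flipped else self.ligand_chains
        return self._chain_coords(chains, atom_set)

    def ligand_atoms(self) -> list[AtomRecord]:
        lig = set(self.ligand_chains)
        return [a for a in self.structure.atoms if a.chain_id in lig]


_ENERGY_REMARK = re.compile(r"^REMARK\s+energies\s+(.*)$")
_MODEL_ORDINAL = re.compile(r"(\d+)")


def _parse_energy_remark(
    line: str, dialect: Mapping[str, str]
) -> dict[str, float] | None:
    m = _ENERGY_REMARK.match(line.strip())
    if not m:
        return None
    out: dict[str, float] = {}
    for token in m.group(1).split():
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        field_name = dialect.get(key.strip().lower())
        if field_name is None:
            continue
        try:
            out[field_name] = float(value)
        except ValueError:
            raise ValueError(f"malformed energy value {token!r} in REMARK energies line") from None
    return out


def _model_id_from_name(path: Path, ordinal: int) -> int:
    nums = _MODEL_ORDINAL.findall(path.stem)
    return int(nums[-1]) if nums else ordinal


def read_docking_ensemble(
    directory: str | Path,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
    dialect: Mapping[str, str] | None = None,
    pattern: str = "*.pdb",
    energy_table: str | Path | None = None,
) -> list[DockingModel]:
    """Read a directory of docking-model PDB files into :class:`DockingModel` s.

    ``model_id`` is taken from the trailing integer in each filename (or the
    file's ordinal position when the name carries none). Energies come from
    each file's ``REMARK energies`` header, or from ``energy_table`` (TSV
    keyed by model_id) when given; the table wins on conflict.
    """
    directory = Path(directory)
    dialect = DEFAULT_HEADER_DIALECT if dialect is None else dict(dialect)
    files = sorted(directory.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no model files matching {pattern!r} in {directory}")

    table: dict[int, dict[str, float]] = {}
    if energy_table is not None:
        df = pd.read_csv(energy_table, sep="\t")
        if "model_id" not in df.columns:
            raise ValueError("energy table must have a model_id column")
        for _, row in df.iterrows():
            table[int(row["model_id"])] = {
                k: float(row[k]) for k in ENERGY_FIELDS if k in df.columns and pd.notna(row[k])
            }

    models: list[DockingModel] = []
    seen_ids: set[int] = set()
    for ordinal, path in enumerate(files):
        header_energies: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith(("ATOM", "HETATM")):
                    break
                parsed = _parse_energy_remark(line, dialect)
                if parsed:
                    header_energies.update(parsed)
        model_id = _model_id_from_name(path, ordinal)
        if model_id in seen_ids:
            raise ValueError(f"duplicate model_id {model_id} (file {path.name})")
        seen_ids.add(model_id)
        header_energies.update(table.get(model_id, {}))
        models.append(
            DockingModel(
                structure=read_pdb(path),
                energies=EnergyComponents(**header_energies),
                model_id=model_id,
                receptor_chains=tuple(receptor_chains),
                ligand_chains=tuple(ligand_chains),
            )
        )
    if not models:
        raise ValueError(f"no parseable models in {directory}")
    return models


def write_docking_ensemble(models: Sequence[DockingModel], directory: str | Path) -> list[Path]:
    """Write models as ``model_<id>.pdb`` files with REMARK energies headers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for model in models:
        tokens = " ".join(
            f"{k}={v:.3f}" for k, v in model.energies.as_dict().items() if v is not None
        )
        path = directory / f"model_{model.model_id:04d}.pdb"
        write_pdb(model.structure, path, remarks=[f"energies {tokens}"] if tokens else [])
        paths.append(path)
    return paths
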