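"""Seeded synthetic inputs with recorded ground truth.

Every analysis stage in this package can be exercised without any
downloaded data: these generators build toy docking ensembles with
planted cluster membership, substrate trajectories with scripted
compartment dwell sequences, tubular pore structures with a prescribed
radius profile, and sequence families drawn from a per-column
conservation vector. Each generator consumes one explicit
``numpy.random.Generator`` stream derived from its seed (no global RNG
state) and returns a :class:`GroundTruth` that serializes beside the
outputs, so a run is reproducible bit-for-bit from (parameters, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .conservation import AMINO_ACIDS, SequenceRecord
from .docking import DockingModel, EnergyComponents
from .geometry import rotate_about_axis
from .structure import AtomRecord, RecordClass, Structure
from .symcluster import Axis
from .trajloc import ATOM_SETS, CompartmentParams

__all__ = [
    "GroundTruth",
    "gen_docking_ensemble",
    "gen_trajectory",
    "gen_localization_dataset",
    "gen_channel_structure",
    "gen_family",
    "build_toy_receptor",
    "build_toy_ligand",
]

import pandas as pd


@dataclass
class GroundTruth:
    """Planted parameters of one generator run, serializable as JSON."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    planted: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not JSON serializable: {type(o)}")

        text = json.dumps(
            {
                "generator": self.generator,
                "seed": self.seed,
                "params": self.params,
                "planted": self.planted,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
            default=default,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source: str | Path) -> "GroundTruth":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return GroundTruth(
            generator=data["generator"],
            seed=data["seed"],
            params=data.get("params", {}),
            planted=data.get("planted", {}),
            warnings=data.get("warnings", []),
        )


# ---------------------------------------------------------------------------
# docking ensembles
# ---------------------------------------------------------------------------

RECEPTOR_CHAINS = ("A", "B", "C", "D", "E")
LIGAND_CHAINS = ("X", "Y")


def build_toy_receptor(
    n_fold: int = 5,
    ring_radius: float = 15.0,
    rings_per_protomer: int = 3,
    atoms_per_ring: int = 10,
    ring_spacing: float = 4.0,
) -> list[AtomRecord]:
    """Cn toy receptor: per protomer, stacked arcs of CA pseudo-atoms.

    The atom positions are exactly invariant (as a point set) under
    rotation by 360/n about the z axis, so a symmetry rotation of a
    docked ligand is geometrically indistinguishable from redocking at
    the neighboring protomer.
    """
    chains = RECEPTOR_CHAINS[:n_fold] if n_fold <= 5 else tuple(
        chr(ord("A") + i) for i in range(n_fold)
    )
    atoms: list[AtomRecord] = []
    sector = 360.0 / n_fold
    for p, chain in enumerate(chains):
        for r in range(rings_per_protomer):
            for j in range(atoms_per_ring):
                angle = np.deg2rad(p * sector + (j + 0.5) * sector / atoms_per_ring)
                atoms.append(
                    AtomRecord(
                        chain_id=chain,
                        residue_number=r * atoms_per_ring + j + 1,
                        residue_name="GLY",
                        atom_name="CA",
                        element="C",
                        position=np.array(
                            [ring_radius * np.cos(angle), ring_radius * np.sin(angle),
                             r * ring_spacing]
                        ),
                        record_class=RecordClass.PROTEIN,
                    )
                )
    return atoms


def build_toy_ligand(atoms_per_chain: int = 20) -> list[AtomRecord]:
    """C2-symmetric toy homodimer: chain Y is chain X rotated 180° about z.

    Because the two chains are exact 180° images, swapping the chain
    blocks equals a physical half-turn of the dimer — the flip
    correspondence used in symmetry-aware RMSD is geometrically exact.
    """
    atoms: list[AtomRecord] = []
    chain_x = []
    for t in range(atoms_per_chain):
        chain_x.append(
            np.array([4.0 + 2.5 * np.cos(0.6 * t), 2.5 * np.sin(0.6 * t), 0.9 * t - 8.0])
        )
    for chain, flip in ((LIGAND_CHAINS[0], False), (LIGAND_CHAINS[1], True)):
        for t, pos in enumerate(chain_x):
            p = np.array([-pos[0], -pos[1], pos[2]]) if flip else pos
            atoms.append(
                AtomRecord(
                    chain_id=chain,
                    residue_number=t + 1,
                    residue_name="ALA",
                    atom_name="CA",
                    element="C",
                    position=p,
                    record_class=RecordClass.PROTEIN,
                )
            )
    return atoms


def _default_prototype_poses(n_clusters: int) -> list[tuple[float, float, float, float]]:
    """(radial distance, azimuth deg, z, spin deg) for each cluster prototype.

    Prototypes are placed at distinct distances from the symmetry axis so
    that no symmetry rotation or flip can bring two different prototypes
    within clustering distance of each other.
    """
    poses = []
    for c in range(n_clusters):
        poses.append((8.0 + 27.0 * c + 15.0 * max(0, c - 1), 30.0 * c, -14.0 - 6.0 * c, 40.0 * c))
    return poses


def _pose_ligand(
    ligand: list[AtomRecord],
    radial: float,
    azimuth_deg: float,
    z: float,
    spin_deg: float,
) -> np.ndarray:
    coords = np.array([a.position for a in ligand])
    coords = rotate_about_axis(coords, np.array([0.0, 0.0, 1.0]), spin_deg, np.zeros(3))
    az = np.deg2rad(azimuth_deg)
    return coords + np.array([radial * np.cos(az), radial * np.sin(az), z])


_ENERGY_PROFILES = {
    # cluster index -> (mean, sd) per component; singletons use the "noise" row
    "cluster": lambda c: {
        "hs": (-120.0 + 18.0 * c, 5.0),
        "e_vdw": (-52.0 - 4.0 * c, 4.0),
        "e_elec": (-210.0 + 25.0 * c, 15.0),
        "e_desolv": (-12.0 + 2.0 * c, 3.0),
        "e_air": (120.0 + 60.0 * c, 20.0),
        "bsa": (1850.0 - 120.0 * c, 80.0),
    },
    "noise": {
        "hs": (-55.0, 12.0),
        "e_vdw": (-30.0, 6.0),
        "e_elec": (-90.0, 25.0),
        "e_desolv": (-5.0, 4.0),
        "e_air": (400.0, 80.0),
        "bsa": (1100.0, 150.0),
    },
}


def _sample_energies(rng: np.random.Generator, profile: dict) -> EnergyComponents:
    values = {}
    for name, (mean, sd) in profile.items():
        v = float(rng.normal(mean, sd))
        if name == "bsa":
            v = abs(v)
        values[name] = v
    return EnergyComponents(**values)


def gen_docking_ensemble(
    cluster_sizes: Sequence[int] = (45, 111),
    n_noise: int = 44,
    n_fold: int = 5,
    noise_sigma: float = 1.0,
    flip_prob: float = 0.5,
    seed: int = 0,
    jitter_rigid: bool = True,
) -> tuple[list[DockingModel], GroundTruth]:
    """Docking ensemble with planted cluster membership.

    Each model is a cluster prototype pose (or, for the ``n_noise``
    models, its own well-separated singleton pose) perturbed by Gaussian
    coordinate noise, rotated to a uniformly random receptor symmetry
    point, chain-flipped with probability ``flip_prob``, and given a
    random small rigid-body motion of the whole complex. Energy
    components are drawn from per-cluster normal distributions. Planted
    labels (singletons = -1), symmetry steps and flips are recorded in
    the ground truth. The default sizes (45, 111) plus 44 singletons give
    a 200-model ensemble.
    """
    if any(s < 1 for s in cluster_sizes):
        raise ValueError("cluster sizes must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    receptor = build_toy_receptor(n_fold=n_fold)
    ligand = build_toy_ligand()
    proto_defs = _default_prototype_poses(len(cluster_sizes))
    proto_coords = [_pose_ligand(ligand, *p) for p in proto_defs]

    gt_warnings: list[str] = []
    centroids = [c.mean(axis=0) for c in proto_coords]
    for i in range(len(centroids)):
        for j in range(i + 1, len(centroids)):
            if np.linalg.norm(centroids[i] - centroids[j]) < 3.0 * max(noise_sigma, 1e-9):
                msg = f"prototypes {i} and {j} closer than 3x noise sigma"
                warnings.warn(msg)
                gt_warnings.append(msg)

    z_axis = np.array([0.0, 0.0, 1.0])
    models: list[DockingModel] = []
    labels: list[int] = []
    sym_steps: list[int] = []
    flips: list[bool] = []
    model_id = 0

    def emit(lig_coords: np.ndarray, label: int, energies: EnergyComponents) -> None:
        nonlocal model_id
        rec_coords = np.array([a.position for a in receptor])
        k = int(rng.integers(n_fold))
        lig = rotate_about_axis(lig_coords, z_axis, k * 360.0 / n_fold, np.zeros(3))
        flip = bool(rng.random() < flip_prob)
        if flip:
            half = len(lig) // 2
            lig = np.vstack([lig[half:], lig[:half]])
        rec = rec_coords + rng.normal(0.0, noise_sigma, rec_coords.shape)
        lig = lig + rng.normal(0.0, noise_sigma, lig.shape)
        if jitter_rigid:
            axis_dir = rng.normal(size=3)
            axis_dir /= np.linalg.norm(axis_dir)
            angle = float(rng.uniform(-8.0, 8.0))
            shift = rng.uniform(-4.0, 4.0, size=3)
            rec = rotate_about_axis(rec, axis_dir, angle, np.zeros(3)) + shift
            lig = rotate_about_axis(lig, axis_dir, angle, np.zeros(3)) + shift
        atoms = []
        for a, p in zip(receptor, rec):
            atoms.append(AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                                    a.atom_name, a.element, p, a.record_class))
        for a, p in zip(ligand, lig):
            atoms.append(AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                                    a.atom_name, a.element, p, a.record_class))
        models.append(
            DockingModel(
                structure=Structure(atoms, id=f"model_{model_id:04d}"),
                energies=energies,
                model_id=model_id,
                receptor_chains=RECEPTOR_CHAINS[:n_fold],
                ligand_chains=LIGAND_CHAINS,
            )
        )
        labels.append(label)
        sym_steps.append(k)
        flips.append(flip)
        model_id += 1

    for c, size in enumerate(cluster_sizes):
        profile = _ENERGY_PROFILES["cluster"](c)
        for _ in range(size):
            emit(proto_coords[c], c, _sample_energies(rng, profile))
    for s in range(n_noise):
        # singleton poses separated in z at constant radius: no symmetry
        # rotation or flip can bring two of them within clustering range
        az = float(rng.uniform(0.0, 360.0))
        lig = _pose_ligand(ligand, 60.0, az, -40.0 - 12.0 * s, float(rng.uniform(0, 360)))
        emit(lig, -1, _sample_energies(rng, _ENERGY_PROFILES["noise"]))

    truth = GroundTruth(
        generator="docking_ensemble",
        seed=seed,
        params={
            "cluster_sizes": list(cluster_sizes),
            "n_noise": n_noise,
            "n_fold": n_fold,
            "noise_sigma": noise_sigma,
            "flip_prob": flip_prob,
            "prototype_poses": [list(p) for p in proto_defs],
        },
        planted={"labels": labels, "symmetry_steps": sym_steps, "flips": flips},
        warnings=gt_warnings,
    )
    return models, truth


def canonical_axis() -> Axis:
    """Symmetry axis of the un-jittered toy receptor (z axis through origin)."""
    return Axis(np.zeros(3), np.array([0.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

#: representative z (first-system frame) at the middle of each compartment,
#: and the slab half-width available for jitter
_COMPARTMENT_SLABS = {
    "periplasm": (26.0, 5.0),
    "outer periplasmic membrane": (18.0, 3.0),
    "inner periplasmic membrane": (10.0, 5.0),
    "central membrane": (0.0, 5.0),
    "inner cytoplasmic membrane": (-10.0, 5.0),
    "outer cytosolic membrane": (-18.0, 3.0),
    "cytoplasm": (-26.0, 5.0),
}

_SUBSTRATE_OFFSETS = {
    # fixed, zero-sum offsets so the center of geometry equals the scripted
    # position exactly
    "C1": np.array([0.0, 0.0, 0.0]),
    "O2": np.array([0.6, 0.35, 0.0]),
    "O3": np.array([-0.6, -0.35, 0.0]),
}


def gen_trajectory(
    script: Sequence[tuple[str, int]],
    noise_sigma: float = 0.0,
    radial_offset: float = 0.0,
    seed: int = 0,
    replicate: str = "rep1",
    segment: str = "SUB1",
    system: int = 1,
    params: CompartmentParams | None = None,
    frame_start: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Substrate trajectory following a scripted compartment dwell sequence.

    Each script entry (compartment, n_frames) emits that many frames with
    the substrate center of geometry at the compartment's mid-z plus
    Gaussian jitter clipped to stay inside the scripted slab. ``system=2``
    emits coordinates mirrored into the second membrane system
    (z -> 2*fold_center - z), i.e. un-folded, so the folding stage is
    exercised. ``radial_offset`` sets the substrate's distance from the
    box axis; > 40 Å places it outside the protein cylinder.
    """
    params = params or CompartmentParams()
    rng = np.random.default_rng(seed)
    bad = [c for c, _ in script if c not in _COMPARTMENT_SLABS]
    if bad:
        raise ValueError(f"unknown compartments in script: {bad}")
    if any(n < 1 for _, n in script):
        raise ValueError("script frame counts must be >= 1")
    rows = []
    frame = frame_start
    for compartment, n_frames in script:
        mid_z, half = _COMPARTMENT_SLABS[compartment]
        if noise_sigma > half:
            raise ValueError(
                f"noise_sigma {noise_sigma} exceeds the {compartment!r} slab half-width {half}"
            )
        for _ in range(n_frames):
            dz = float(np.clip(rng.normal(0.0, noise_sigma), -half + 1e-6, half - 1e-6)) \
                if noise_sigma > 0 else 0.0
            az = rng.uniform(0, 2 * np.pi) if noise_sigma > 0 else 0.0
            cx = radial_offset * np.cos(az)
            cy = radial_offset * np.sin(az)
            cz = mid_z + dz
            if system == 2:
                cz = 2.0 * params.fold_center_z - cz
            for atom_name, offset in _SUBSTRATE_OFFSETS.items():
                rows.append(
                    {
                        "replicate": replicate,
                        "frame": frame,
                        "segment": segment,
                        "residue_number": 1,
                        "residue_name": "FORA",
                        "atom_name": atom_name,
                        "x": cx + offset[0],
                        "y": cy + offset[1],
                        "z": cz + offset[2],
                    }
                )
            frame += 1
    total = sum(n for _, n in script)
    expected = {c: 0.0 for c in _COMPARTMENT_SLABS}
    for compartment, n_frames in script:
        expected[compartment] += n_frames / total
    truth = GroundTruth(
        generator="trajectory",
        seed=seed,
        params={
            "script": [[c, int(n)] for c, n in script],
            "noise_sigma": noise_sigma,
            "radial_offset": radial_offset,
            "replicate": replicate,
            "segment": segment,
            "system": system,
        },
        planted={"occupancy": expected},
    )
    return pd.DataFrame(rows), truth


def gen_localization_dataset(
    script: Sequence[tuple[str, int]],
    n_replicates: int = 3,
    n_channels: int = 5,
    noise_sigma: float = 0.0,
    seed: int = 0,
    params: CompartmentParams | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """The full study-scale scenario: one script run per (replicate, channel).

    With the defaults this yields 5 protomer channels x 3 replicates
    = 15 independent observations, alternating between the two membrane
    systems so folding is exercised.
    """
    tables = []
    rng = np.random.default_rng(seed)
    for r in range(n_replicates):
        for c in range(n_channels):
            table, _ = gen_trajectory(
                script,
                noise_sigma=noise_sigma,
                seed=int(rng.integers(2**31 - 1)),
                replicate=f"rep{r + 1}",
                segment=f"SUB{c + 1}",
                system=1 if c % 2 == 0 else 2,
                params=params,
            )
            tables.append(table)
    total = sum(n for _, n in script)
    expected = {c: 0.0 for c in _COMPARTMENT_SLABS}
    for compartment, n_frames in script:
        expected[compartment] += n_frames / total
    truth = GroundTruth(
        generator="localization_dataset",
        seed=seed,
        params={
            "script": [[c, int(n)] for c, n in script],
            "n_replicates": n_replicates,
            "n_channels": n_channels,
            "noise_sigma": noise_sigma,
        },
        planted={
            "occupancy": expected,
            "n_observations": n_replicates * n_channels,
        },
    )
    return pd.concat(tables, ignore_index=True), truth


# ---------------------------------------------------------------------------
# channel structures
# ---------------------------------------------------------------------------


def gen_channel_structure(
    radius_fn: Callable[[float], float],
    length: float = 20.0,
    ring_spacing: float = 1.0,
    atoms_per_ring: int = 12,
    side_chain_delta: float = 1.5,
    gate: tuple[float, str] | None = None,
    gate_depth: float = 1.0,
    gate_atoms: int = 2,
    polarity_layout: Sequence[str] | None = None,
    anchor_residues: tuple[int, int] = (155, 22),
    seed: int = 0,
) -> tuple[Structure, GroundTruth]:
    """Tubular toy pore whose probe radius follows ``radius_fn``.

    ``radius_fn`` prescribes the *probe* radius (clearance), not the
    atom-center wall radius: wall atoms sit at ``radius_fn(s) + vdW``.
    Wall rings are stacked every ``ring_spacing`` Å along z from 0 to
    ``length``. Each interior wall position is one residue: its CB
    side-chain atom forms the inner wall at ``radius_fn(s) + vdW`` and
    its CA main-chain atom sits ``side_chain_delta`` further out, so the
    profiled all-atom radius is radius_fn(s) and the free radius
    radius_fn(s) + side_chain_delta. Glycine rings (or
    ``side_chain_delta = 0``) put the main chain itself on the inner
    wall, collapsing the local dynamic range to zero.
    The first and last rings are single anchor residues (numbers
    ``anchor_residues``) whose centroids sit on the pore axis, giving the
    tracer exact endpoints. ``gate=(s_gate, resname)`` plants two
    opposing constriction atoms of that residue name, ``gate_depth`` Å
    deeper into the pore, at the ring nearest ``s_gate``.
    ``polarity_layout`` names the residue per interior ring (default all
    GLY = hydrophobic).
    """
    if length <= 0 or ring_spacing <= 0:
        raise ValueError("length and ring_spacing must be positive")
    n_rings = int(round(length / ring_spacing)) + 1
    s_values = [r * ring_spacing for r in range(n_rings)]
    for s in s_values:
        if radius_fn(s) < 0.5:
            raise ValueError(f"radius_fn({s}) < 0.5 Å: below probe feasibility")
    if polarity_layout is not None and len(polarity_layout) != n_rings - 2:
        raise ValueError(
            f"polarity_layout must name the {n_rings - 2} interior rings"
        )
    vdw_c = 1.70
    atoms: list[AtomRecord] = []

    def ring_positions(s: float, wall_radius: float) -> list[np.ndarray]:
        return [
            np.array(
                [wall_radius * np.cos(2 * np.pi * j / atoms_per_ring),
                 wall_radius * np.sin(2 * np.pi * j / atoms_per_ring), s]
            )
            for j in range(atoms_per_ring)
        ]

    # anchor rings: one residue each, centroid on the axis
    for ring_idx, resnum in ((0, anchor_residues[0]), (n_rings - 1, anchor_residues[1])):
        s = s_values[ring_idx]
        for j, pos in enumerate(ring_positions(s, radius_fn(s) + vdw_c)):
            atoms.append(
                AtomRecord("A", resnum, "GLY", f"C{j + 1}", "C", pos, RecordClass.PROTEIN)
            )

    layout = list(polarity_layout) if polarity_layout is not None else ["ALA"] * (n_rings - 2)
    planted_polarity = []
    planted_free = []
    resnum_base = 1000
    for r in range(1, n_rings - 1):
        s = s_values[r]
        resname = layout[r - 1]
        planted_polarity.append(resname)
        # glycine has no side chain: its main chain forms the inner wall and
        # the local dynamic range collapses to zero
        has_side_chain = side_chain_delta > 0 and resname != "GLY"
        delta = side_chain_delta if has_side_chain else 0.0
        planted_free.append([s, radius_fn(s) + delta])
        mc_positions = ring_positions(s, radius_fn(s) + delta + vdw_c)
        sc_positions = ring_positions(s, radius_fn(s) + vdw_c)
        for j in range(atoms_per_ring):
            resnum = resnum_base + r * atoms_per_ring + j
            atoms.append(
                AtomRecord("A", resnum, resname, "CA", "C", mc_positions[j],
                           RecordClass.PROTEIN)
            )
            if has_side_chain:
                atoms.append(
                    AtomRecord("A", resnum, resname, "CB", "C", sc_positions[j],
                               RecordClass.PROTEIN)
                )

    gate_planted = None
    if gate is not None:
        s_gate, gate_resname = gate
        ring_idx = min(range(n_rings), key=lambda r: abs(s_values[r] - s_gate))
        s = s_values[ring_idx]
        pinch_radius = radius_fn(s) - gate_depth + vdw_c
        if radius_fn(s) - gate_depth < 0.2:
            raise ValueError("gate_depth leaves no open pore at the gate station")
        # the pinch atoms alternate between two residues (the two opposing
        # gate side chains); gate_atoms=2 is the minimal opposing pair,
        # larger values close the constriction into a full ring
        for g in range(gate_atoms):
            phi = 2 * np.pi * g / gate_atoms
            atoms.append(
                AtomRecord(
                    "A", 9001 + g % 2, gate_resname, f"CZ{g + 1}", "C",
                    np.array([pinch_radius * np.cos(phi), pinch_radius * np.sin(phi), s]),
                    RecordClass.PROTEIN,
                )
            )
        gate_planted = {
            "s": s,
            "residues": [[gate_resname, 9001], [gate_resname, 9002]],
            "pinch_radius": radius_fn(s) - gate_depth,
        }

    structure = Structure(atoms, id="toy_pore")
    truth = GroundTruth(
        generator="channel_structure",
        seed=seed,
        params={
            "length": length,
            "ring_spacing": ring_spacing,
            "atoms_per_ring": atoms_per_ring,
            "side_chain_delta": side_chain_delta,
            "anchor_residues": list(anchor_residues),
        },
        planted={
            "radius_profile": [[s, radius_fn(s)] for s in s_values],
            "free_radius_profile": planted_free,
            "polarity_layout": planted_polarity,
            "gate": gate_planted,
        },
    )
    return structure, truth


def mainchain_twin(
    structure: Structure, keep_residues: Sequence[int] = (155, 22)
) -> Structure:
    """Main-chain-only copy of a toy pore (anchor rings retained).

    Profiling the twin's all-atom radius reproduces the original's free
    radius, which is how the free-radius bookkeeping is cross-checked.
    """
    keep = set(keep_residues)
    twin = structure.select(
        lambda a: a.atom_name in ("N", "CA", "C", "O") or a.residue_number in keep
    )
    twin.id = structure.id + "_mainchain"
    return twin


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------


def gen_family(
    ref: SequenceRecord,
    conservation: Sequence[float],
    n: int = 100,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Sequence family drawn from a per-column conservation vector.

    Each sequence copies the reference residue at column i with
    probability ``conservation[i]`` and otherwise substitutes a uniform
    different residue; columns are then deleted independently at
    ``indel_rate``. Per-sequence deletion positions are recorded so
    region gap statistics have an exact planted answer.
    """
    if len(conservation) != len(ref):
        raise ValueError("conservation vector length must match the reference")
    if any(not (0 < p <= 1) for p in conservation):
        raise ValueError("conservation probabilities must be in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= indel_rate < 1):
        raise ValueError("indel_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    alphabet = AMINO_ACIDS
    family: list[SequenceRecord] = []
    deletions: list[list[int]] = []
    for i in range(n):
        letters = []
        deleted: list[int] = []
        for pos, (ref_letter, p) in enumerate(zip(ref.residues, conservation)):
            if rng.random() < indel_rate:
                deleted.append(pos + 1)
                continue
            if rng.random() < p:
                letters.append(ref_letter)
            else:
                choices = alphabet.replace(ref_letter, "")
                letters.append(choices[int(rng.integers(len(choices)))])
        if not letters:
            letters = [ref.residues[0]]  # degenerate all-deleted draw
            deleted = deleted[:-1]
        family.append(SequenceRecord(f"syn{i:05d}", "".join(letters)))
        deletions.append(deleted)
    truth = GroundTruth(
        generator="family",
        seed=seed,
        params={"n": n, "indel_rate": indel_rate, "ref_id": ref.id},
        planted={
            "conservation": [float(p) for p in conservation],
            "deletions": deletions,
        },
    )
    return family, truth
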