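"""MD-trajectory substrate localization in a two-membrane simulation frame.

The simulation box holds two facing membrane systems (first membrane
centered at z = 0, second at z = -93), so the cytosolic space between
them is closed and the periplasmic space closes over the periodic
boundary. Folding mirrors the second system onto the first about the
midpoint z = -46.618 Å; a single descending chain of z thresholds then
classifies every substrate position into one of seven compartments
(periplasm, three membrane sublayers per side, cytoplasm).

Positions radially outside the protein cylinder (40 Å about the box
axis) that sit in the lipid headgroup band (|z| <= 21) are excluded and
counted as "Other"; replicates in which the substrate leaks across the
membrane outside the protein are dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import kabsch_superpose, paired_rmsd
from .structure import BACKBONE_ATOMS, Structure

__all__ = [
    "TRAJ_COLUMNS",
    "CompartmentParams",
    "LocalizationSummary",
    "MembraneComposition",
    "ATOM_SETS",
    "validate_trajectory",
    "center_of_geometry",
    "fold_coordinates",
    "classify_z",
    "apply_exclusions",
    "occupancy",
    "contacts",
    "rmsd_profiles",
    "leaflet_counts",
]

TRAJ_COLUMNS = (
    "replicate", "frame", "segment", "residue_number", "residue_name",
    "atom_name", "x", "y", "z",
)

#: named atom sets used for substrate / key-residue centers of geometry
ATOM_SETS: dict[str, tuple[str, ...]] = {
    "FORA": ("C1", "O2", "O3"),  # formate
    "FORH": ("C", "O2", "O3"),   # formic acid
    "RES209": ("C", "N", "CA", "O"),
}

COMPARTMENT_LABELS = (
    "periplasm",
    "outer periplasmic membrane",
    "inner periplasmic membrane",
    "central membrane",
    "inner cytoplasmic membrane",
    "outer cytosolic membrane",
    "cytoplasm",
)

OTHER_LABEL = "Other"


@dataclass(frozen=True)
class CompartmentParams:
    """Geometry of the two-membrane frame and its compartment classifier.

    ``boundaries``/``labels``: the descending z thresholds; z >= t_k gives
    label k, below all thresholds gives the final label. The printed
    analysis chain is symmetric about the membrane center:
    21/15/5/-5/-15/-21.
    ``fold_center_z``: midpoint between the two membrane centers (0 and
    -93) about which the second system is mirrored.
    ``cylinder_radius``/``cylinder_origin``: radial protein boundary.
    ``headgroup_zlim``: |z| band treated as lipid headgroups for the
    outside-protein exclusion.
    ``substrate_start_z``: initial substrate z in each system (near
    residue 209).
    """

    fold_center_z: float = -46.618
    boundaries: tuple[float, ...] = (21.0, 15.0, 5.0, -5.0, -15.0, -21.0)
    labels: tuple[str, ...] = COMPARTMENT_LABELS
    cylinder_radius: float = 40.0
    cylinder_origin: tuple[float, float] = (0.0, 0.0)
    headgroup_zlim: float = 21.0
    substrate_start_z: tuple[float, float] = (-3.14, -90.2)

    def __post_init__(self) -> None:
        b = self.boundaries
        if any(b[i] <= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"boundaries must be strictly descending, got {b}")
        if len(self.labels) != len(b) + 1:
            raise ValueError(
                f"need {len(b) + 1} labels for {len(b)} boundaries, got {len(self.labels)}"
            )


@dataclass
class LocalizationSummary:
    """Per-(replicate, segment) compartment occupancy fractions."""

    fractions: pd.DataFrame  # index (replicate, segment), columns labels + Other
    n_observations: int
    dropped_replicates: list = field(default_factory=list)


@dataclass(frozen=True)
class MembraneComposition:
    """Lipid species of one leaflet with their literal copy numbers."""

    leaflet: str
    species: tuple[str, ...]
    ratio: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.species) != len(self.ratio):
            raise ValueError("species and ratio must have the same length")
        if any(int(r) != r or r <= 0 for r in self.ratio):
            raise ValueError("ratio entries must be positive integers")


#: E. coli inner-membrane stationary-phase composition used in the simulations
OUTER_LEAFLET = MembraneComposition(
    "outer",
    ("POPE", "PYPE", "OYPE", "PYPG", "PMPE", "QMPE", "PMPG"),
    (6, 17, 5, 7, 32, 8, 3),
)
INNER_LEAFLET = MembraneComposition(
    "inner",
    ("POPE", "PYPE", "OYPE", "PYPG", "PMPE", "QMPE", "PMPG"),
    (6, 17, 5, 12, 20, 8, 8),
)


def validate_trajectory(traj: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAJ_COLUMNS if c not in traj.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    if not np.all(np.isfinite(traj[["x", "y", "z"]].to_numpy(dtype=float))):
        raise ValueError("trajectory contains non-finite coordinates")
    if (traj["frame"] < 0).any():
        raise ValueError("frame indices must be non-negative")
    for (rep, seg), group in traj.groupby(["replicate", "segment"], sort=False):
        frames = group["frame"].to_numpy()
        if np.any(np.diff(frames) < 0):
            raise ValueError(
                f"frames not non-decreasing within replicate {rep!r} segment {seg!r}"
            )
    return traj


def center_of_geometry(
    traj: pd.DataFrame,
    atom_set: str | Sequence[str],
    groupby: Sequence[str] = ("replicate", "segment", "frame"),
) -> pd.DataFrame:
    """Unweighted per-frame mean position of a named atom set.

    ``atom_set`` is a key of :data:`ATOM_SETS` or an explicit tuple of
    atom names. The mean is arithmetic (not mass-weighted), matching the
    extraction procedure the trajectories are analyzed with. Raises if
    any group is missing one of the named atoms.
    """
    names = ATOM_SETS[atom_set] if isinstance(atom_set, str) else tuple(atom_set)
    sel = traj[traj["atom_name"].isin(names)]
    if sel.empty:
        raise ValueError(f"no atoms of set {names} in trajectory")
    counts = sel.groupby(list(groupby), sort=False)["atom_name"].nunique()
    bad = counts[counts < len(names)]
    if not bad.empty:
        key = bad.index[0]
        present = set(
            sel.set_index(list(groupby)).loc[[key], "atom_name"]
        )
        missing = set(names) - present
        raise ValueError(f"atoms {sorted(missing)} missing in group {key}")
    cog = sel.groupby(list(groupby), sort=False)[["x", "y", "z"]].mean().reset_index()
    return cog


def fold_coordinates(traj: pd.DataFrame, fold_center_z: float = -46.618) -> pd.DataFrame:
    """Mirror the second membrane system into the first system's frame.

    Rows with z < ``fold_center_z`` belong to the second system and are
    reflected via z' = 2*center - z; rows at or above the center are
    untouched. The reflection is an involution on the folded half and the
    identity on already-folded data, so applying the fold twice is safe.
    """
    out = traj.copy()
    z = out["z"].to_numpy(dtype=float)
    below = z < fold_center_z
    z = np.where(below, 2.0 * fold_center_z - z, z)
    out["z"] = z
    out["system"] = np.where(below, 2, 1)
    return out


def classify_z(
    z: float | np.ndarray, params: CompartmentParams | None = None
) -> str | np.ndarray:
    """Compartment label(s) for membrane-centered z coordinate(s).

    The first threshold t with z >= t yields its label; z below every
    threshold is cytoplasm. Total: every finite z gets exactly one label.
    """
    params = params or CompartmentParams()
    arr = np.asarray(z, dtype=float)
    conditions = [arr >= t for t in params.boundaries]
    out = np.select(conditions, params.labels[:-1], default=params.labels[-1])
    if np.ndim(z) == 0:
        return str(out[()])
    return out


def _bulk_code(labels: np.ndarray, params: CompartmentParams) -> np.ndarray:
    """+1 for periplasm, -1 for cytoplasm, 0 for membrane sublayers."""
    code = np.zeros(len(labels), dtype=int)
    code[labels == params.labels[0]] = 1
    code[labels == params.labels[-1]] = -1
    return code


def _has_outside_crossing(
    z: np.ndarray, outside: np.ndarray, params: CompartmentParams
) -> bool:
    """True if the path crosses cytoplasm <-> periplasm with every membrane-band
    frame of the traversal lying outside the protein cylinder."""
    labels = classify_z(z, params)
    code = _bulk_code(labels, params)
    in_band = np.abs(z) <= params.headgroup_zlim
    last_bulk = 0
    saw_inside_band = False  # traversal frame in the band, inside the cylinder
    saw_outside = False  # any outside-cylinder frame along the traversal
    for i in range(len(z)):
        if code[i] != 0:
            if (
                last_bulk != 0
                and code[i] != last_bulk
                and (saw_outside or outside[i])
                and not saw_inside_band
            ):
                return True
            last_bulk = code[i]
            saw_inside_band = False
            saw_outside = bool(outside[i])
        else:
            if in_band[i] and not outside[i]:
                saw_inside_band = True
            if outside[i]:
                saw_outside = True
    return False


def apply_exclusions(
    traj: pd.DataFrame, params: CompartmentParams | None = None
) -> tuple[pd.DataFrame, np.ndarray, list]:
    """Headgroup/outside-protein exclusion and membrane-leak replicate removal.

    Expects a folded substrate-position table (one row per replicate,
    segment, frame). Returns (filtered table, excluded-row mask aligned to
    the input order, dropped replicate ids). A row is excluded — and later
    counted as "Other" — when it lies radially outside the protein
    cylinder and within the lipid headgroup band |z| <= headgroup_zlim.
    A replicate is dropped entirely when any of its substrate paths
    crosses cytoplasm <-> periplasm while outside the protein (membrane
    leakage); permeation through the pore is retained.
    """
    params = params or CompartmentParams()
    traj = traj.reset_index(drop=True)
    x = traj["x"].to_numpy(dtype=float) - params.cylinder_origin[0]
    y = traj["y"].to_numpy(dtype=float) - params.cylinder_origin[1]
    z = traj["z"].to_numpy(dtype=float)
    outside = np.sqrt(x * x + y * y) > params.cylinder_radius
    excluded = outside & (np.abs(z) <= params.headgroup_zlim)

    dropped: list = []
    for rep, rep_group in traj.groupby("replicate", sort=False):
        for _, seg_group in rep_group.groupby("segment", sort=False):
            idx = seg_group.sort_values("frame").index.to_numpy()
            if _has_outside_crossing(z[idx], outside[idx], params):
                dropped.append(rep)
                break
    kept = traj[~excluded & ~traj["replicate"].isin(dropped)]
    if dropped and kept.empty:
        raise ValueError("all replicates dropped by the membrane-crossing filter")
    return kept, excluded, dropped


def occupancy(
    traj: pd.DataFrame,
    params: CompartmentParams | None = None,
    excluded: np.ndarray | None = None,
    dropped_replicates: Sequence | None = None,
) -> LocalizationSummary:
    """Compartment occupancy fractions per (replicate, segment) observation.

    ``traj`` is the folded substrate-position table *before* exclusion;
    ``excluded`` (from :func:`apply_exclusions`) marks rows counted as
    "Other". Fractions over the 7 compartments plus "Other" sum to 1 for
    every observation; one observation = one channel (segment) in one
    replicate, e.g. 5 protomers x 3 replicates = 15.
    """
    params = params or CompartmentParams()
    traj = traj.reset_index(drop=True)
    if traj.empty:
        raise ValueError("no frames to summarize")
    if excluded is None:
        excluded = np.zeros(len(traj), dtype=bool)
    dropped = set(dropped_replicates or ())
    work = traj[~traj["replicate"].isin(dropped)].copy()
    if work.empty:
        raise ValueError("no frames left after dropping replicates")
    labels = classify_z(work["z"].to_numpy(dtype=float), params)
    labels = np.where(excluded[work.index.to_numpy()], OTHER_LABEL, labels)
    work["compartment"] = labels
    all_labels = list(params.labels) + [OTHER_LABEL]
    counts = (
        work.groupby(["replicate", "segment"])["compartment"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=all_labels, fill_value=0)
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return LocalizationSummary(
        fractions=fractions,
        n_observations=len(fractions),
        dropped_replicates=sorted(dropped),
    )


def contacts(
    substrate: pd.DataFrame,
    protein: pd.DataFrame,
    cutoff: float = 4.0,
) -> pd.DataFrame:
    """Per-residue substrate contact frequencies at an atomic distance cutoff.

    Atom pairs within ``cutoff`` Å produce a residue-level contact; a
    residue counts at most once per frame however many of its atoms touch
    the substrate. Frequency = contacting frames / total frames (over the
    frames present in ``substrate``). Returns a table
    (segment, residue_number, n_frames, frequency).
    """
    frames = sorted(substrate["frame"].unique())
    prot_frames = set(protein["frame"].unique())
    missing = [f for f in frames if f not in prot_frames]
    if missing:
        raise ValueError(f"protein coordinates missing for frames {missing[:5]}")
    counts: dict[tuple, int] = {}
    prot_by_frame = dict(tuple(protein.groupby("frame", sort=False)))
    sub_by_frame = dict(tuple(substrate.groupby("frame", sort=False)))
    for f in frames:
        sub_xyz = sub_by_frame[f][["x", "y", "z"]].to_numpy(dtype=float)
        prot = prot_by_frame[f]
        prot_xyz = prot[["x", "y", "z"]].to_numpy(dtype=float)
        tree = cKDTree(prot_xyz)
        hit_atoms = sorted({j for hits in tree.query_ball_point(sub_xyz, cutoff) for j in hits})
        if not hit_atoms:
            continue
        residues = set(
            zip(prot["segment"].to_numpy()[hit_atoms],
                prot["residue_number"].to_numpy()[hit_atoms])
        )
        for key in residues:
            counts[key] = counts.get(key, 0) + 1
    n_frames = len(frames)
    rows = [
        {"segment": seg, "residue_number": res, "n_frames": c, "frequency": c / n_frames}
        for (seg, res), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["segment", "residue_number", "n_frames", "frequency"])


def rmsd_profiles(
    traj: pd.DataFrame,
    reference: Structure,
    selection: frozenset[str] = BACKBONE_ATOMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Backbone RMSD time series and per-residue RMSD after a global fit.

    Each frame's selected atoms are superposed on the reference
    (minimizing the global backbone RMSD); the per-residue profile is the
    RMS deviation of each residue's selected atoms across all frames
    after that global fit. Returns (per-frame series, per-residue table).
    """
    ref_atoms = [a for a in reference.atoms if a.atom_name in selection]
    if not ref_atoms:
        raise ValueError("reference has no atoms in the selection")
    ref_keys = [(a.residue_number, a.atom_name) for a in ref_atoms]
    ref_xyz = np.array([a.position for a in ref_atoms])
    key_index = {k: i for i, k in enumerate(ref_keys)}

    sel = traj[traj["atom_name"].isin(selection)]
    series_rows = []
    sq_dev_sum = np.zeros(len(ref_keys))
    n_frames = 0
    for frame, group in sel.groupby("frame", sort=True):
        xyz = np.full((len(ref_keys), 3), np.nan)
        for res, name, x, y, z in zip(
            group["residue_number"], group["atom_name"],
            group["x"], group["y"], group["z"],
        ):
            i = key_index.get((res, name))
            if i is not None:
                xyz[i] = (x, y, z)
        if np.isnan(xyz).any():
            missing = [ref_keys[i] for i in np.nonzero(np.isnan(xyz).any(axis=1))[0][:3]]
            raise ValueError(f"frame {frame}: selection atoms missing, e.g. {missing}")
        transform, fitted = kabsch_superpose(xyz, ref_xyz)
        series_rows.append({"frame": frame, "rmsd": fitted})
        sq_dev_sum += np.sum((transform.apply(xyz) - ref_xyz) ** 2, axis=1)
        n_frames += 1
    if n_frames == 0:
        raise ValueError("no frames with selection atoms")

    per_atom_ms = sq_dev_sum / n_frames
    residues = sorted({res for res, _ in ref_keys})
    per_residue_rows = []
    for res in residues:
        idx = [i for i, (r, _) in enumerate(ref_keys) if r == res]
        per_residue_rows.append(
            {"residue_number": res, "rmsd": float(np.sqrt(per_atom_ms[idx].mean()))}
        )
    return pd.DataFrame(series_rows), pd.DataFrame(per_residue_rows)


def leaflet_counts(comp: MembraneComposition) -> tuple[dict[str, int], int]:
    """Literal per-species lipid counts and the leaflet total.

    The composition ratios are actual copy numbers (outer leaflet
    6:17:5:7:32:8:3 -> 78 lipids, inner 6:17:5:12:20:8:8 -> 76).
    """
    if not comp.ratio:
        raise ValueError("empty composition")
    counts = dict(zip(comp.species, (int(r) for r in comp.ratio)))
    return counts, int(sum(comp.ratio))
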