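"""Symmetry-agnostic clustering of docking poses against a Cn receptor.

Docking engines that treat a homo-oligomeric receptor as n distinct
chains produce ensembles in which physically identical ligand poses sit
at different symmetry points (and, for a homodimeric ligand, with the two
ligand chains swapped). Chain-ID-based alignment then scatters one pose
family over up to 2n apparent clusters. This module removes that
degeneracy:

1. models are rescored without the restraint-violation term and the
   best-scoring model becomes the reference;
2. every model is superposed on the reference via the receptor, and its
   ligand RMSD to the reference ligand is minimized over all n receptor
   symmetry rotations (360/n degree steps about the symmetry axis) and,
   optionally, the ligand chain-swap ("180° flip") correspondence;
3. the all-vs-all matrix of these symmetry-aware ligand RMSDs defines a
   similarity graph (edge iff RMSD <= cutoff, default 7.5 Å) whose
   connected components are the clusters, subject to a minimum size of
   max(ceil(frac * n_models), floor) with defaults 5% and 10.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .docking import DockingModel, EnergyComponents
from .geometry import kabsch_superpose, paired_rmsd, point_line_distance, rotate_about_axis

__all__ = [
    "SymClusterParams",
    "Axis",
    "ClusterResult",
    "DEFAULT_SCORE_WEIGHTS",
    "modified_score",
    "select_reference",
    "symmetry_angles",
    "estimate_symmetry_axis",
    "symaware_ligand_rmsd",
    "rmsd_matrix",
    "min_cluster_size",
    "graph_clusters",
    "cluster_summary",
    "ligand_axis_distance",
    "cluster_ensemble",
]

#: (w_vdw, w_elec, w_desolv, w_air) — the docking engine's water-refinement
#: weights with the restraint-violation term removed (w_air = 0).
DEFAULT_SCORE_WEIGHTS = (1.0, 0.2, 1.0, 0.0)

UNCLUSTERED = -1


@dataclass(frozen=True)
class Axis:
    """A line given by a point and a direction (need not be unit length)."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if p.shape != (3,) or d.shape != (3,):
            raise ValueError("axis point and direction must be 3-vectors")
        if np.linalg.norm(d) < 1e-12:
            raise ValueError("axis direction must be non-zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / np.linalg.norm(d))


@dataclass(frozen=True)
class SymClusterParams:
    """Knobs of the symmetry-aware clustering.

    ``n_fold``: receptor rotational symmetry order (5 for a pentamer).
    ``rmsd_cutoff``: similarity threshold on the ligand RMSD in Å.
    ``min_cluster_frac`` / ``min_cluster_floor``: a cluster must hold at
    least max(ceil(frac*n), floor) models; smaller components are left
    unclustered.
    ``allow_ligand_flip``: also try the swapped ligand-chain correspondence
    (exact for a C2-symmetric homodimer ligand).
    ``rmsd_atom_set``: atoms entering receptor superposition and ligand
    RMSD; CA by default.
    """

    n_fold: int = 5
    rmsd_cutoff: float = 7.5
    min_cluster_frac: float = 0.05
    min_cluster_floor: int = 10
    allow_ligand_flip: bool = True
    rmsd_atom_set: str = "CA"
    score_weights: tuple[float, float, float, float] = DEFAULT_SCORE_WEIGHTS

    def __post_init__(self) -> None:
        if self.n_fold < 1:
            raise ValueError("n_fold must be >= 1")
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be positive")
        if not (0 < self.min_cluster_frac < 1):
            raise ValueError("min_cluster_frac must be in (0, 1)")
        if self.min_cluster_floor < 1:
            raise ValueError("min_cluster_floor must be >= 1")
        if self.rmsd_atom_set not in ("CA", "backbone", "all"):
            raise ValueError("rmsd_atom_set must be CA, backbone or all")


@dataclass
class ClusterResult:
    reference_id: int
    labels: np.ndarray  # per-model cluster id, UNCLUSTERED (-1) outside clusters
    model_ids: list[int]
    cluster_sizes: list[int]  # descending, index = cluster id
    rmsd_matrix: np.ndarray
    comparison_count: int
    summaries: dict[int, dict[str, dict]] = field(default_factory=dict)


def modified_score(
    e: EnergyComponents,
    weights: Sequence[float] = DEFAULT_SCORE_WEIGHTS,
) -> float:
    """Linear rescoring w_vdw*Evdw + w_elec*Eelec + w_desolv*Edesolv + w_air*Eair.

    With the default weights the restraint-violation term drops out
    (w_air = 0), so a model lacking Eair remains scorable. Lower is better.
    """
    w_vdw, w_elec, w_desolv, w_air = weights
    required = {"e_vdw": w_vdw, "e_elec": w_elec, "e_desolv": w_desolv}
    total = 0.0
    for name, w in required.items():
        value = getattr(e, name)
        if value is None:
            raise ValueError(f"cannot score model: energy component {name} is absent")
        total += w * value
    if w_air != 0.0:
        if e.e_air is None:
            raise ValueError("cannot score model: energy component e_air is absent")
        total += w_air * e.e_air
    return total


def select_reference(
    models: Sequence[DockingModel],
    weights: Sequence[float] = DEFAULT_SCORE_WEIGHTS,
) -> int:
    """Model id of the best (lowest) modified score; ties -> lowest model_id."""
    if not models:
        raise ValueError("cannot select a reference from an empty ensemble")
    best = min(models, key=lambda m: (modified_score(m.energies, weights), m.model_id))
    return best.model_id


def symmetry_angles(n_fold: int) -> list[float]:
    """The n rotations (degrees) covering all symmetry points of a Cn receptor."""
    if n_fold < 1:
        raise ValueError("n_fold must be >= 1")
    return [k * 360.0 / n_fold for k in range(n_fold)]


def estimate_symmetry_axis(model: DockingModel) -> Axis:
    """Estimate the receptor Cn axis from the protomer centroids.

    The centroids of the receptor chains lie on a circle about the
    symmetry axis; the axis passes through their mean along the normal of
    their best-fit plane (the smallest-variance principal direction).
    """
    centroids = np.array(
        [model.structure.chain_coords(c).mean(axis=0) for c in model.receptor_chains]
    )
    if len(centroids) < 3:
        raise ValueError(
            "axis estimation needs >= 3 receptor chains; supply the axis explicitly"
        )
    center = centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids - center)
    return Axis(center, vt[-1])


def symaware_ligand_rmsd(
    model: DockingModel,
    reference: DockingModel,
    params: SymClusterParams,
    axis: Axis | None = None,
) -> float:
    """Minimum ligand RMSD over receptor symmetry rotations and ligand flips.

    The model is superposed onto the reference via the receptor atoms
    (``params.rmsd_atom_set``); the aligned ligand is then rotated about
    the reference symmetry axis by each angle in
    ``symmetry_angles(params.n_fold)`` and compared with the reference
    ligand under the identity and (if allowed) swapped chain
    correspondence. Always <= the naive (no-symmetry, no-flip) RMSD, which
    is the 0°/identity combination.

    ``axis`` must be the symmetry axis in the *reference* model's frame;
    ``None`` estimates it from the reference receptor.
    """
    if axis is None:
        axis = estimate_symmetry_axis(reference)
    rec_m = model.receptor_coords(params.rmsd_atom_set)
    rec_r = reference.receptor_coords(params.rmsd_atom_set)
    if rec_m.shape != rec_r.shape:
        raise ValueError(
            f"receptor atom counts differ between models {model.model_id} and "
            f"{reference.model_id}: {rec_m.shape[0]} vs {rec_r.shape[0]}"
        )
    transform, _ = kabsch_superpose(rec_m, rec_r)

    lig_ref = reference.ligand_coords(params.rmsd_atom_set)
    mappings = [False, True] if params.allow_ligand_flip and len(model.ligand_chains) == 2 else [False]
    best = math.inf
    for flipped in mappings:
        lig = transform.apply(model.ligand_coords(params.rmsd_atom_set, flipped=flipped))
        if lig.shape != lig_ref.shape:
            raise ValueError(
                f"ligand atom counts differ between models {model.model_id} and "
                f"{reference.model_id}: {lig.shape[0]} vs {lig_ref.shape[0]}"
            )
        for angle in symmetry_angles(params.n_fold):
            rotated = lig if angle == 0.0 else rotate_about_axis(
                lig, axis.direction, angle, center=axis.point
            )
            best = min(best, paired_rmsd(rotated, lig_ref))
    return best


def rmsd_matrix(
    models: Sequence[DockingModel],
    params: SymClusterParams,
    axis: Axis | None = None,
) -> tuple[np.ndarray, int]:
    """All-vs-all symmetry-aware ligand RMSD matrix and ordered-pair count.

    The matrix is symmetric with a zero diagonal; the reported comparison
    count is n*(n-1) ordered pairs (39800 for a 200-model ensemble).
    ``axis=None`` estimates each reference model's own symmetry axis from
    its receptor, which is the right thing when models carry independent
    rigid-body offsets; pass an explicit axis only for a common frame.
    """
    n = len(models)
    if n < 2:
        raise ValueError("rmsd_matrix needs at least 2 models")
    axes = [axis] * n if axis is not None else [estimate_symmetry_axis(m) for m in models]

    # Precompute per-model coordinate arrays and, per reference, the stack of
    # symmetry rotation operators — the per-pair work then reduces to one
    # receptor superposition and a vectorized RMSD over all angle/flip combos.
    from scipy.spatial.transform import Rotation as _Rotation

    angles = symmetry_angles(params.n_fold)
    rec, lig_id, lig_fl = [], [], []
    rot_stacks = []
    for m, ax in zip(models, axes):
        rec.append(m.receptor_coords(params.rmsd_atom_set))
        lig_id.append(m.ligand_coords(params.rmsd_atom_set, flipped=False))
        use_flip = params.allow_ligand_flip and len(m.ligand_chains) == 2
        lig_fl.append(m.ligand_coords(params.rmsd_atom_set, flipped=True) if use_flip else None)
        rot_stacks.append(
            np.stack([
                _Rotation.from_rotvec(np.deg2rad(a) * ax.direction).as_matrix()
                for a in angles
            ])
        )

    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rec[i].shape != rec[j].shape or lig_id[i].shape != lig_id[j].shape:
                raise ValueError(
                    f"pairwise RMSD failed for models "
                    f"({models[i].model_id}, {models[j].model_id}): atom counts differ"
                )
            try:
                transform, _ = kabsch_superpose(rec[i], rec[j])
            except ValueError as exc:
                raise ValueError(
                    f"pairwise RMSD failed for models "
                    f"({models[i].model_id}, {models[j].model_id}): {exc}"
                ) from exc
            point = axes[j].point
            rots = rot_stacks[j]  # (n_fold, 3, 3)
            candidates = [lig_id[i]] if lig_fl[i] is None else [lig_id[i], lig_fl[i]]
            best = math.inf
            for lig in candidates:
                moved = transform.apply(lig) - point
                # (n_fold, n_atoms, 3) rotated copies about the reference axis
                rotated = np.einsum("kab,nb->kna", rots, moved) + point
                d = rotated - lig_id[j][None, :, :]
                rms = np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))
                best = min(best, float(rms.min()))
            matrix[i, j] = matrix[j, i] = best
    return matrix, n * (n - 1)


def min_cluster_size(n_models: int, frac: float = 0.05, floor: int = 10) -> int:
    """Minimum retained-cluster size: max(ceil(frac * n), floor)."""
    return max(math.ceil(frac * n_models), floor)


def graph_clusters(
    matrix: np.ndarray,
    params: SymClusterParams,
    model_ids: Sequence[int] | None = None,
    reference_id: int = -1,
) -> ClusterResult:
    """Cluster a symmetric RMSD matrix by thresholded connected components.

    Two models are similar iff their RMSD <= ``params.rmsd_cutoff``; the
    connected components of the resulting graph are the clusters.
    Components smaller than :func:`min_cluster_size` are marked
    unclustered (label -1); retained clusters are relabeled 0, 1, ... by
    size descending (ties broken by smallest member index for stability).
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("RMSD matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-6):
        raise ValueError("RMSD matrix must be symmetric (tolerance 1e-6)")
    ids = list(model_ids) if model_ids is not None else list(range(n))
    if len(ids) != n:
        raise ValueError("model_ids length does not match matrix size")

    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    ii, jj = np.nonzero(matrix <= params.rmsd_cutoff)
    graph.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj) if i < j)

    min_size = min_cluster_size(n, params.min_cluster_frac, params.min_cluster_floor)
    components = [sorted(c) for c in nx.connected_components(graph)]
    retained = [c for c in components if len(c) >= min_size]
    retained.sort(key=lambda c: (-len(c), c[0]))

    labels = np.full(n, UNCLUSTERED, dtype=int)
    for cluster_id, members in enumerate(retained):
        labels[members] = cluster_id
    return ClusterResult(
        reference_id=reference_id,
        labels=labels,
        model_ids=ids,
        cluster_sizes=[len(c) for c in retained],
        rmsd_matrix=matrix,
        comparison_count=n * (n - 1),
    )


def _box_stats(values: np.ndarray) -> dict:
    """Box-plot statistics: quartiles, median, whiskers at the most extreme
    data points within 1.5 IQR of the box, plus the raw points."""
    values = np.asarray(values, dtype=float)
    q25, q50, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    if inside.size == 0:  # constant data has zero IQR; whiskers collapse
        inside = np.array([q50])
    return {
        "q25": float(q25),
        "median": float(q50),
        "q75": float(q75),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "points": [float(v) for v in values],
    }


def ligand_axis_distance(
    model: DockingModel,
    axis: Axis | None = None,
    marker_atom_names: Sequence[str] | None = None,
) -> float:
    """Minimum distance of the ligand marker atoms to the channel axis.

    ``marker_atom_names`` restricts the ligand atoms considered (e.g. a
    bound-cofactor selection); ``None`` uses every ligand atom. With
    ``axis=None`` the model's own receptor symmetry axis is used.
    """
    if axis is None:
        axis = estimate_symmetry_axis(model)
    atoms = model.ligand_atoms()
    if marker_atom_names is not None:
        wanted = set(marker_atom_names)
        atoms = [a for a in atoms if a.atom_name in wanted]
    if not atoms:
        raise ValueError("empty marker-atom selection")
    coords = np.array([a.position for a in atoms])
    return float(point_line_distance(coords, axis.point, axis.direction).min())


def cluster_summary(
    models: Sequence[DockingModel],
    labels: np.ndarray,
    axis: Axis | None = None,
) -> dict[int, dict[str, dict]]:
    """Per-cluster box statistics for each energy component and, when an
    axis is given, the ligand-to-axis distance.

    Returns {cluster_id: {component: box stats}}; clusters with no members
    are skipped with a warning, components absent from every member are
    omitted.
    """
    labels = np.asarray(labels)
    out: dict[int, dict[str, dict]] = {}
    for cluster_id in sorted(set(int(l) for l in labels if l != UNCLUSTERED)):
        members = [m for m, l in zip(models, labels) if l == cluster_id]
        if not members:
            warnings.warn(f"cluster {cluster_id} is empty; skipped")
            continue
        stats: dict[str, dict] = {}
        for component in ("hs", "e_vdw", "e_elec", "e_desolv", "bsa"):
            values = [getattr(m.energies, component) for m in members]
            present = [v for v in values if v is not None]
            if present:
                stats[component] = _box_stats(np.array(present))
        if axis is not None or isinstance(members[0], DockingModel):
            stats["axis_distance"] = _box_stats(
                np.array([ligand_axis_distance(m, axis) for m in members])
            )
        out[cluster_id] = stats
    return out


def cluster_ensemble(
    models: Sequence[DockingModel],
    params: SymClusterParams | None = None,
    axis: Axis | None = None,
) -> ClusterResult:
    """End-to-end clustering: reference selection, RMSD matrix, graph
    clustering and per-cluster summaries."""
    params = params or SymClusterParams()
    reference_id = select_reference(models, params.score_weights)
    matrix, _ = rmsd_matrix(models, params, axis)
    result = graph_clusters(
        matrix, params, model_ids=[m.model_id for m in models], reference_id=reference_id
    )
    result.summaries = cluster_summary(models, result.labels, axis=axis)
    return result
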