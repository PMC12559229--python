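"""Pore-radius and polarity profiling between two residue anchors.

For each station along the pore the profile records two radii: the
"radius" measured against all atoms and the "free radius" measured
against main-chain atoms only. Their difference — the dynamic channel
range — quantifies how far side chains protrude into the pore and hence
how much the effective pore width can vary with side-chain motion. A
spatial gate (e.g. the phenylalanine pair constricting an anion channel
towards the periplasm) shows up as a local radius minimum whose nearest
side-chain atoms belong to two distinct gate residues.

The path is initialized as the straight segment between the anchor
residue centroids; each interior station center is then relaxed within
the plane perpendicular to the local path direction to maximize the
all-atom clearance radius (coordinate pattern search, 0.01 Å
convergence). This is a deliberately simple tracer for near-straight
pores, not a Voronoi channel finder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .structure import BACKBONE_ATOMS, Structure

__all__ = [
    "DEFAULT_VDW_RADII",
    "DEFAULT_POLARITY_CLASSES",
    "ChannelProfileParams",
    "ChannelStation",
    "station_radius",
    "build_profile",
    "gate_detect",
    "polarity_profile",
]

DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}

_POSITIVE = {"ARG", "LYS", "HIS", "HSD", "HSE", "HSP", "HID", "HIE", "HIP"}
_NEGATIVE = {"ASP", "GLU"}
_HYDROPHILIC = {"SER", "THR", "ASN", "GLN", "TYR", "CYS"}

DEFAULT_POLARITY_CLASSES: dict[str, str] = {}
for _name in _POSITIVE:
    DEFAULT_POLARITY_CLASSES[_name] = "positive"
for _name in _NEGATIVE:
    DEFAULT_POLARITY_CLASSES[_name] = "negative"
for _name in _HYDROPHILIC:
    DEFAULT_POLARITY_CLASSES[_name] = "hydrophilic"
for _name in ("ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "TRP", "MET", "GLY"):
    DEFAULT_POLARITY_CLASSES[_name] = "hydrophobic"

POLARITY_CLASS_NAMES = ("positive", "negative", "hydrophilic", "hydrophobic")


@dataclass(frozen=True)
class ChannelProfileParams:
    """Channel tracing configuration.

    Anchors are (chain, residue) pairs; the defaults are the channel
    endpoints used for the pentameric formate channel (A155 periplasmic,
    A22 cytoplasmic) with a 1.0 Å bottleneck radius. ``station_step`` is
    the spacing of stations along the path, ``lining_shell`` the distance
    beyond the probe surface within which residues count as lining.
    """

    start_anchor: tuple[str, int] = ("A", 155)
    end_anchor: tuple[str, int] = ("A", 22)
    bottleneck_radius: float = 1.0
    station_step: float = 0.5
    vdw_radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    lining_shell: float = 3.0
    polarity_classes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_POLARITY_CLASSES)
    )

    def __post_init__(self) -> None:
        if self.bottleneck_radius <= 0:
            raise ValueError("bottleneck_radius must be positive")
        if self.station_step <= 0:
            raise ValueError("station_step must be positive")


@dataclass
class ChannelStation:
    s: float  # arclength from the start anchor, Å
    center: np.ndarray
    radius: float  # all-atom probe radius
    free_radius: float  # main-chain-only probe radius
    dynamic_range: float  # free_radius - radius
    lining: list[tuple[str, int, str]]  # (residue_name, residue_number, polarity class)
    blocked: bool = False


def _vdw_for(element: str, atom_name: str, vdw_radii: Mapping[str, float]) -> float:
    key = element if element in vdw_radii else atom_name[:1]
    if key not in vdw_radii:
        raise KeyError(f"no van der Waals radius for element {element!r} (atom {atom_name!r})")
    return vdw_radii[key]


def station_radius(
    center: np.ndarray,
    coords: np.ndarray,
    vdw: np.ndarray,
) -> float:
    """Clearance radius at ``center``: min over atoms of (distance - vdW), clamped at 0."""
    if len(coords) == 0:
        raise ValueError("no atoms to measure against")
    d = np.linalg.norm(coords - np.asarray(center, dtype=float), axis=1) - vdw
    return float(max(0.0, d.min()))


def _structure_arrays(
    structure: Structure, vdw_radii: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    coords = structure.coords()
    vdw = np.array([_vdw_for(a.element, a.atom_name, vdw_radii) for a in structure.atoms])
    mainchain = np.array([a.atom_name in BACKBONE_ATOMS for a in structure.atoms])
    return coords, vdw, mainchain, list(structure.atoms)


def _maximize_clearance(
    center: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    coords: np.ndarray,
    vdw: np.ndarray,
    tol: float = 0.01,
    initial_step: float = 1.0,
    max_iter: int = 200,
) -> np.ndarray:
    """Pattern search in the (u, v) plane maximizing the clearance radius."""
    best = np.asarray(center, dtype=float)
    best_r = station_radius(best, coords, vdw)
    step = initial_step
    iters = 0
    while step > tol and iters < max_iter:
        moved = False
        for d in (u, -u, v, -v):
            cand = best + step * d
            r = station_radius(cand, coords, vdw)
            if r > best_r + 1e-12:
                best, best_r = cand, r
                moved = True
        if not moved:
            step *= 0.5
        iters += 1
    return best


def _residue_centroid(structure: Structure, chain: str, residue: int) -> np.ndarray:
    pos = [
        a.position
        for a in structure.atoms
        if a.chain_id == chain and a.residue_number == residue
    ]
    if not pos:
        raise ValueError(f"anchor residue {chain}:{residue} not found in structure")
    return np.mean(pos, axis=0)


def build_profile(
    structure: Structure,
    params: ChannelProfileParams | None = None,
) -> list[ChannelStation]:
    """Trace the pore between the anchors and profile it station by station.

    Station centers start on the straight anchor-to-anchor segment and
    are relaxed perpendicular to it for maximal all-atom clearance
    (endpoints stay fixed). Per station: all-atom radius, main-chain free
    radius, dynamic range, lining residues (any atom surface within
    radius + lining_shell of the center) with polarity class, and a
    ``blocked`` flag where radius < bottleneck_radius.
    """
    params = params or ChannelProfileParams()
    start = _residue_centroid(structure, *params.start_anchor)
    end = _residue_centroid(structure, *params.end_anchor)
    length = float(np.linalg.norm(end - start))
    if length < params.station_step:
        raise ValueError("anchors are closer than one station step")

    coords, vdw, mainchain, atoms = _structure_arrays(structure, params.vdw_radii)
    if not mainchain.any():
        raise ValueError("structure has no main-chain atoms for the free radius")
    lo = coords.min(axis=0) - 5.0
    hi = coords.max(axis=0) + 5.0

    axis = (end - start) / length
    # in-plane basis perpendicular to the path, derived from the structure
    # itself (first atom with a usable perpendicular component) so the
    # whole search — and therefore the profile — is exactly covariant
    # under rigid motion of the input
    u = None
    for ref_pos in coords:
        perp = (ref_pos - start) - ((ref_pos - start) @ axis) * axis
        norm = np.linalg.norm(perp)
        if norm > 1e-6:
            u = perp / norm
            break
    if u is None:  # all atoms on the path axis; any perpendicular will do
        seed = np.array([1.0, 0.0, 0.0])
        if abs(axis @ seed) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        u = np.cross(axis, seed)
        u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    n_stations = int(np.floor(length / params.station_step + 1e-9)) + 1
    stations: list[ChannelStation] = []
    for k in range(n_stations):
        s = k * params.station_step
        center = start + s * axis
        if 0 < k < n_stations - 1:
            center = _maximize_clearance(center, u, v, coords, vdw)
        if np.any(center < lo) or np.any(center > hi):
            raise ValueError(f"station at s={s:.1f} escaped the structure bounding box")
        radius = station_radius(center, coords, vdw)
        free_radius = station_radius(center, coords[mainchain], vdw[mainchain])
        surface_dist = np.linalg.norm(coords - center, axis=1) - vdw
        lining_mask = surface_dist <= radius + params.lining_shell
        lining_res: dict[tuple[str, int], str] = {}
        for idx in np.nonzero(lining_mask)[0]:
            a = atoms[idx]
            key = (a.residue_name, a.residue_number)
            if key not in lining_res:
                cls = params.polarity_classes.get(a.residue_name)
                if cls is None:
                    raise KeyError(f"no polarity class for residue {a.residue_name!r}")
                lining_res[key] = cls
        stations.append(
            ChannelStation(
                s=s,
                center=center,
                radius=radius,
                free_radius=free_radius,
                dynamic_range=free_radius - radius,
                lining=[(name, num, cls) for (name, num), cls in sorted(lining_res.items())],
                blocked=radius < params.bottleneck_radius,
            )
        )
    return stations


def gate_detect(
    profile: Sequence[ChannelStation],
    structure: Structure,
    gate_residue: str = "PHE",
    vdw_radii: Mapping[str, float] | None = None,
    near_tol: float = 0.5,
) -> list[dict]:
    """Find spatial gates: radius local minima pinched by >= 2 gate residues.

    At each local minimum of the all-atom radius, the side-chain atoms
    (non-backbone) whose surfaces lie within ``near_tol`` Å of the
    closest one are collected; if they belong to at least two distinct
    residues named ``gate_residue``, the station is reported with those
    residues. Empty result when no gate exists.
    """
    vdw_radii = dict(DEFAULT_VDW_RADII) if vdw_radii is None else dict(vdw_radii)
    side_atoms = [a for a in structure.atoms if a.atom_name not in BACKBONE_ATOMS]
    if not side_atoms or len(profile) < 3:
        return []
    side_xyz = np.array([a.position for a in side_atoms])
    side_vdw = np.array([_vdw_for(a.element, a.atom_name, vdw_radii) for a in side_atoms])

    gates = []
    radii = np.array([st.radius for st in profile])
    for i in range(1, len(profile) - 1):
        if not (radii[i] < radii[i - 1] and radii[i] < radii[i + 1]):
            continue
        surface = np.linalg.norm(side_xyz - profile[i].center, axis=1) - side_vdw
        nearest = surface.min()
        pinchers = {
            (side_atoms[j].residue_name, side_atoms[j].residue_number)
            for j in np.nonzero(surface <= nearest + near_tol)[0]
        }
        gate_res = sorted(r for r in pinchers if r[0] == gate_residue)
        if len(gate_res) >= 2:
            gates.append({"station": i, "s": profile[i].s, "residues": gate_res})
    return gates


def polarity_profile(
    profile: Sequence[ChannelStation],
) -> list[dict]:
    """Per-station polarity-class fractions of the lining residues.

    A station is flagged amphipathic when its lining mixes hydrophobic
    with charged or hydrophilic residues.
    """
    out = []
    for st in profile:
        n = len(st.lining)
        fractions = {cls: 0.0 for cls in POLARITY_CLASS_NAMES}
        for _, _, cls in st.lining:
            fractions[cls] += 1.0
        if n:
            for cls in fractions:
                fractions[cls] /= n
        polar = fractions["positive"] + fractions["negative"] + fractions["hydrophilic"]
        out.append(
            {
                "s": st.s,
                "fractions": fractions,
                "amphipathic": polar > 0 and fractions["hydrophobic"] > 0,
            }
        )
    return out
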