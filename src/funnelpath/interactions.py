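"""Geometric detectors for typed ligand–protein interactions.

Five interaction types are monitored per frame: direct hydrogen bonds
(HB), water-mediated hydrogen bonds (HB_H2O), ionic contacts, cation-π
and π-π stacking.  Each detector is a pure function of coordinates and
:class:`DetectorParams`; all distance/angle cutoffs are inclusive, so a
pair exactly at a cutoff counts as interacting.

Hydrogen-bond geometry supports two modes: a heavy-atom criterion
(donor–acceptor distance only, the default, robust to structures without
explicit hydrogens) and an explicit-hydrogen criterion that additionally
requires the D–H···A angle to clear ``hb_angle_min``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .axis import AxisFrame
from .models import (
    ConfigError,
    EmptyInputError,
    GroupAnnotation,
    StructureModel,
    Trajectory,
)

__all__ = [
    "DetectorParams",
    "InteractionRecord",
    "InteractionTable",
    "detect_hbond",
    "detect_water_bridge",
    "detect_ionic",
    "detect_cation_pi",
    "detect_pi_pi",
    "scan_trajectory",
    "ring_centroid_normal",
]

INTERACTION_TYPES = ("HB", "HB_H2O", "ionic", "cation_pi", "pi_pi")


@dataclass(frozen=True)
class DetectorParams:
    """Geometric cutoffs of the five detectors (Å / degrees).

    Defaults follow common practice for contact analysis: H-bond
    donor–acceptor ≤ 3.5 Å (angle ≥ 120° when hydrogens are used), ionic
    N/O pair ≤ 4.0 Å, cation-π ≤ 6.0 Å within 45° of the ring normal,
    parallel π-π stacking ≤ 5.5 Å within 30° interplanar angle.
    """

    hb_da_max: float = 3.5
    hb_angle_min: float = 120.0
    ionic_max: float = 4.0
    catpi_dist_max: float = 6.0
    catpi_angle_max: float = 45.0
    pipi_centroid_max: float = 5.5
    pipi_angle_max: float = 30.0
    hb_use_hydrogens: bool = False

    def __post_init__(self) -> None:
        for name in ("hb_da_max", "ionic_max", "catpi_dist_max", "pipi_centroid_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("hb_angle_min", "catpi_angle_max", "pipi_angle_max"):
            v = getattr(self, name)
            if not 0 < v <= 180:
                raise ConfigError(f"{name} must lie in (0, 180]")


@dataclass(frozen=True)
class InteractionRecord:
    frame_index: int
    type: str
    ligand_part: str  # backbone | side_chain
    partner_residue: str  # chain:resnum:resname
    distance: float
    angle: float | None = None
    bridging_water: str | None = None


@dataclass
class InteractionTable:
    """Per-frame interaction records plus the ligand center-of-mass z track."""

    records: list
    com_z: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.com_z = np.asarray(self.com_z, dtype=float)
        if self.com_z.shape != (self.n_frames,):
            raise ConfigError("com_z length must equal n_frames")
        if not np.all(np.isfinite(self.com_z)):
            raise ConfigError("com_z contains non-finite values")
        for rec in self.records:
            if not 0 <= rec.frame_index < self.n_frames:
                raise ConfigError(f"record frame {rec.frame_index} out of range")

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "frame": r.frame_index,
                "type": r.type,
                "ligand_part": r.ligand_part,
                "partner": r.partner_residue,
                "bridging_water": r.bridging_water or "",
                "distance": r.distance,
                "angle": np.nan if r.angle is None else r.angle,
                "com_z": self.com_z[r.frame_index],
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "frame", "type", "ligand_part", "partner",
                "bridging_water", "distance", "angle", "com_z",
            ],
        )

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.4f")

    def presence(self) -> dict:
        """Boolean per-frame presence per key (type, ligand_part, partner)."""
        out: dict[tuple, np.ndarray] = {}
        for r in self.records:
            key = (r.type, r.ligand_part, r.partner_residue)
            if key not in out:
                out[key] = np.zeros(self.n_frames, dtype=bool)
            out[key][r.frame_index] = True
        return out


# ---------------------------------------------------------------------------
# geometry helpers


def ring_centroid_normal(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares ring plane: centroid and unit normal.

    Raises ``ValueError`` for degenerate (collinear) rings.
    """
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8:
        raise ValueError("degenerate ring plane")
    return centroid, vt[2]


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _polar_members(model: StructureModel, group: GroupAnnotation) -> list[int]:
    return [
        i for i in group.member_atom_ids
        if model.atom(i).element.upper() in ("N", "O")
    ]


def _ligand_part(model: StructureModel, group: GroupAnnotation) -> str:
    return (
        "backbone"
        if all(model.atom(i).is_backbone for i in group.member_atom_ids)
        else "side_chain"
    )


# ---------------------------------------------------------------------------
# detectors


def _hbond_geometry(
    pos: np.ndarray,
    model: StructureModel,
    donor: GroupAnnotation,
    acceptor: GroupAnnotation,
    params: DetectorParams,
) -> tuple[float, float | None] | None:
    """(distance, angle) of the qualifying D/A geometry, or None."""
    d_idx = model.index_of(donor.member_atom_ids[0])
    a_heavy = [model.index_of(i) for i in acceptor.member_atom_ids
               if model.atom(i).is_heavy]
    if not a_heavy:
        return None
    d_pos = pos[d_idx]
    dists = np.linalg.norm(pos[a_heavy] - d_pos, axis=1)
    k = int(np.argmin(dists))
    if dists[k] > params.hb_da_max:
        return None
    if not params.hb_use_hydrogens:
        return float(dists[k]), None
    hydrogens = [model.index_of(i) for i in donor.member_atom_ids[1:]]
    if not hydrogens:
        return None
    a_pos = pos[a_heavy[k]]
    best = None
    for h in hydrogens:
        ang = _angle_deg(d_pos - pos[h], a_pos - pos[h])
        if ang >= params.hb_angle_min and (best is None or ang > best):
            best = ang
    if best is None:
        return None
    return float(dists[k]), best


def detect_hbond(
    pos: np.ndarray,
    model: StructureModel,
    donor: GroupAnnotation,
    acceptor: GroupAnnotation,
    params: DetectorParams | None = None,
    frame_index: int = 0,
    ligand_group: GroupAnnotation | None = None,
) -> list[InteractionRecord]:
    """Direct hydrogen bond between a donor and an acceptor group."""
    params = params or DetectorParams()
    geom = _hbond_geometry(pos, model, donor, acceptor, params)
    if geom is None:
        return []
    lig = ligand_group if ligand_group is not None else donor
    partner = acceptor if lig is donor else donor
    return [
        InteractionRecord(
            frame_index=frame_index,
            type="HB",
            ligand_part=_ligand_part(model, lig),
            partner_residue=partner.residue_tag,
            distance=geom[0],
            angle=geom[1],
        )
    ]


def detect_water_bridge(
    pos: np.ndarray,
    model: StructureModel,
    ligand_group: GroupAnnotation,
    protein_group: GroupAnnotation,
    waters: list,
    params: DetectorParams | None = None,
    frame_index: int = 0,
) -> list[InteractionRecord]:
    """Water-mediated hydrogen bond: one water H-bonded to both partners.

    Both partners are polar groups (donor or acceptor); the water may act
    in either role, so the criterion is the heavy-atom H-bond distance
    from the water oxygen to each partner's polar heavy atom.  One record
    per bridging water.
    """
    params = params or DetectorParams()
    lig_heavy = [model.index_of(i) for i in ligand_group.member_atom_ids
                 if model.atom(i).is_heavy]
    pro_heavy = [model.index_of(i) for i in protein_group.member_atom_ids
                 if model.atom(i).is_heavy]
    records = []
    for water in waters:
        oxy = [model.index_of(i) for i in water.member_atom_ids
               if model.atom(i).element.upper() == "O"]
        if not oxy:
            continue
        w = pos[oxy[0]]
        d_lig = float(np.min(np.linalg.norm(pos[lig_heavy] - w, axis=1)))
        d_pro = float(np.min(np.linalg.norm(pos[pro_heavy] - w, axis=1)))
        if d_lig <= params.hb_da_max and d_pro <= params.hb_da_max:
            records.append(
                InteractionRecord(
                    frame_index=frame_index,
                    type="HB_H2O",
                    ligand_part=_ligand_part(model, ligand_group),
                    partner_residue=protein_group.residue_tag,
                    distance=max(d_lig, d_pro),
                    bridging_water=water.residue_tag,
                )
            )
    return records


def detect_ionic(
    pos: np.ndarray,
    model: StructureModel,
    cationic: GroupAnnotation,
    anionic: GroupAnnotation,
    params: DetectorParams | None = None,
    frame_index: int = 0,
    ligand_group: GroupAnnotation | None = None,
) -> list[InteractionRecord]:
    """Ionic contact: closest N/O pair between the charged groups ≤ cutoff."""
    params = params or DetectorParams()
    cat = [model.index_of(i) for i in _polar_members(model, cationic)]
    ani = [model.index_of(i) for i in _polar_members(model, anionic)]
    if not cat or not ani:
        return []
    d = np.linalg.norm(pos[cat][:, None, :] - pos[ani][None, :, :], axis=2)
    dmin = float(d.min())
    if dmin > params.ionic_max:
        return []
    lig = ligand_group if ligand_group is not None else cationic
    partner = anionic if lig is cationic else cationic
    return [
        InteractionRecord(
            frame_index=frame_index,
            type="ionic",
            ligand_part=_ligand_part(model, lig),
            partner_residue=partner.residue_tag,
            distance=dmin,
        )
    ]


def detect_cation_pi(
    pos: np.ndarray,
    model: StructureModel,
    cationic: GroupAnnotation,
    ring: GroupAnnotation,
    params: DetectorParams | None = None,
    frame_index: int = 0,
    ligand_group: GroupAnnotation | None = None,
) -> list[InteractionRecord]:
    """Cation-π contact: charge center near the ring face.

    Uses the group's designated charge-center atom (else the member
    centroid); requires centroid distance ≤ ``catpi_dist_max`` and an
    angle ≤ ``catpi_angle_max`` between the ring normal (sign chosen to
    minimize the angle) and the centroid→cation vector.
    """
    params = params or DetectorParams()
    if cationic.charge_center_id is not None:
        cation = pos[model.index_of(cationic.charge_center_id)]
    else:
        idx = [model.index_of(i) for i in cationic.member_atom_ids]
        cation = pos[idx].mean(axis=0)
    ring_pos = pos[[model.index_of(i) for i in ring.member_atom_ids]]
    try:
        centroid, normal = ring_centroid_normal(ring_pos)
    except ValueError:
        warnings.warn(f"{ring.residue_tag}: degenerate ring plane; skipped", stacklevel=2)
        return []
    v = cation - centroid
    dist = float(np.linalg.norm(v))
    if dist > params.catpi_dist_max or dist < 1e-9:
        return []
    ang = _angle_deg(v, normal)
    ang = min(ang, 180.0 - ang)
    if ang > params.catpi_angle_max:
        return []
    lig = ligand_group if ligand_group is not None else cationic
    partner = ring if lig is cationic else cationic
    return [
        InteractionRecord(
            frame_index=frame_index,
            type="cation_pi",
            ligand_part=_ligand_part(model, lig),
            partner_residue=partner.residue_tag,
            distance=dist,
            angle=ang,
        )
    ]


def detect_pi_pi(
    pos: np.ndarray,
    model: StructureModel,
    ring_a: GroupAnnotation,
    ring_b: GroupAnnotation,
    params: DetectorParams | None = None,
    frame_index: int = 0,
    ligand_group: GroupAnnotation | None = None,
) -> list[InteractionRecord]:
    """Parallel π-π stacking: close centroids, near-parallel ring planes.

    T-shaped stacking is deliberately out of scope.
    """
    params = params or DetectorParams()
    pa = pos[[model.index_of(i) for i in ring_a.member_atom_ids]]
    pb = pos[[model.index_of(i) for i in ring_b.member_atom_ids]]
    try:
        ca, na = ring_centroid_normal(pa)
        cb, nb = ring_centroid_normal(pb)
    except ValueError:
        warnings.warn("degenerate ring plane in pi-pi detection; skipped", stacklevel=2)
        return []
    dist = float(np.linalg.norm(ca - cb))
    if dist > params.pipi_centroid_max:
        return []
    ang = _angle_deg(na, nb)
    ang = min(ang, 180.0 - ang)
    if ang > params.pipi_angle_max:
        return []
    lig = ligand_group if ligand_group is not None else ring_a
    partner = ring_b if lig is ring_a else ring_a
    return [
        InteractionRecord(
            frame_index=frame_index,
            type="pi_pi",
            ligand_part=_ligand_part(model, lig),
            partner_residue=partner.residue_tag,
            distance=dist,
            angle=ang,
        )
    ]


# ---------------------------------------------------------------------------
# trajectory scan


def _candidate_residues(
    traj: Trajectory, candidate_distance: float
) -> set:
    """Protein residues with any atom within the cutoff of the ligand in any frame."""
    model = traj.model
    lig_idx = model.selection_indices("ligand")
    pro_idx = model.selection_indices("protein")
    tags = [model.atoms[i].residue_tag for i in pro_idx]
    found: set[str] = set()
    from scipy.spatial import cKDTree

    for frame in traj.frames:
        tree = cKDTree(frame[lig_idx])
        d, _ = tree.query(frame[pro_idx], k=1)
        for t, di in zip(tags, d):
            if di <= candidate_distance:
                found.add(t)
    return found


def scan_trajectory(
    traj: Trajectory,
    axis: AxisFrame,
    params: DetectorParams | None = None,
    candidate_residues: set | None = None,
    candidate_distance: float = 8.0,
) -> InteractionTable:
    """Apply all five detectors over every frame of a trajectory.

    Protein partner groups are restricted to ``candidate_residues``
    (default: residues coming within ``candidate_distance`` Å of the
    ligand in at least one frame).  Ligand-side groups determine
    ``ligand_part`` (backbone vs side chain); the per-frame mass-weighted
    ligand center of mass is projected onto the axis as ``com_z``.
    """
    params = params or DetectorParams()
    model = traj.model
    if not model.ligand_selection:
        raise EmptyInputError("model has no ligand selection")

    if candidate_residues is None:
        candidate_residues = _candidate_residues(traj, candidate_distance)

    lig_ids = model.ligand_selection
    pro_ids = model.protein_selection

    def lig_groups(kind):
        return model.groups_of_kind(kind, within=lig_ids)

    def pro_groups(kind):
        return [
            g for g in model.groups_of_kind(kind, within=pro_ids)
            if g.residue_tag in candidate_residues
        ]

    waters = model.groups_of_kind("water")
    lig_polar = lig_groups("hb_donor") + lig_groups("hb_acceptor")
    pro_polar = pro_groups("hb_donor") + pro_groups("hb_acceptor")

    records: list[InteractionRecord] = []
    com_z = np.empty(traj.n_frames)
    for f, pos in enumerate(traj.frames):
        com_z[f] = float(axis.z(model.ligand_com(pos)))
        for donor in lig_groups("hb_donor"):
            for acceptor in pro_groups("hb_acceptor"):
                records += detect_hbond(pos, model, donor, acceptor, params,
                                        frame_index=f, ligand_group=donor)
        for acceptor in lig_groups("hb_acceptor"):
            for donor in pro_groups("hb_donor"):
                records += detect_hbond(pos, model, donor, acceptor, params,
                                        frame_index=f, ligand_group=acceptor)
        seen_pairs: set = set()
        for lg in lig_polar:
            for pg in pro_polar:
                pair = (lg.group_id, pg.group_id)
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                records += detect_water_bridge(pos, model, lg, pg, waters, params,
                                               frame_index=f)
        for cat in lig_groups("cationic"):
            for ani in pro_groups("anionic"):
                records += detect_ionic(pos, model, cat, ani, params,
                                        frame_index=f, ligand_group=cat)
        for ani in lig_groups("anionic"):
            for cat in pro_groups("cationic"):
                records += detect_ionic(pos, model, cat, ani, params,
                                        frame_index=f, ligand_group=ani)
        for cat in lig_groups("cationic"):
            for ring in pro_groups("aromatic_ring"):
                records += detect_cation_pi(pos, model, cat, ring, params,
                                            frame_index=f, ligand_group=cat)
        for ring in lig_groups("aromatic_ring"):
            for cat in pro_groups("cationic"):
                records += detect_cation_pi(pos, model, cat, ring, params,
                                            frame_index=f, ligand_group=ring)
        for ra in lig_groups("aromatic_ring"):
            for rb in pro_groups("aromatic_ring"):
                records += detect_pi_pi(pos, model, ra, rb, params,
                                        frame_index=f, ligand_group=ra)
    return InteractionTable(records=records, com_z=com_z, n_frames=traj.n_frames)
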