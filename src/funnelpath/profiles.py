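"""Summary statistics along the translocation axis and over time.

This module turns interaction tables and trajectories into the
figure-level quantities of a transport study:

* slice-resolved interaction-probability profiles (1-Å slices along z,
  with a ≥20% peak-occurrence filter),
* ligand-position occupancy bar graphs,
* ligand-RMSD traces (translation-only registration on the protein
  center of mass, carbon atoms) and their occurrence histograms with
  block standard errors,
* protein backbone RMSD (Kabsch superposition onto a reference) and
  RMSF (after alignment onto the first frame),
* target-RMSD traces with a linearly scheduled restraint potential of
  the targeted-MD form U(t) = k/(2N)·(RMSD(t) − RMSD*(t))².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interactions import InteractionTable
from .models import ConfigError, EmptyInputError, TopologyError, Trajectory

__all__ = [
    "SliceGrid",
    "SliceProfile",
    "RmsdHistogram",
    "interaction_probability_profile",
    "occupancy_profile",
    "ligand_rmsd_trace",
    "rmsd_occurrence_histogram",
    "protein_rmsd_trace",
    "rmsf_profile",
    "target_rmsd_trace",
    "restraint_potential",
    "kabsch",
    "strip_chain",
]


# ---------------------------------------------------------------------------
# slice statistics


@dataclass(frozen=True)
class SliceGrid:
    """Half-open 1-Å slices [z_min + k·w, z_min + (k+1)·w) along the axis."""

    z_min: float = -15.0
    width: float = 1.0
    n_slices: int = 30

    def __post_init__(self) -> None:
        if self.width <= 0 or self.n_slices < 1:
            raise ConfigError("slice width and count must be positive")

    @property
    def edges(self) -> np.ndarray:
        return self.z_min + self.width * np.arange(self.n_slices + 1)

    def index(self, z: np.ndarray) -> np.ndarray:
        """Slice index per z; −1 marks the overflow bucket (outside range)."""
        z = np.asarray(z, dtype=float)
        k = np.floor((z - self.z_min) / self.width).astype(int)
        k[(k < 0) | (k >= self.n_slices)] = -1
        return k


def strip_chain(residue_tag: str) -> str:
    """Pool partner residues over monomers/replicas: 'A:208:GLU' → 'GLU208'."""
    chain, resnum, resname = residue_tag.split(":")
    return f"{resname}{resnum}"


@dataclass
class SliceProfile:
    """P(interaction key, slice) with occupancy counts and occurrence filter."""

    grid: SliceGrid
    occupancy: np.ndarray  # frames per slice
    keys: list  # (type, ligand_part, partner) with chain-stripped partner
    probability: np.ndarray  # (n_keys, n_slices), NaN where occupancy == 0
    present_counts: np.ndarray  # (n_keys, n_slices)
    kept_keys: list
    threshold: float
    overflow: int = 0

    def peak(self, key) -> float:
        i = self.keys.index(key)
        row = self.probability[i]
        return float(np.nanmax(row)) if np.any(~np.isnan(row)) else 0.0

    def to_dataframe(self):
        import pandas as pd

        edges = self.grid.edges
        rows = []
        kept = set(self.kept_keys)
        for i, key in enumerate(self.keys):
            for s in range(self.grid.n_slices):
                p = self.probability[i, s]
                rows.append(
                    {
                        "type": key[0],
                        "ligand_part": key[1],
                        "partner": key[2],
                        "slice_low": edges[s],
                        "slice_high": edges[s + 1],
                        "occupancy": int(self.occupancy[s]),
                        "present": int(self.present_counts[i, s]),
                        "P": np.nan if np.isnan(p) else p,
                        "kept": key in kept,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["type", "ligand_part", "partner", "slice_low", "slice_high",
                     "occupancy", "present", "P", "kept"],
        )

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_json(self, path: str) -> None:
        import json

        payload = {
            "z_min": self.grid.z_min,
            "width": self.grid.width,
            "threshold": self.threshold,
            "occupancy": [int(c) for c in self.occupancy],
            "overflow": int(self.overflow),
            "keys": ["|".join(k) for k in self.keys],
            "kept_keys": ["|".join(k) for k in self.kept_keys],
            "P": [
                [None if np.isnan(v) else round(float(v), 9) for v in row]
                for row in self.probability
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _pooled_slices(tables: list, grid: SliceGrid):
    if not tables:
        raise EmptyInputError("no interaction tables supplied")
    total = sum(t.n_frames for t in tables)
    if total == 0:
        raise EmptyInputError("zero frames across tables")
    slice_idx = [grid.index(t.com_z) for t in tables]
    occupancy = np.zeros(grid.n_slices, dtype=int)
    overflow = 0
    for idx in slice_idx:
        inside = idx >= 0
        occupancy += np.bincount(idx[inside], minlength=grid.n_slices)
        overflow += int((~inside).sum())
    return slice_idx, occupancy, overflow


def interaction_probability_profile(
    tables: list,
    grid: SliceGrid | None = None,
    threshold: float = 0.20,
    pool_frames: bool = True,
) -> SliceProfile:
    """Interaction probability per key and 1-Å slice, pooled over tables.

    P(key, slice) = frames with the interaction present and the ligand
    center of mass inside the slice, divided by frames with the COM
    inside the slice.  A key is kept when its peak probability over
    slices is ≥ ``threshold`` (inclusive).  Keys aggregate partner
    residues over chains.  ``pool_frames=False`` averages per-table
    probabilities instead of pooling frames.
    """
    grid = grid or SliceGrid()
    slice_idx, occupancy, overflow = _pooled_slices(tables, grid)

    keys: list[tuple] = []
    key_pos: dict[tuple, int] = {}
    per_table_presence = []
    for t in tables:
        pres = {}
        for (itype, part, partner), mask in t.presence().items():
            key = (itype, part, strip_chain(partner))
            if key not in key_pos:
                key_pos[key] = len(keys)
                keys.append(key)
            if key in pres:
                pres[key] |= mask
            else:
                pres[key] = mask.copy()
        per_table_presence.append(pres)

    n_keys = len(keys)
    present = np.zeros((n_keys, grid.n_slices), dtype=int)
    for idx, pres in zip(slice_idx, per_table_presence):
        inside = idx >= 0
        for key, mask in pres.items():
            i = key_pos[key]
            sel = mask & inside
            if sel.any():
                present[i] += np.bincount(idx[sel], minlength=grid.n_slices)

    if pool_frames:
        with np.errstate(invalid="ignore", divide="ignore"):
            prob = np.where(occupancy > 0, present / np.maximum(occupancy, 1), np.nan)
    else:
        # per-table probabilities averaged over tables with occupancy
        prob_sum = np.zeros((n_keys, grid.n_slices))
        counts = np.zeros(grid.n_slices)
        for idx, pres in zip(slice_idx, per_table_presence):
            inside = idx >= 0
            occ_t = np.bincount(idx[inside], minlength=grid.n_slices)
            has = occ_t > 0
            counts += has
            p_t = np.zeros((n_keys, grid.n_slices))
            for key, mask in pres.items():
                i = key_pos[key]
                sel = mask & inside
                if sel.any():
                    p_t[i] = np.bincount(idx[sel], minlength=grid.n_slices)
            p_t[:, has] = p_t[:, has] / occ_t[has]
            p_t[:, ~has] = 0.0
            prob_sum += p_t
        with np.errstate(invalid="ignore", divide="ignore"):
            prob = np.where(counts > 0, prob_sum / np.maximum(counts, 1), np.nan)

    kept = []
    for i, key in enumerate(keys):
        row = prob[i]
        peak = float(np.nanmax(row)) if np.any(~np.isnan(row)) else 0.0
        if peak >= threshold:
            kept.append(key)
    return SliceProfile(
        grid=grid,
        occupancy=occupancy,
        keys=keys,
        probability=prob,
        present_counts=present,
        kept_keys=kept,
        threshold=threshold,
        overflow=overflow,
    )


def occupancy_profile(tables: list, grid: SliceGrid | None = None):
    """Frames-per-slice counts of the ligand COM, plus an overflow bucket."""
    grid = grid or SliceGrid()
    _, occupancy, overflow = _pooled_slices(tables, grid)
    return occupancy, overflow


# ---------------------------------------------------------------------------
# RMSD / RMSF


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (rotation R, translation t).

    Returns (R, t) such that mobile @ R.T + t best fits reference.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ConfigError("superposition needs >= 3 matched atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return rot, trans


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def ligand_rmsd_trace(
    traj: Trajectory,
    reference_coords: np.ndarray,
    selection: np.ndarray | None = None,
    rotational_fit: bool = False,
) -> np.ndarray:
    """Ligand RMSD per frame against a reference pose.

    Each frame and the reference are translated so the protein center of
    mass sits at the origin (translation only by default — the
    convention for tracking a substrate drifting inside a transporter);
    the RMSD is then taken over the ligand carbon atoms (or an explicit
    atom-index ``selection``).  ``rotational_fit=True`` additionally
    superposes the protein onto the reference protein.
    """
    model = traj.model
    reference_coords = np.asarray(reference_coords, dtype=float)
    if reference_coords.shape != (model.n_atoms, 3):
        raise TopologyError("reference coordinates do not match the topology")
    if selection is None:
        selection = np.array(
            [i for i in model.selection_indices("ligand")
             if model.atoms[i].element.upper() == "C"],
            dtype=int,
        )
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise EmptyInputError("empty ligand RMSD selection")

    pro_idx = model.selection_indices("protein")
    masses = model.masses[pro_idx]

    def centered(coords):
        com = (coords[pro_idx] * masses[:, None]).sum(axis=0) / masses.sum()
        return coords - com

    ref = centered(reference_coords)
    out = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        cur = centered(frame)
        if rotational_fit:
            rot, trans = kabsch(cur[pro_idx], ref[pro_idx])
            cur = cur @ rot.T + trans
        out[f] = _rmsd(cur[selection], ref[selection])
    return out


@dataclass
class RmsdHistogram:
    """Occurrence counts N_O per RMSD bin, with block standard errors."""

    bin_edges: np.ndarray
    counts: np.ndarray
    se: np.ndarray
    n_blocks: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "N_O": self.counts,
                "se": self.se,
            }
        )

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")


def rmsd_occurrence_histogram(
    series: list | np.ndarray,
    bin_width: float = 0.5,
    n_blocks: int = 3,
) -> RmsdHistogram:
    """Histogram of occurrences N_O over pooled RMSD series with block SE.

    Frames are pooled over all series; the standard error per bin is the
    standard deviation of block-wise counts (contiguous equal blocks of
    the pooled series, remainder to the last block, each scaled to
    full-trajectory units) divided by √n_blocks.
    """
    if isinstance(series, np.ndarray):
        series = [series]
    values = np.concatenate([np.asarray(s, dtype=float).ravel() for s in series])
    if values.size == 0:
        raise EmptyInputError("no RMSD values to histogram")
    if n_blocks < 2:
        raise ConfigError("need at least 2 blocks for a block SE")
    top = max(values.max(), bin_width)
    n_bins = int(np.ceil(top / bin_width + 1e-9))
    edges = bin_width * np.arange(n_bins + 1)
    # np.histogram's last bin is closed; widen slightly to keep [low, high) semantics
    idx = np.minimum(np.floor(values / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)

    block_size = values.size // n_blocks
    block_counts = np.empty((n_blocks, n_bins))
    for b in range(n_blocks):
        lo = b * block_size
        hi = values.size if b == n_blocks - 1 else (b + 1) * block_size
        block_idx = idx[lo:hi]
        scale = values.size / max(hi - lo, 1)
        block_counts[b] = np.bincount(block_idx, minlength=n_bins) * scale
    se = block_counts.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return RmsdHistogram(bin_edges=edges, counts=counts, se=se, n_blocks=n_blocks)


def protein_rmsd_trace(
    traj: Trajectory,
    reference_coords: np.ndarray,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Backbone-heavy-atom RMSD per frame after optimal superposition.

    ``reference_coords`` may contain NaN rows for residues missing from
    the reference structure; those atoms are excluded from both the fit
    and the RMSD, mirroring how unresolved crystal residues are skipped.
    """
    model = traj.model
    reference_coords = np.asarray(reference_coords, dtype=float)
    if reference_coords.shape != (model.n_atoms, 3):
        raise TopologyError("reference coordinates do not match the topology")
    if selection is None:
        selection = np.array(
            [i for i in model.selection_indices("protein")
             if model.atoms[i].is_backbone and model.atoms[i].is_heavy],
            dtype=int,
        )
    selection = np.asarray(selection, dtype=int)
    resolved = np.isfinite(reference_coords[selection]).all(axis=1)
    selection = selection[resolved]
    if selection.size < 3:
        raise ConfigError("fewer than 3 mapped atoms for superposition")
    ref = reference_coords[selection]
    out = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        mob = frame[selection]
        rot, trans = kabsch(mob, ref)
        out[f] = _rmsd(mob @ rot.T + trans, ref)
    return out


def rmsf_profile(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    per_residue: bool = False,
):
    """Root-mean-square fluctuation per selected atom.

    Every frame is superposed onto the first frame over the selection;
    RMSF_i = √⟨‖x_i − ⟨x_i⟩‖²⟩ over frames.  With ``per_residue`` the
    atomic values are averaged within each residue.
    """
    model = traj.model
    if traj.n_frames < 2:
        raise EmptyInputError("RMSF needs at least 2 frames")
    if selection is None:
        selection = np.array(
            [i for i in model.selection_indices("protein")
             if model.atoms[i].is_backbone and model.atoms[i].is_heavy],
            dtype=int,
        )
    selection = np.asarray(selection, dtype=int)
    if selection.size < 3:
        raise ConfigError("fewer than 3 atoms for RMSF alignment")
    ref = traj.frames[0][selection]
    aligned = np.empty((traj.n_frames, selection.size, 3))
    for f, frame in enumerate(traj.frames):
        mob = frame[selection]
        rot, trans = kabsch(mob, ref)
        aligned[f] = mob @ rot.T + trans
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    if not per_residue:
        return rmsf
    tags = [model.atoms[i].residue_tag for i in selection]
    order: list[str] = []
    sums: dict[str, list] = {}
    for t, v in zip(tags, rmsf):
        if t not in sums:
            sums[t] = []
            order.append(t)
        sums[t].append(v)
    return order, np.array([np.mean(sums[t]) for t in order])


def target_rmsd_trace(
    traj: Trajectory,
    target_coords: np.ndarray,
    selection: np.ndarray,
) -> np.ndarray:
    """Best-fit RMSD of a targeted selection to target coordinates, per frame."""
    model = traj.model
    target_coords = np.asarray(target_coords, dtype=float)
    selection = np.asarray(selection, dtype=int)
    if target_coords.shape == (model.n_atoms, 3):
        target = target_coords[selection]
    elif target_coords.shape == (selection.size, 3):
        target = target_coords
    else:
        raise TopologyError("target coordinates do not map onto the selection")
    out = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        mob = frame[selection]
        rot, trans = kabsch(mob, target)
        out[f] = _rmsd(mob @ rot.T + trans, target)
    return out


def restraint_potential(
    series: np.ndarray,
    k: float,
    t_total: float,
    n_atoms: int,
    times: np.ndarray | None = None,
    rmsd0: float | None = None,
) -> np.ndarray:
    """Targeted-MD restraint energy per frame.

    U(t) = (k / 2N)·(RMSD(t) − RMSD*(t))² with the scheduled RMSD*(t) =
    RMSD*(0)·(1 − t/T_total) decaying linearly to zero; the schedule
    anchor RMSD*(0) is ``rmsd0`` (default: the first value of the
    series).  The functional form is the standard targeted-MD
    convention; k is in energy/Å² per atom and N is the number of
    targeted atoms.
    """
    series = np.asarray(series, dtype=float)
    if t_total <= 0:
        raise ConfigError("t_total must be positive")
    if n_atoms < 1:
        raise ConfigError("n_atoms must be positive")
    if times is None:
        times = np.linspace(0.0, t_total, series.size)
    times = np.asarray(times, dtype=float)
    anchor = float(series[0]) if rmsd0 is None else float(rmsd0)
    scheduled = anchor * (1.0 - times / t_total)
    return (k / (2.0 * n_atoms)) * (series - scheduled) ** 2
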