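"""Structure and trajectory file I/O.

PDB files (single- and multi-model) are handled through biotite; binary
trajectory formats (DCD, XTC) through MDAnalysis.  Reading yields the
package's own containers so that the rest of the pipeline is
format-agnostic.

PDB dialect choices: a single altloc is kept (highest occupancy, ties to
'A'); insertion codes are folded into the residue number ordering; any
residue named HOH/WAT/TIP3/SOL is water.
"""

from __future__ import annotations

import os
import warnings

import numpy as np

from .annotate import WATER_RESNAMES
from .models import (
    AtomRecord,
    BACKBONE_NAMES,
    EmptyInputError,
    ParseError,
    StructureModel,
    TopologyError,
    Trajectory,
)

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
]

_PDB_SUFFIXES = (".pdb", ".ent", ".pdb1")


def _guess_element(name: str, given: str) -> str:
    if given and given.strip():
        return given.strip().upper()
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element for atom name {name!r}")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return stripped[:2].upper()
    return stripped[0].upper()


def _atoms_from_array(array) -> list[AtomRecord]:
    import biotite.structure as struc

    n = array.array_length()
    if n == 0:
        raise EmptyInputError("file holds zero atoms")
    try:
        atom_ids = array.get_annotation("atom_id")
    except KeyError:
        atom_ids = np.arange(1, n + 1)
    if len(set(int(i) for i in atom_ids)) != n:
        atom_ids = np.arange(1, n + 1)
    coords = array.coord if array.coord.ndim == 2 else array.coord[0]
    records = []
    for i in range(n):
        element = _guess_element(array.atom_name[i], array.element[i])
        name = str(array.atom_name[i]).strip()
        records.append(
            AtomRecord(
                atom_id=int(atom_ids[i]),
                name=name,
                element=element,
                residue_name=str(array.res_name[i]).strip(),
                residue_number=int(array.res_id[i]),
                chain_id=str(array.chain_id[i]).strip() or "A",
                position=coords[i],
                is_backbone=name in BACKBONE_NAMES,
                is_heavy=element != "H",
            )
        )
    return records


def _default_selections(
    atoms: list[AtomRecord], ligand_resnames: set | None, hetero: np.ndarray | None
) -> tuple[frozenset, frozenset]:
    ligand, protein = set(), set()
    for i, a in enumerate(atoms):
        resname = a.residue_name.upper()
        if resname in WATER_RESNAMES:
            continue
        if ligand_resnames is not None:
            is_ligand = resname in ligand_resnames
        else:
            is_ligand = bool(hetero[i]) if hetero is not None else False
        (ligand if is_ligand else protein).add(a.atom_id)
    return frozenset(ligand), frozenset(protein)


def read_structure(path: str, ligand_resnames=None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel` (first model only).

    ``ligand_resnames`` names the ligand residues; otherwise HETATM
    records (minus waters) form the ligand selection.  No radii or group
    annotations are assigned yet.
    """
    from biotite.structure.io.pdb import PDBFile

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(path)
        array = pdb.get_structure(
            model=1, altloc="occupancy", extra_fields=["atom_id", "occupancy"]
        )
    except EmptyInputError:
        raise
    except Exception as exc:  # biotite raises assorted ValueErrors
        raise ParseError(f"{path}: {exc}") from exc
    if array.array_length() == 0:
        raise EmptyInputError(f"{path}: zero atoms")
    if not np.all(np.isfinite(array.coord)):
        raise ParseError(f"{path}: atom with missing/non-finite coordinates")
    atoms = _atoms_from_array(array)
    if ligand_resnames is not None:
        ligand_resnames = {r.upper() for r in ligand_resnames}
    lig, prot = _default_selections(atoms, ligand_resnames, array.hetero)
    return StructureModel(atoms=atoms, ligand_selection=lig, protein_selection=prot)


def _frames_from_pdb(path: str, n_atoms: int) -> list[np.ndarray]:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    coords = stack.coord
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] != n_atoms:
        raise TopologyError(
            f"{path}: {coords.shape[1]} atoms per frame, topology has {n_atoms}"
        )
    return [coords[k].astype(float) for k in range(coords.shape[0])]


def read_trajectory(
    topology: str | StructureModel, coords: str, ligand_resnames=None
) -> Trajectory:
    """Read a trajectory (multi-model PDB, DCD or XTC) over a PDB topology.

    Frame times come from the file metadata when meaningful (converted
    ps → ns) and fall back to uniform unit spacing.
    """
    model = (
        topology
        if isinstance(topology, StructureModel)
        else read_structure(topology, ligand_resnames=ligand_resnames)
    )
    suffix = os.path.splitext(coords)[1].lower()
    if suffix in _PDB_SUFFIXES:
        frames = _frames_from_pdb(coords, model.n_atoms)
        return Trajectory(model=model, frames=frames)

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe.empty(model.n_atoms, trajectory=True)
        try:
            universe.load_new(coords)
        except Exception as exc:
            raise ParseError(f"{coords}: {exc}") from exc
        if universe.trajectory.n_atoms != model.n_atoms:
            raise TopologyError(
                f"{coords}: {universe.trajectory.n_atoms} atoms, "
                f"topology has {model.n_atoms}"
            )
        frames, times = [], []
        for ts in universe.trajectory:
            frames.append(ts.positions.astype(float).copy())
            times.append(float(ts.time))
    if not frames:
        raise EmptyInputError(f"{coords}: zero frames")
    times_arr = np.asarray(times) / 1000.0  # ps -> ns
    if len(times_arr) > 1 and np.all(np.diff(times_arr) > 0):
        frame_times = times_arr
    else:
        frame_times = None
    return Trajectory(model=model, frames=frames, frame_times=frame_times)


def _array_from_model(model: StructureModel, positions: np.ndarray | None = None):
    import biotite.structure as struc

    n = model.n_atoms
    array = struc.AtomArray(n)
    pos = model.positions if positions is None else np.asarray(positions)
    array.coord = pos.astype(np.float32)
    hetero = np.zeros(n, dtype=bool)
    for i, a in enumerate(model.atoms):
        array.chain_id[i] = a.chain_id[:4]
        array.res_id[i] = a.residue_number
        array.res_name[i] = a.residue_name[:5]
        array.atom_name[i] = a.name[:6]
        array.element[i] = a.element
        hetero[i] = (
            a.atom_id in model.ligand_selection
            or a.residue_name.upper() in WATER_RESNAMES
        )
    array.hetero = hetero
    array.set_annotation(
        "atom_id", np.array([a.atom_id for a in model.atoms], dtype=int)
    )
    return array


def write_structure(model: StructureModel, path: str) -> None:
    """Write a StructureModel to a single-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_array_from_model(model))
    pdb.write(path)


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write frames as multi-model PDB, DCD or XTC (chosen by suffix)."""
    suffix = os.path.splitext(path)[1].lower()
    if suffix in _PDB_SUFFIXES:
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        template = _array_from_model(traj.model)
        stack = struc.stack([template] * traj.n_frames)
        stack.coord = np.asarray(traj.frames, dtype=np.float32)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(path)
        return

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe.empty(traj.model.n_atoms, trajectory=True)
        kwargs = {}
        if suffix == ".xtc":
            # default XTC compression keeps 3 decimals in nm (0.01 Å);
            # 5 decimals keeps round-trips well inside 1e-3 Å
            kwargs["precision"] = 5
        with mda.Writer(path, n_atoms=traj.model.n_atoms, **kwargs) as writer:
            for frame in traj.frames:
                universe.atoms.positions = frame.astype(np.float32)
                writer.write(universe.atoms)
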