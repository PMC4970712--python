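"""Core in-memory containers: atoms, functional groups, structures, trajectories.

Coordinates are in Å throughout, times in ns.  A :class:`StructureModel`
carries one topology (atoms + group annotations + ligand/protein splits);
a :class:`Trajectory` shares a single model across ordered coordinate frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "GroupAnnotation",
    "StructureModel",
    "Trajectory",
    "GROUP_KINDS",
    "ELEMENT_MASSES",
    "FunnelPathError",
    "ParseError",
    "TopologyError",
    "EmptyInputError",
    "TypingError",
    "ConfigError",
]

GROUP_KINDS = frozenset(
    {"hb_donor", "hb_acceptor", "cationic", "anionic", "aromatic_ring", "water"}
)

# Average atomic masses (u) for center-of-mass weighting.  Unknown elements
# fall back to carbon so that pseudo-atoms still carry weight.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "HN"})


class FunnelPathError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(FunnelPathError):
    """A structure or trajectory file could not be parsed."""


class TopologyError(FunnelPathError):
    """Topology and coordinates disagree (atom counts, atom mapping)."""


class EmptyInputError(FunnelPathError):
    """An input held zero atoms or zero frames."""


class TypingError(FunnelPathError):
    """Radius or group typing could not be resolved."""


class ConfigError(FunnelPathError):
    """An invalid parameter combination was supplied."""


@dataclass
class AtomRecord:
    """One atom of a structure.

    ``vdw_radius`` is the radius used by the pore profiler; it is 0.0 until
    :func:`funnelpath.annotate.assign_radii` has run (or the producer sets it).
    """

    atom_id: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    vdw_radius: float = 0.0
    is_backbone: bool = False
    is_heavy: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.atom_id}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ParseError(f"atom {self.atom_id} has non-finite coordinates")

    @property
    def mass(self) -> float:
        return ELEMENT_MASSES.get(self.element.upper(), ELEMENT_MASSES["C"])

    @property
    def residue_tag(self) -> str:
        return f"{self.chain_id}:{self.residue_number}:{self.residue_name}"


@dataclass
class GroupAnnotation:
    """A functional group: H-bond donor/acceptor, charged group, ring or water.

    ``member_atom_ids`` are ordered; for donors the first member is the donor
    heavy atom and any following members are its hydrogens; for rings the
    order traces the ring so centroid/normal are well defined.
    ``charge_center_id`` names the atom used as the cation charge center
    (e.g. CZ for a guanidinium group).
    """

    group_id: int
    kind: str
    member_atom_ids: tuple
    residue_tag: str
    charge_center_id: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in GROUP_KINDS:
            raise ValueError(f"unknown group kind {self.kind!r}")
        self.member_atom_ids = tuple(int(i) for i in self.member_atom_ids)
        if not self.member_atom_ids:
            raise ValueError("group has no member atoms")
        if self.kind == "aromatic_ring" and len(self.member_atom_ids) < 5:
            raise ValueError("aromatic_ring group needs at least 5 members")


@dataclass
class StructureModel:
    """Atoms plus annotations; the shared topology of a trajectory."""

    atoms: list[AtomRecord]
    groups: list[GroupAnnotation] = field(default_factory=list)
    ligand_selection: frozenset = frozenset()
    protein_selection: frozenset = frozenset()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyInputError("structure holds zero atoms")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise TopologyError("atom_id values are not unique")
        self.ligand_selection = frozenset(self.ligand_selection)
        self.protein_selection = frozenset(self.protein_selection)
        if self.ligand_selection & self.protein_selection:
            raise TopologyError("ligand and protein selections overlap")
        self._index = {a.atom_id: i for i, a in enumerate(self.atoms)}
        known = set(ids)
        for g in self.groups:
            missing = set(g.member_atom_ids) - known
            if missing:
                raise TopologyError(f"group {g.group_id} references unknown atoms {missing}")

    # -- array views -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def index_of(self, atom_id: int) -> int:
        return self._index[atom_id]

    def indices_of(self, atom_ids: Iterable[int]) -> np.ndarray:
        return np.array([self._index[i] for i in atom_ids], dtype=int)

    def atom(self, atom_id: int) -> AtomRecord:
        return self.atoms[self._index[atom_id]]

    def with_positions(self, positions: np.ndarray) -> "StructureModel":
        """A copy of the model whose atoms carry the given coordinates."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_atoms, 3):
            raise TopologyError(
                f"expected coordinates of shape ({self.n_atoms}, 3), got {positions.shape}"
            )
        atoms = [replace(a, position=positions[i].copy()) for i, a in enumerate(self.atoms)]
        return StructureModel(
            atoms=atoms,
            groups=list(self.groups),
            ligand_selection=self.ligand_selection,
            protein_selection=self.protein_selection,
            metadata=dict(self.metadata),
        )

    # -- selections --------------------------------------------------------
    def selection_indices(self, which: str) -> np.ndarray:
        if which == "ligand":
            ids = sorted(self.ligand_selection)
        elif which == "protein":
            ids = sorted(self.protein_selection)
        else:
            raise ValueError(which)
        return self.indices_of(ids)

    def ligand_com(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Mass-weighted center of mass of the ligand selection."""
        if not self.ligand_selection:
            raise EmptyInputError("model has no ligand selection")
        idx = self.selection_indices("ligand")
        pos = self.positions if positions is None else np.asarray(positions, dtype=float)
        m = self.masses[idx]
        return (pos[idx] * m[:, None]).sum(axis=0) / m.sum()

    def groups_of_kind(self, kind: str, within: frozenset | None = None) -> list[GroupAnnotation]:
        out = []
        for g in self.groups:
            if g.kind != kind:
                continue
            if within is not None and not set(g.member_atom_ids) <= within:
                continue
            out.append(g)
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames over one topology.  Times are in ns."""

    model: StructureModel
    frames: list[np.ndarray]
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyInputError("trajectory holds zero frames")
        n = self.model.n_atoms
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise TopologyError(f"frame {k} has shape {f.shape}, expected ({n}, 3)")
        self.has_times = self.frame_times is not None
        if self.frame_times is None:
            self.frame_times = np.arange(len(self.frames), dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (len(self.frames),):
                raise TopologyError("frame_times length must equal number of frames")
            if np.any(np.diff(self.frame_times) <= 0):
                raise TopologyError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def select_frames(self, spec: str | Sequence[int] | None) -> list[int]:
        """Resolve a frame selection.

        ``None`` → all frames; ``"last:X ns"`` → frames within the final X ns;
        ``"last:K"`` → the final K frames; an explicit index sequence is
        passed through.
        """
        n = self.n_frames
        if spec is None:
            return list(range(n))
        if isinstance(spec, str):
            if not spec.startswith("last:"):
                raise ConfigError(f"unknown frame selection {spec!r}")
            arg = spec[len("last:"):].strip()
            if arg.endswith("ns"):
                window = float(arg[:-2])
                t_end = float(self.frame_times[-1])
                return [i for i, t in enumerate(self.frame_times) if t > t_end - window]
            k = int(arg)
            if k <= 0:
                raise ConfigError("frame window must be positive")
            return list(range(max(0, n - k), n))
        idx = [int(i) for i in spec]
        for i in idx:
            if not 0 <= i < n:
                raise ConfigError(f"frame index {i} out of range")
        return idx
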