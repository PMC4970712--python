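"""Synthetic channels, ligand paths and scripted interaction events.

Everything the pipeline consumes can be generated here with exact,
machine-readable ground truth: pseudo-atom channels whose maximal-sphere
radius profile is known in closed form, state fixtures with constrictions
at chosen positions, and scripted translocation trajectories in which an
arginine-like pseudo-ligand walks down the channel axis while probe
residues are posed, frame by frame, to satisfy or violate each
interaction detector with a stated geometric margin.

None of this is physically realistic — there is no force field and no
thermodynamics.  The generator's sole purpose is to give every analysis
stage an input whose correct answer is known exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import (
    AtomRecord,
    ConfigError,
    GroupAnnotation,
    StructureModel,
    Trajectory,
)

__all__ = [
    "ChannelSpec",
    "ScheduledEvent",
    "EventSchedule",
    "GroundTruth",
    "make_channel",
    "make_state_fixture",
    "make_state_trajectory",
    "jittered_trajectory",
    "make_translocation",
    "default_translocation_schedule",
    "STATE_FIXTURE_KINDS",
]


# ---------------------------------------------------------------------------
# channels


@dataclass(frozen=True)
class ChannelSpec:
    """A channel of pseudo-atom rings realizing a radius function ρ(z).

    ``kind`` picks the built-in profile (cylinder, cone, hourglass) with
    ``rho_params``; a custom callable ``radius_fn`` overrides it.  The
    wall is built from rings of ``atoms_per_ring`` atoms of radius
    ``atom_radius`` every ``ring_spacing`` Å between ``z_min`` and
    ``z_max``.
    """

    kind: str = "cylinder"
    rho_params: tuple = (8.0,)
    z_min: float = -15.0
    z_max: float = 15.0
    ring_spacing: float = 1.0
    atoms_per_ring: int = 36
    element: str = "C"
    atom_radius: float = 1.5

    def radius_fn(self, z: np.ndarray | float):
        z = np.asarray(z, dtype=float)
        if self.kind == "cylinder":
            (rho,) = self.rho_params
            return np.full_like(z, rho, dtype=float)
        if self.kind == "cone":
            rho0, slope = self.rho_params
            return rho0 + slope * z
        if self.kind == "hourglass":
            rho_max, rho_min, width = self.rho_params
            return rho_max - (rho_max - rho_min) * np.exp(-(z ** 2) / width)
        if self.kind == "constricted":
            # base radius with Gaussian constrictions at given centers
            rho0, rho_min, sigma, centers = self.rho_params
            out = np.full_like(z, rho0, dtype=float)
            for c in centers:
                out = out - (rho0 - rho_min) * np.exp(-((z - c) ** 2) / (2 * sigma ** 2))
            return out
        raise ConfigError(f"unknown channel kind {self.kind!r}")


def _channel_atoms(spec: ChannelSpec, start_id: int = 1) -> list[AtomRecord]:
    atoms = []
    z_rings = np.arange(spec.z_min, spec.z_max + spec.ring_spacing / 2, spec.ring_spacing)
    angles = 2 * np.pi * np.arange(spec.atoms_per_ring) / spec.atoms_per_ring
    aid = start_id
    for ring_no, z in enumerate(z_rings, start=1):
        rho = float(spec.radius_fn(z))
        if rho <= spec.atom_radius:
            raise ConfigError(f"ρ({z:.2f}) = {rho:.2f} Å does not leave an open lumen")
        for j, th in enumerate(angles, start=1):
            atoms.append(
                AtomRecord(
                    atom_id=aid,
                    name=f"C{j}",
                    element=spec.element,
                    residue_name="CHN",
                    residue_number=ring_no,
                    chain_id="X",
                    position=np.array([rho * np.cos(th), rho * np.sin(th), z]),
                    vdw_radius=spec.atom_radius,
                )
            )
            aid += 1
    return atoms


def make_channel(spec: ChannelSpec | None = None):
    """Build the channel StructureModel and its analytic profile sampler.

    The sampler gives the expected maximal-sphere radius at any z with
    the center on the axis: min over rings of √(ρ_k² + (z − z_k)²) − r_a.
    At a ring plane this reduces to ρ − r_a and midway between two rings
    of a cylinder to √(ρ² + (Δz/2)²) − r_a.

    A wall whose neighboring atom centers are ≥ 2·r_a apart can leak the
    probe sphere; such channels are flagged ``leaky_wall`` with a warning.
    """
    spec = spec or ChannelSpec()
    atoms = _channel_atoms(spec)
    z_rings = np.arange(spec.z_min, spec.z_max + spec.ring_spacing / 2, spec.ring_spacing)
    rho_rings = np.asarray(spec.radius_fn(z_rings), dtype=float)

    max_chord = float(2 * rho_rings.max() * np.sin(np.pi / spec.atoms_per_ring))
    leaky = max(max_chord, spec.ring_spacing) >= 2 * spec.atom_radius
    if leaky:
        warnings.warn(
            "channel wall is leaky: neighboring atom centers are >= 2 atom radii apart",
            stacklevel=2,
        )
    model = StructureModel(
        atoms=atoms,
        protein_selection=frozenset(a.atom_id for a in atoms),
        metadata={"channel_spec": spec, "leaky_wall": leaky},
    )

    def sampler(z):
        z = np.atleast_1d(np.asarray(z, dtype=float))
        d = np.sqrt(rho_rings[None, :] ** 2 + (z[:, None] - z_rings[None, :]) ** 2)
        r = d.min(axis=1) - spec.atom_radius
        return r if r.size > 1 else float(r[0])

    return model, sampler


STATE_FIXTURE_KINDS = ("OF_open", "occluded", "IF_open", "bilaterally_open")

# Constriction placement per state: the OF-open state is pinched shut on
# the inward-facing side (z ≈ −8) and vice versa; the occluded state on
# both sides; the bilaterally open channel nowhere.
_STATE_CENTERS = {
    "OF_open": (-8.0,),
    "IF_open": (8.0,),
    "occluded": (-8.0, 8.0),
    "bilaterally_open": (),
}


def state_fixture_spec(kind: str) -> ChannelSpec:
    if kind not in _STATE_CENTERS:
        raise ConfigError(f"unknown state fixture kind {kind!r}")
    return ChannelSpec(
        kind="constricted",
        rho_params=(6.0, 2.0, 2.0, _STATE_CENTERS[kind]),
    )


def make_state_fixture(kind: str) -> StructureModel:
    """A channel whose funnel profile realizes one conformational state."""
    model, _ = make_channel(state_fixture_spec(kind))
    model.metadata["state_kind"] = kind
    return model


def jittered_trajectory(
    model: StructureModel, n_frames: int, sigma: float, seed: int = 0
) -> Trajectory:
    """Frames of the model with i.i.d. Gaussian coordinate jitter."""
    rng = np.random.default_rng(seed)
    base = model.positions
    frames = [base + sigma * rng.normal(size=base.shape) for _ in range(n_frames)]
    return Trajectory(model=model, frames=frames)


def make_state_trajectory(
    kind: str, n_frames: int = 20, sigma: float = 0.1, seed: int = 0
) -> Trajectory:
    """A jittered multi-frame version of a state fixture."""
    return jittered_trajectory(make_state_fixture(kind), n_frames, sigma, seed)


# ---------------------------------------------------------------------------
# scripted translocation


@dataclass(frozen=True)
class ScheduledEvent:
    """One scripted interaction: type, ligand attachment site, frames."""

    itype: str  # HB | HB_H2O | ionic | cation_pi | pi_pi
    ligand_part: str  # backbone | side_chain
    frames: tuple
    slice_low: float  # target slice lower edge (bookkeeping)


@dataclass
class EventSchedule:
    """Ligand z-path plus the scripted per-frame interaction events."""

    n_frames: int
    z_path: np.ndarray
    events: list
    lateral_sigma: float = 0.3
    lateral_tau: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.z_path = np.asarray(self.z_path, dtype=float)
        if self.z_path.shape != (self.n_frames,):
            raise ConfigError("z_path length must equal n_frames")
        for ev in self.events:
            for f in ev.frames:
                if not 0 <= f < self.n_frames:
                    raise ConfigError(f"scheduled frame {f} out of range")


def dwell_path(z_values, frames_per_z: int) -> np.ndarray:
    """Piecewise-constant path dwelling ``frames_per_z`` frames at each z."""
    return np.repeat(np.asarray(z_values, dtype=float), frames_per_z)


def default_translocation_schedule(seed: int = 0, frames_per: int = 20) -> EventSchedule:
    """The bundled translocation preset (300 frames at the default size).

    The ligand dwells ``frames_per`` frames at each of 15 slice centers
    from −7.5 to +6.5 Å.  One event of every detector type is scheduled
    in a distinct slice, with peak probabilities 0.5 (HB), 0.3 (HB_H2O),
    0.8 (ionic), 0.4 (cation-π) and 0.6 (π-π), plus a decoy H-bond whose
    peak probability of 0.15 falls below the 20% occurrence filter.
    """
    z_values = np.arange(-7.5, 7.0, 1.0)  # 15 dwell points
    path = dwell_path(z_values, frames_per)

    def block(k: int, frac: float) -> tuple:
        start = k * frames_per
        return tuple(range(start, start + round(frac * frames_per)))

    events = [
        ScheduledEvent("HB", "backbone", block(5, 0.50), -3.0),
        ScheduledEvent("HB_H2O", "backbone", block(7, 0.30), -1.0),
        ScheduledEvent("ionic", "side_chain", block(8, 0.80), 0.0),
        ScheduledEvent("cation_pi", "side_chain", block(10, 0.40), 2.0),
        ScheduledEvent("pi_pi", "side_chain", block(12, 0.60), 4.0),
        ScheduledEvent("HB", "side_chain", block(3, 0.15), -5.0),  # decoy
    ]
    return EventSchedule(
        n_frames=len(path), z_path=path, events=events, seed=seed
    )


# -- ligand template --------------------------------------------------------

_LIG_ATOMS = [
    # (name, element, local position); an arginine-like pseudo-ligand with
    # a guanidinium-like cationic head and a small aromatic ring so every
    # detector type has a ligand-side partner.
    ("N", "N", (-1.5, 0.0, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.2, 0.9, 0.0)),
    ("O", "O", (1.2, 2.1, 0.0)),
    ("CB", "C", (0.0, -1.4, 0.0)),
    ("CG", "C", (0.0, -2.8, 0.0)),
    ("CD", "C", (0.0, -4.0, 0.0)),
    ("NE", "N", (0.0, -5.2, 0.0)),
    ("CZ", "C", (0.0, -6.4, 0.0)),
    ("NH1", "N", (-1.1, -7.1, 0.0)),
    ("NH2", "N", (1.1, -7.1, 0.0)),
]
_LIG_RING_CENTER = np.array([3.2, -1.0, 0.0])
_RING_RADIUS = 1.39


def _hexagon(center, radius=_RING_RADIUS, normal_z=True):
    pts = []
    for k in range(6):
        th = np.pi * k / 3
        pts.append(np.asarray(center) + radius * np.array([np.cos(th), np.sin(th), 0.0]))
    return pts


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class _Probe:
    resname: str
    resnum: int
    atom_names: list
    elements: list
    contact_pose: np.ndarray  # (n, 3) in the ligand local frame
    park_angle: float  # radians on the parking circle
    park_z: float
    group_kind: str
    group_atoms: list  # names forming the annotated group


def _build_probes(events: list) -> list:
    """One probe residue per scheduled event, posed by interaction type."""
    lig = {name: np.array(p) for name, _, p in _LIG_ATOMS}
    probes = []
    n_events = len(events)
    for i, ev in enumerate(events):
        resnum = 501 + i
        angle = 2 * np.pi * i / max(n_events + 1, 7)
        if ev.itype == "HB":
            if ev.ligand_part == "backbone":
                o = lig["N"] + 2.9 * np.array([-1.0, 0.0, 0.0])
            else:
                o = lig["NH1"] + 2.9 * _unit(lig["NH1"] - lig["CZ"])
            pose = np.stack([o, o + np.array([-1.2, 0.0, 0.0])])
            probes.append(_Probe("ACC", resnum, ["O", "C"], ["O", "C"], pose,
                                 angle, ev.slice_low + 0.5, "hb_acceptor", ["O"]))
        elif ev.itype == "HB_H2O":
            anchor = lig["N"] if ev.ligand_part == "backbone" else lig["NH1"]
            o = anchor + 5.0 * np.array([-1.0, 0.0, 0.0])
            pose = np.stack([o, o + np.array([-1.2, 0.0, 0.0])])
            probes.append(_Probe("BRG", resnum, ["O", "C"], ["O", "C"], pose,
                                 angle, ev.slice_low + 0.5, "hb_acceptor", ["O"]))
        elif ev.itype == "ionic":
            oe1 = lig["NH2"] + 3.4 * _unit(lig["NH2"] - lig["CZ"])
            oe2 = oe1 + np.array([0.6, -1.1, 0.0])
            cd = oe1 + np.array([1.2, 0.4, 0.0])
            pose = np.stack([cd, oe1, oe2])
            probes.append(_Probe("GLA", resnum, ["CD", "OE1", "OE2"],
                                 ["C", "O", "O"], pose,
                                 angle, ev.slice_low + 0.5, "anionic", ["OE1", "OE2"]))
        elif ev.itype == "cation_pi":
            center = lig["CZ"] + np.array([0.0, 0.0, 4.5])
            pose = np.stack(_hexagon(center))
            names = [f"C{k}" for k in range(1, 7)]
            probes.append(_Probe("PHE", resnum, names, ["C"] * 6, pose,
                                 angle, ev.slice_low + 0.5, "aromatic_ring", names))
        elif ev.itype == "pi_pi":
            center = _LIG_RING_CENTER + np.array([0.0, 0.0, 3.4])
            pose = np.stack(_hexagon(center))
            names = [f"C{k}" for k in range(1, 7)]
            probes.append(_Probe("TRP", resnum, names, ["C"] * 6, pose,
                                 angle, ev.slice_low + 0.5, "aromatic_ring", names))
        else:
            raise ConfigError(f"unknown scheduled interaction type {ev.itype!r}")
    return probes


_WATER_LOCAL = None  # placed relative to the bridge geometry at build time
_PARK_RADIUS = 14.0


@dataclass
class GroundTruth:
    """Sidecar truth for a scripted translocation.

    ``events`` maps the pooled interaction key "type|part|PARTNER" to the
    sorted frames on which the interaction holds; ``p_star`` is the slice
    probability implied by ``events`` and ``com_z`` and can be recomputed
    from them at any time (``recompute_p_star``).
    """

    n_frames: int
    com_z: np.ndarray
    events: dict
    slice_z_min: float
    slice_width: float
    n_slices: int
    p_star: dict = field(default_factory=dict)
    seed: int = 0

    def recompute_p_star(self) -> dict:
        z = np.asarray(self.com_z, dtype=float)
        idx = np.floor((z - self.slice_z_min) / self.slice_width).astype(int)
        inside = (idx >= 0) & (idx < self.n_slices)
        occupancy = np.bincount(idx[inside], minlength=self.n_slices)
        out = {}
        for key, frames in self.events.items():
            mask = np.zeros(self.n_frames, dtype=bool)
            mask[list(frames)] = True
            present = np.bincount(idx[mask & inside], minlength=self.n_slices)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(occupancy > 0, present / np.maximum(occupancy, 1), np.nan)
            out[key] = p
        return out

    def to_json(self, path: str) -> None:
        payload = {
            "n_frames": int(self.n_frames),
            "com_z": [float(v) for v in self.com_z],
            "events": {k: [int(f) for f in v] for k, v in self.events.items()},
            "slice_z_min": self.slice_z_min,
            "slice_width": self.slice_width,
            "n_slices": self.n_slices,
            "p_star": {
                k: [None if np.isnan(v) else float(v) for v in row]
                for k, row in self.p_star.items()
            },
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            n_frames=payload["n_frames"],
            com_z=np.asarray(payload["com_z"], dtype=float),
            events={k: tuple(v) for k, v in payload["events"].items()},
            slice_z_min=payload["slice_z_min"],
            slice_width=payload["slice_width"],
            n_slices=payload["n_slices"],
            p_star={
                k: np.array([np.nan if v is None else v for v in row])
                for k, row in payload["p_star"].items()
            },
            seed=payload["seed"],
        )


def _ou_noise(rng, n: int, sigma: float, tau: float) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck series (lateral ligand wobble)."""
    if sigma == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = sigma * rng.normal()
    decay = np.exp(-1.0 / tau)
    drive = sigma * np.sqrt(1.0 - decay ** 2)
    for t in range(1, n):
        x[t] = decay * x[t - 1] + drive * rng.normal()
    return x


def make_translocation(
    schedule: EventSchedule | None = None,
    channel_spec: ChannelSpec | None = None,
    slice_z_min: float = -15.0,
    slice_width: float = 1.0,
    n_slices: int = 30,
    clash_tolerance: float = 0.0,
):
    """Scripted translocation trajectory with exact ground truth.

    The pseudo-ligand's center of mass follows ``schedule.z_path`` down
    the channel axis with seeded Ornstein–Uhlenbeck lateral noise; probe
    residues are posed in contact geometry (satisfying their detector
    with ≥0.3 Å / ≥5° margin) on their scheduled frames and parked far
    outside all cutoffs otherwise, so the detector record set is exactly
    the schedule.  Returns ``(Trajectory, GroundTruth)``.
    """
    schedule = schedule or default_translocation_schedule()
    channel_spec = channel_spec or ChannelSpec(kind="cylinder", rho_params=(12.0,))
    rng = np.random.default_rng(schedule.seed)

    channel_atoms = _channel_atoms(channel_spec)
    next_id = channel_atoms[-1].atom_id + 1

    # ligand atoms, recentered so the mass-weighted COM is exactly at the origin
    from .models import ELEMENT_MASSES

    lig_local = np.array([p for _, _, p in _LIG_ATOMS] + _hexagon(_LIG_RING_CENTER))
    lig_names = [n for n, _, _ in _LIG_ATOMS] + [f"CR{k}" for k in range(1, 7)]
    lig_elements = [e for _, e, _ in _LIG_ATOMS] + ["C"] * 6
    masses = np.array([ELEMENT_MASSES[e] for e in lig_elements])
    com_shift = (lig_local * masses[:, None]).sum(axis=0) / masses.sum()
    lig_local = lig_local - com_shift

    lig_atoms = []
    lig_ids = {}
    from .models import BACKBONE_NAMES

    for name, el, pos in zip(lig_names, lig_elements, lig_local):
        lig_atoms.append(
            AtomRecord(
                atom_id=next_id, name=name, element=el, residue_name="LIG",
                residue_number=1, chain_id="L", position=pos,
                vdw_radius=1.5, is_backbone=name in BACKBONE_NAMES,
            )
        )
        lig_ids[name] = next_id
        next_id += 1

    probes = _build_probes(schedule.events)
    probe_atoms: list[AtomRecord] = []
    probe_slices: list[slice] = []
    probe_park: list[np.ndarray] = []
    probe_pose: list[np.ndarray] = []
    for p in probes:
        start = len(probe_atoms)
        park_center = np.array(
            [_PARK_RADIUS * np.cos(p.park_angle), _PARK_RADIUS * np.sin(p.park_angle), p.park_z]
        )
        pose = p.contact_pose - com_shift
        park = park_center + (pose - pose.mean(axis=0))
        for name, el, pos in zip(p.atom_names, p.elements, park):
            probe_atoms.append(
                AtomRecord(
                    atom_id=next_id, name=name, element=el, residue_name=p.resname,
                    residue_number=p.resnum, chain_id="P", position=pos, vdw_radius=1.5,
                )
            )
            next_id += 1
        probe_slices.append(slice(start, len(probe_atoms)))
        probe_park.append(park)
        probe_pose.append(pose)

    # one bridging water per HB_H2O event, posed midway with an out-of-line kink
    water_atoms: list[AtomRecord] = []
    water_pose: dict[int, np.ndarray] = {}
    water_park: dict[int, np.ndarray] = {}
    lig = {name: np.array(p) for name, _, p in _LIG_ATOMS}
    for i, ev in enumerate(schedule.events):
        if ev.itype != "HB_H2O":
            continue
        anchor = (lig["N"] if ev.ligand_part == "backbone" else lig["NH1"]) - com_shift
        # water O at 2.8 Å from both the ligand anchor and the probe O (5.0 Å apart)
        kink = float(np.sqrt(2.8 ** 2 - 2.5 ** 2))
        w = anchor + np.array([-2.5, 0.0, kink])
        water_pose[i] = w
        angle = 2 * np.pi * (len(schedule.events) + len(water_atoms)) / (len(schedule.events) + 3)
        water_park[i] = np.array(
            [_PARK_RADIUS * np.cos(angle), _PARK_RADIUS * np.sin(angle), ev.slice_low + 0.5]
        )
        water_atoms.append(
            AtomRecord(
                atom_id=next_id, name="O", element="O", residue_name="HOH",
                residue_number=601 + i, chain_id="W", position=water_park[i],
                vdw_radius=1.5,
            )
        )
        next_id += 1

    atoms = channel_atoms + lig_atoms + probe_atoms + water_atoms

    # group annotations
    groups: list[GroupAnnotation] = []
    gid = 0

    def add(kind, ids, tag, charge_center=None):
        nonlocal gid
        gid += 1
        groups.append(GroupAnnotation(gid, kind, tuple(ids), tag, charge_center))

    lig_tag = "L:1:LIG"
    add("hb_donor", [lig_ids["N"]], lig_tag)
    add("hb_acceptor", [lig_ids["O"]], lig_tag)
    add("hb_donor", [lig_ids["NH1"]], lig_tag)
    add("hb_donor", [lig_ids["NH2"]], lig_tag)
    add("cationic", [lig_ids[n] for n in ("NE", "CZ", "NH1", "NH2")], lig_tag,
        charge_center=lig_ids["CZ"])
    add("aromatic_ring", [lig_ids[f"CR{k}"] for k in range(1, 7)], lig_tag)

    offset = len(channel_atoms) + len(lig_atoms)
    for p, sl in zip(probes, probe_slices):
        tag = f"P:{p.resnum}:{p.resname}"
        name_to_id = {
            probe_atoms[i].name: probe_atoms[i].atom_id for i in range(sl.start, sl.stop)
        }
        add(p.group_kind, [name_to_id[n] for n in p.group_atoms], tag)
    for wa in water_atoms:
        add("water", [wa.atom_id], wa.residue_tag)

    model = StructureModel(
        atoms=atoms,
        groups=groups,
        ligand_selection=frozenset(a.atom_id for a in lig_atoms),
        protein_selection=frozenset(
            a.atom_id for a in channel_atoms + probe_atoms
        ),
        metadata={"channel_spec": channel_spec, "schedule_seed": schedule.seed},
    )

    # frame assembly
    n = schedule.n_frames
    x_noise = _ou_noise(rng, n, schedule.lateral_sigma, schedule.lateral_tau)
    y_noise = _ou_noise(rng, n, schedule.lateral_sigma, schedule.lateral_tau)

    n_channel = len(channel_atoms)
    n_lig = len(lig_atoms)
    channel_xyz = np.array([a.position for a in channel_atoms])

    frames = []
    event_frames = [set(ev.frames) for ev in schedule.events]
    for f in range(n):
        shift = np.array([x_noise[f], y_noise[f], schedule.z_path[f]])
        frame = np.empty((model.n_atoms, 3))
        frame[:n_channel] = channel_xyz
        frame[n_channel:n_channel + n_lig] = lig_local + shift
        cursor = n_channel + n_lig
        for i, (p, pose, park) in enumerate(zip(probes, probe_pose, probe_park)):
            n_p = pose.shape[0]
            if f in event_frames[i]:
                placed = pose + shift
                # a posed probe must stay inside the channel lumen
                lat = np.linalg.norm(placed[:, :2], axis=1)
                z_here = placed[:, 2]
                limit = np.asarray(channel_spec.radius_fn(z_here)) - channel_spec.atom_radius
                if np.any(lat > limit + clash_tolerance):
                    raise ConfigError(
                        f"frame {f}: probe {p.resname}{p.resnum} clashes with the channel wall"
                    )
                frame[cursor:cursor + n_p] = placed
            else:
                frame[cursor:cursor + n_p] = park
            cursor += n_p
        for i, ev in enumerate(schedule.events):
            if i not in water_pose:
                continue
            if f in event_frames[i]:
                frame[cursor] = water_pose[i] + shift
            else:
                frame[cursor] = water_park[i]
            cursor += 1
        frames.append(frame)

    traj = Trajectory(model=model, frames=frames)

    # ground truth
    events_gt: dict[str, tuple] = {}
    for ev, p in zip(schedule.events, probes):
        key = f"{ev.itype}|{ev.ligand_part}|{p.resname}{p.resnum}"
        prev = set(events_gt.get(key, ()))
        events_gt[key] = tuple(sorted(prev | set(ev.frames)))
    gt = GroundTruth(
        n_frames=n,
        com_z=schedule.z_path.copy(),
        events=events_gt,
        slice_z_min=slice_z_min,
        slice_width=slice_width,
        n_slices=n_slices,
        seed=schedule.seed,
    )
    gt.p_star = gt.recompute_p_star()
    return traj, gt
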