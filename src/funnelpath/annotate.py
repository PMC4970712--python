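"""Van der Waals radius assignment and functional-group typing.

Radii default to the HOLE "simple" set, the conventional choice for
maximal-sphere pore profiling.  Group typing maps residue/atom-name
patterns to the partner classes the interaction detectors consume:
H-bond donors/acceptors, cationic and anionic groups, aromatic rings and
waters.  Both tables are plain dictionaries and can be overridden from
YAML configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .models import (
    GroupAnnotation,
    StructureModel,
    TypingError,
)

__all__ = [
    "SIMPLE_RADII",
    "WATER_RESNAMES",
    "Ruleset",
    "assign_radii",
    "annotate_groups",
]

# HOLE "simple" radius set (Å).
SIMPLE_RADII = {"C": 1.85, "N": 1.75, "O": 1.65, "S": 2.00, "H": 1.00, "P": 2.10}

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def assign_radii(
    model: StructureModel,
    table: dict | None = None,
    default: float | None = None,
) -> StructureModel:
    """Return a copy of ``model`` with per-atom vdW radii from ``table``.

    Elements absent from the table take ``default`` (with a warning); if no
    default is configured an unknown element raises :class:`TypingError`.
    """
    table = SIMPLE_RADII if table is None else table
    lookup = {k.upper(): float(v) for k, v in table.items()}
    atoms = []
    warned: set[str] = set()
    for a in model.atoms:
        el = a.element.upper()
        if el in lookup:
            r = lookup[el]
        elif default is not None:
            r = float(default)
            if el not in warned:
                warnings.warn(
                    f"element {el!r} not in radius table; using default {default} Å",
                    stacklevel=2,
                )
                warned.add(el)
        else:
            raise TypingError(f"no radius for element {el!r} and no default configured")
        atoms.append(replace(a, vdw_radius=r))
    return StructureModel(
        atoms=atoms,
        groups=list(model.groups),
        ligand_selection=model.ligand_selection,
        protein_selection=model.protein_selection,
        metadata=dict(model.metadata),
    )


@dataclass
class GroupRule:
    """One group recipe inside a residue: kind + ordered member atom names."""

    kind: str
    atom_names: tuple
    charge_center: str | None = None


@dataclass
class Ruleset:
    """Residue-name → group recipes, plus backbone and water conventions.

    ``backbone_polar`` adds an N donor and an O acceptor to every amino
    acid backbone; waters become single-residue ``water`` groups.
    """

    residue_rules: dict = field(default_factory=dict)
    water_resnames: frozenset = WATER_RESNAMES
    backbone_polar: bool = True
    amino_acids: frozenset = AMINO_ACIDS

    @classmethod
    def default(cls) -> "Ruleset":
        rules: dict[str, list[GroupRule]] = {
            "ARG": [
                GroupRule("cationic", ("NE", "CZ", "NH1", "NH2"), charge_center="CZ"),
                GroupRule("hb_donor", ("NE",)),
                GroupRule("hb_donor", ("NH1",)),
                GroupRule("hb_donor", ("NH2",)),
            ],
            "LYS": [
                GroupRule("cationic", ("NZ",), charge_center="NZ"),
                GroupRule("hb_donor", ("NZ",)),
            ],
            "ASP": [
                GroupRule("anionic", ("OD1", "OD2")),
                GroupRule("hb_acceptor", ("OD1",)),
                GroupRule("hb_acceptor", ("OD2",)),
            ],
            "GLU": [
                GroupRule("anionic", ("OE1", "OE2")),
                GroupRule("hb_acceptor", ("OE1",)),
                GroupRule("hb_acceptor", ("OE2",)),
            ],
            "SER": [
                GroupRule("hb_donor", ("OG",)),
                GroupRule("hb_acceptor", ("OG",)),
            ],
            "THR": [
                GroupRule("hb_donor", ("OG1",)),
                GroupRule("hb_acceptor", ("OG1",)),
            ],
            "ASN": [
                GroupRule("hb_donor", ("ND2",)),
                GroupRule("hb_acceptor", ("OD1",)),
            ],
            "GLN": [
                GroupRule("hb_donor", ("NE2",)),
                GroupRule("hb_acceptor", ("OE1",)),
            ],
            "PHE": [
                GroupRule("aromatic_ring", ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")),
            ],
            "TYR": [
                GroupRule("aromatic_ring", ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")),
                GroupRule("hb_donor", ("OH",)),
                GroupRule("hb_acceptor", ("OH",)),
            ],
            # Trp carries two fused rings; either one may satisfy a
            # ring-based contact, so both are annotated.
            "TRP": [
                GroupRule("aromatic_ring", ("CG", "CD1", "NE1", "CE2", "CD2")),
                GroupRule("aromatic_ring", ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2")),
                GroupRule("hb_donor", ("NE1",)),
            ],
        }
        return cls(residue_rules=rules)

    @classmethod
    def from_dict(cls, spec: dict) -> "Ruleset":
        rules: dict[str, list[GroupRule]] = {}
        for resname, entries in spec.get("residues", {}).items():
            rules[resname.upper()] = [
                GroupRule(
                    kind=e["kind"],
                    atom_names=tuple(e["atoms"]),
                    charge_center=e.get("charge_center"),
                )
                for e in entries
            ]
        return cls(
            residue_rules=rules,
            water_resnames=frozenset(
                n.upper() for n in spec.get("water_resnames", sorted(WATER_RESNAMES))
            ),
            backbone_polar=bool(spec.get("backbone_polar", True)),
            amino_acids=frozenset(
                n.upper() for n in spec.get("amino_acids", sorted(AMINO_ACIDS))
            ),
        )


def annotate_groups(model: StructureModel, rules: Ruleset | None = None) -> StructureModel:
    """Return a copy of ``model`` with functional groups rebuilt from ``rules``.

    Annotation is deterministic and idempotent: existing groups are
    discarded and rebuilt.  An aromatic ring whose members cannot all be
    resolved is skipped with a warning rather than failing the residue.
    """
    rules = rules or Ruleset.default()
    by_residue: dict[tuple, dict[str, int]] = {}
    residue_order: list[tuple] = []
    for a in model.atoms:
        key = (a.chain_id, a.residue_number, a.residue_name)
        if key not in by_residue:
            by_residue[key] = {}
            residue_order.append(key)
        # first occurrence wins for duplicate names (altloc already folded)
        by_residue[key].setdefault(a.name, a.atom_id)

    groups: list[GroupAnnotation] = []
    gid = 0
    for key in residue_order:
        chain, resnum, resname = key
        tag = f"{chain}:{resnum}:{resname}"
        name_map = by_residue[key]
        upper = resname.upper()
        if upper in rules.water_resnames:
            gid += 1
            groups.append(
                GroupAnnotation(
                    group_id=gid,
                    kind="water",
                    member_atom_ids=tuple(name_map[n] for n in name_map),
                    residue_tag=tag,
                )
            )
            continue
        if rules.backbone_polar and upper in rules.amino_acids:
            if "N" in name_map:
                gid += 1
                members = [name_map["N"]]
                for hname in ("H", "HN", "H1", "H2", "H3"):
                    if hname in name_map:
                        members.append(name_map[hname])
                groups.append(
                    GroupAnnotation(gid, "hb_donor", tuple(members), tag)
                )
            if "O" in name_map:
                gid += 1
                groups.append(GroupAnnotation(gid, "hb_acceptor", (name_map["O"],), tag))
        for rule in rules.residue_rules.get(upper, []):
            resolved = [name_map[n] for n in rule.atom_names if n in name_map]
            if len(resolved) != len(rule.atom_names):
                if rule.kind == "aromatic_ring":
                    warnings.warn(
                        f"{tag}: aromatic ring incomplete "
                        f"({len(resolved)}/{len(rule.atom_names)} atoms); skipped",
                        stacklevel=2,
                    )
                continue
            if rule.kind == "aromatic_ring" and len(resolved) < 5:
                warnings.warn(f"{tag}: ring has <5 members; skipped", stacklevel=2)
                continue
            if rule.kind == "hb_donor":
                # attach explicit hydrogens bonded by naming convention
                heavy = rule.atom_names[0]
                hydro = [
                    name_map[n]
                    for n in name_map
                    if n.startswith("H") and n[1:].startswith(heavy[1:]) and n != heavy
                ]
                resolved = [name_map[heavy]] + sorted(hydro)
            gid += 1
            charge_center = (
                name_map.get(rule.charge_center) if rule.charge_center else None
            )
            groups.append(
                GroupAnnotation(
                    group_id=gid,
                    kind=rule.kind,
                    member_atom_ids=tuple(resolved),
                    residue_tag=tag,
                    charge_center_id=charge_center,
                )
            )

    return StructureModel(
        atoms=list(model.atoms),
        groups=groups,
        ligand_selection=model.ligand_selection,
        protein_selection=model.protein_selection,
        metadata=dict(model.metadata),
    )
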