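import numpy as np
import pytest

from funnelpath.axis import AxisFrame
from funnelpath.models import AtomRecord, GroupAnnotation, StructureModel


@pytest.fixture
def lab_axis():
    return AxisFrame(origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]))


def build_model(atom_specs, groups=(), ligand=(), protein=()):
    """Construct a StructureModel from (name, element, resname, resnum, chain, xyz).

    ``groups`` are (kind, member_names, charge_center_name_or_None) tuples;
    member names are looked up residue-blind, first match wins.
    """
    atoms = []
    by_name = {}
    for i, (name, el, resname, resnum, chain, xyz) in enumerate(atom_specs, start=1):
        atoms.append(
            AtomRecord(
                atom_id=i, name=name, element=el, residue_name=resname,
                residue_number=resnum, chain_id=chain, position=np.asarray(xyz, float),
                vdw_radius=1.5,
                is_backbone=name in ("N", "CA", "C", "O"),
            )
        )
        by_name.setdefault(name, i)
    ann = []
    for gid, (kind, members, center) in enumerate(groups, start=1):
        ids = [by_name[m] for m in members]
        tag = atoms[ids[0] - 1].residue_tag
        ann.append(
            GroupAnnotation(gid, kind, tuple(ids), tag,
                            charge_center_id=by_name.get(center) if center else None)
        )
    lig = frozenset(by_name[n] for n in ligand)
    pro = frozenset(by_name[n] for n in protein)
    return StructureModel(atoms=atoms, groups=ann,
                          ligand_selection=lig, protein_selection=pro)


def random_rigid_transform(rng):
    """A uniformly random rotation plus a bounded translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans
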