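import numpy as np
import pytest

from funnelpath.axis import AxisFrame
from funnelpath.interactions import (
    DetectorParams,
    detect_cation_pi,
    detect_hbond,
    detect_ionic,
    detect_pi_pi,
    detect_water_bridge,
    scan_trajectory,
)
from funnelpath.models import EmptyInputError, Trajectory

from conftest import build_model, random_rigid_transform

EPS = 1e-6


def hbond_model(d, y=0.0):
    """Donor N at origin, acceptor O at distance d along x (offset y)."""
    return build_model(
        [
            ("N", "N", "LIG", 1, "L", (0, 0, 0)),
            ("O", "O", "SER", 2, "A", (d, y, 0)),
        ],
        groups=[("hb_donor", ["N"], None), ("hb_acceptor", ["O"], None)],
        ligand=["N"],
        protein=["O"],
    )


def run_hbond(model, params=None):
    donor, acceptor = model.groups
    return detect_hbond(model.positions, model, donor, acceptor,
                        params or DetectorParams(), ligand_group=donor)


@pytest.mark.parametrize(
    "d,expected",
    [
        (2.9, True),
        (3.6, False),
        (3.5, True),            # boundary is inclusive
        (3.5 - EPS, True),
        (3.5 + EPS, False),
    ],
)
def test_hbond_distance_criterion(d, expected):
    records = run_hbond(hbond_model(d))
    assert bool(records) is expected
    if records:
        assert records[0].type == "HB"
        assert records[0].distance == pytest.approx(d)


def test_hbond_explicit_hydrogen_angle():
    """With explicit H, the D-H···A angle must clear the cutoff."""

    def model_with_h(h_pos):
        return build_model(
            [
                ("N", "N", "LIG", 1, "L", (0, 0, 0)),
                ("HN1", "H", "LIG", 1, "L", h_pos),
                ("O", "O", "SER", 2, "A", (2.9, 0, 0)),
            ],
            groups=[("hb_donor", ["N", "HN1"], None), ("hb_acceptor", ["O"], None)],
            ligand=["N", "HN1"],
            protein=["O"],
        )

    params = DetectorParams(hb_use_hydrogens=True)
    # H nearly on the D→A line: angle ≈ 165° ≥ 120°
    near_linear = model_with_h((1.0, 0.13, 0.0))
    assert run_hbond(near_linear, params)
    # H far off the line: angle ≈ 86° < 120°
    bent = model_with_h((0.07, 1.0, 0.0))
    assert not run_hbond(bent, params)


def ionic_model(d):
    return build_model(
        [
            ("NH1", "N", "LIG", 1, "L", (0, 0, 0)),
            ("CZ", "C", "LIG", 1, "L", (-1.3, 0, 0)),
            ("OE1", "O", "GLU", 2, "A", (d, 0, 0)),
            ("OE2", "O", "GLU", 2, "A", (d + 1.0, 1.0, 0)),
        ],
        groups=[("cationic", ["NH1", "CZ"], "CZ"), ("anionic", ["OE1", "OE2"], None)],
        ligand=["NH1", "CZ"],
        protein=["OE1", "OE2"],
    )


@pytest.mark.parametrize(
    "d,expected",
    [(3.2, True), (4.5, False), (0.5, True), (4.0, True), (4.0 + EPS, False)],
)
def test_ionic_min_pair_distance(d, expected):
    model = ionic_model(d)
    cat, ani = model.groups
    records = detect_ionic(model.positions, model, cat, ani, DetectorParams(),
                           ligand_group=cat)
    assert bool(records) is expected
    if records:
        # the geometry is the closest N/O pair; carbon members are ignored
        assert records[0].distance == pytest.approx(d)


def ring_model(cation_pos):
    atoms = [("CZ", "C", "LIG", 1, "L", cation_pos)]
    for k in range(6):
        th = np.pi * k / 3
        atoms.append(
            (f"C{k+1}", "C", "PHE", 2, "A", (1.39 * np.cos(th), 1.39 * np.sin(th), 0))
        )
    return build_model(
        atoms,
        groups=[("cationic", ["CZ"], "CZ"),
                ("aromatic_ring", [f"C{k+1}" for k in range(6)], None)],
        ligand=["CZ"],
        protein=[f"C{k+1}" for k in range(6)],
    )


@pytest.mark.parametrize(
    "pos,expected",
    [
        ((0, 0, 4.0), True),        # on the normal: angle 0
        ((0, 0, -4.0), True),       # normal sign folded
        ((4.0, 0, 0), False),       # in-plane: angle 90
        ((0, 0, 6.0), True),        # distance boundary inclusive
        ((0, 0, 6.0 + 1e-5), False),
        ((4.0 * np.sin(np.radians(45)), 0, 4.0 * np.cos(np.radians(45))), True),
        ((4.0 * np.sin(np.radians(50)), 0, 4.0 * np.cos(np.radians(50))), False),
    ],
)
def test_cation_pi_distance_and_angle(pos, expected):
    model = ring_model(pos)
    cat, ring = model.groups
    records = detect_cation_pi(model.positions, model, cat, ring, DetectorParams(),
                               ligand_group=cat)
    assert bool(records) is expected


def two_ring_model(offset, tilt_deg=0.0):
    atoms = []
    for k in range(6):
        th = np.pi * k / 3
        atoms.append(
            (f"A{k+1}", "C", "LIG", 1, "L", (1.39 * np.cos(th), 1.39 * np.sin(th), 0))
        )
    tilt = np.radians(tilt_deg)
    rot = np.array(
        [[1, 0, 0], [0, np.cos(tilt), -np.sin(tilt)], [0, np.sin(tilt), np.cos(tilt)]]
    )
    for k in range(6):
        th = np.pi * k / 3
        p = rot @ np.array([1.39 * np.cos(th), 1.39 * np.sin(th), 0.0]) + offset
        atoms.append((f"B{k+1}", "C", "TRP", 2, "A", tuple(p)))
    return build_model(
        atoms,
        groups=[("aromatic_ring", [f"A{k+1}" for k in range(6)], None),
                ("aromatic_ring", [f"B{k+1}" for k in range(6)], None)],
        ligand=[f"A{k+1}" for k in range(6)],
        protein=[f"B{k+1}" for k in range(6)],
    )


@pytest.mark.parametrize(
    "offset,tilt,expected",
    [
        ((0, 0, 4.0), 0.0, True),      # parallel stacking
        ((0, 0, 4.0), 90.0, False),    # T-shaped: out of scope
        ((0, 0, 5.6), 0.0, False),     # beyond centroid cutoff
        ((0, 0, 5.5), 0.0, True),      # boundary inclusive
        ((0, 0, 4.0), 30.0, True),     # angle boundary inclusive
        ((0, 0, 4.0), 31.0, False),
    ],
)
def test_pi_pi_parallel_stacking(offset, tilt, expected):
    model = two_ring_model(np.array(offset), tilt)
    ra, rb = model.groups
    records = detect_pi_pi(model.positions, model, ra, rb, DetectorParams(),
                           ligand_group=ra)
    assert bool(records) is expected


def bridge_model(water_positions, d_pair=5.0):
    atoms = [
        ("N", "N", "LIG", 1, "L", (0, 0, 0)),
        ("OG", "O", "SER", 2, "A", (d_pair, 0, 0)),
    ]
    for i, w in enumerate(water_positions):
        atoms.append(("O" if i == 0 else f"O{i}", "O", "HOH", 100 + i, "W", w))
    groups = [("hb_donor", ["N"], None), ("hb_acceptor", ["OG"], None)]
    for i in range(len(water_positions)):
        groups.append(("water", ["O" if i == 0 else f"O{i}"], None))
    return build_model(atoms, groups=groups, ligand=["N"], protein=["OG"])


def test_water_bridge_detection():
    mid = (2.5, 0.0, np.sqrt(2.8 ** 2 - 2.5 ** 2))  # 2.8 Å from both partners
    model = bridge_model([mid])
    lig, pro = model.groups[0], model.groups[1]
    waters = model.groups_of_kind("water")
    records = detect_water_bridge(model.positions, model, lig, pro, waters)
    assert len(records) == 1
    assert records[0].type == "HB_H2O"
    assert records[0].bridging_water == "W:100:HOH"


def test_water_bonded_to_one_side_only_is_no_bridge():
    model = bridge_model([(1.0, 0.0, 0.0)], d_pair=9.0)  # near ligand, far from protein
    lig, pro = model.groups[0], model.groups[1]
    records = detect_water_bridge(model.positions, model, lig, pro,
                                  model.groups_of_kind("water"))
    assert records == []


def test_two_bridging_waters_give_two_records():
    z = np.sqrt(2.8 ** 2 - 2.5 ** 2)
    model = bridge_model([(2.5, 0.0, z), (2.5, 0.0, -z)])
    lig, pro = model.groups[0], model.groups[1]
    records = detect_water_bridge(model.positions, model, lig, pro,
                                  model.groups_of_kind("water"))
    assert len(records) == 2
    # multiplicity is kept in records; profiling collapses to pair presence
    assert len({r.bridging_water for r in records}) == 2


def _all_detector_fixtures():
    fixtures = []
    m = hbond_model(2.9)
    fixtures.append(("HB+", m, lambda mm: run_hbond(mm)))
    m = hbond_model(4.2)
    fixtures.append(("HB-", m, lambda mm: run_hbond(mm)))
    m = ionic_model(3.2)
    fixtures.append(
        ("ionic+", m,
         lambda mm: detect_ionic(mm.positions, mm, mm.groups[0], mm.groups[1])))
    m = ring_model((0, 0, 4.0))
    fixtures.append(
        ("catpi+", m,
         lambda mm: detect_cation_pi(mm.positions, mm, mm.groups[0], mm.groups[1])))
    m = ring_model((5.0, 0, 1.0))
    fixtures.append(
        ("catpi-", m,
         lambda mm: detect_cation_pi(mm.positions, mm, mm.groups[0], mm.groups[1])))
    m = two_ring_model(np.array([0, 0, 4.0]))
    fixtures.append(
        ("pipi+", m,
         lambda mm: detect_pi_pi(mm.positions, mm, mm.groups[0], mm.groups[1])))
    z = np.sqrt(2.8 ** 2 - 2.5 ** 2)
    m = bridge_model([(2.5, 0.0, z)])
    fixtures.append(
        ("bridge+", m,
         lambda mm: detect_water_bridge(mm.positions, mm, mm.groups[0], mm.groups[1],
                                        mm.groups_of_kind("water"))))
    return fixtures


def test_detectors_invariant_under_rigid_transforms():
    """No classification flips over random joint rotations+translations."""
    rng = np.random.default_rng(17)
    fixtures = _all_detector_fixtures()
    base = {name: bool(run(m)) for name, m, run in fixtures}
    flips = 0
    for _ in range(200):
        rot, trans = random_rigid_transform(rng)
        for name, m, run in fixtures:
            moved = m.with_positions(m.positions @ rot.T + trans)
            if bool(run(moved)) != base[name]:
                flips += 1
    assert flips == 0


def test_detectors_are_pure_functions():
    for name, m, run in _all_detector_fixtures():
        assert run(m) == run(m)


def scripted_hbond_trajectory():
    """10 frames; the acceptor sits in range only on frames 0-3."""
    model = hbond_model(2.9)
    frames = []
    for f in range(10):
        pos = model.positions.copy()
        if f >= 4:
            pos[1, 0] = 8.0  # move the acceptor out of range
        frames.append(pos)
    return Trajectory(model=model, frames=frames)


def test_scan_trajectory_scripted_events(lab_axis):
    traj = scripted_hbond_trajectory()
    table = scan_trajectory(traj, lab_axis)
    hb = [r for r in table.records if r.type == "HB"]
    assert sorted(r.frame_index for r in hb) == [0, 1, 2, 3]
    assert len(table.com_z) == 10
    assert np.all(np.isfinite(table.com_z))


def test_scan_requires_ligand():
    model = hbond_model(2.9)
    stripped = build_model(
        [("O", "O", "SER", 2, "A", (0, 0, 0))],
        groups=[("hb_acceptor", ["O"], None)],
        protein=["O"],
    )
    traj = Trajectory(model=stripped, frames=[stripped.positions])
    with pytest.raises(EmptyInputError):
        scan_trajectory(traj, AxisFrame(np.zeros(3), np.array([0.0, 0.0, 1.0])))
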