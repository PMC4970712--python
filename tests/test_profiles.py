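import numpy as np
import pytest

from funnelpath.interactions import InteractionRecord, InteractionTable
from funnelpath.models import EmptyInputError, Trajectory
from funnelpath.profiles import (
    SliceGrid,
    interaction_probability_profile,
    kabsch,
    ligand_rmsd_trace,
    occupancy_profile,
    protein_rmsd_trace,
    restraint_potential,
    rmsd_occurrence_histogram,
    rmsf_profile,
    target_rmsd_trace,
)

from conftest import build_model, random_rigid_transform


def table_from_script(com_z, present_frames, itype="HB", part="backbone",
                      partner="A:10:SER"):
    """An InteractionTable with one key present on the given frames."""
    com_z = np.asarray(com_z, dtype=float)
    records = [
        InteractionRecord(frame_index=f, type=itype, ligand_part=part,
                          partner_residue=partner, distance=3.0)
        for f in present_frames
    ]
    return InteractionTable(records=records, com_z=com_z, n_frames=len(com_z))


GRID = SliceGrid(z_min=-15.0, width=1.0, n_slices=30)


def test_probability_is_presence_over_occupancy():
    """10 frames in one slice, interaction in 4 of them → P = 0.4."""
    table = table_from_script([0.5] * 10, present_frames=range(4))
    prof = interaction_probability_profile([table], GRID)
    i = prof.keys.index(("HB", "backbone", "SER10"))
    s = GRID.index(np.array([0.5]))[0]
    assert prof.probability[i, s] == pytest.approx(0.4)
    assert prof.occupancy[s] == 10
    # empty slices are masked, never 0/0
    assert np.isnan(prof.probability[i, 0])


def test_occurrence_filter_threshold_semantics():
    """Peak ≥ 20% is kept (inclusive); a 15% peak is dropped."""
    kept = table_from_script([0.5] * 10, range(2))          # peak 0.2
    decoy = table_from_script([1.5] * 20, range(3),
                              partner="A:11:GLU")           # peak 0.15
    prof = interaction_probability_profile([kept, decoy], GRID, threshold=0.20)
    assert ("HB", "backbone", "SER10") in prof.kept_keys
    assert ("HB", "backbone", "GLU11") not in prof.kept_keys


def test_raising_threshold_never_adds_keys():
    tables = [
        table_from_script([0.5] * 10, range(5)),
        table_from_script([1.5] * 10, range(3), partner="A:11:GLU"),
    ]
    kept_sets = []
    for thr in (0.1, 0.3, 0.5, 0.8):
        prof = interaction_probability_profile(tables, GRID, threshold=thr)
        kept_sets.append(set(prof.kept_keys))
    for lo, hi in zip(kept_sets, kept_sets[1:]):
        assert hi <= lo


def test_pooling_is_order_invariant():
    t1 = table_from_script([0.5] * 10, range(4))
    t2 = table_from_script([0.5, 1.5] * 5, range(2), partner="A:11:GLU")
    a = interaction_probability_profile([t1, t2], GRID)
    b = interaction_probability_profile([t2, t1], GRID)
    for key in a.keys:
        ia, ib = a.keys.index(key), b.keys.index(key)
        np.testing.assert_array_equal(
            np.nan_to_num(a.probability[ia], nan=-1),
            np.nan_to_num(b.probability[ib], nan=-1),
        )
    np.testing.assert_array_equal(a.occupancy, b.occupancy)


def test_probability_bounds_and_counts():
    rng = np.random.default_rng(5)
    com = rng.uniform(-14, 14, size=200)
    present = rng.choice(200, size=80, replace=False)
    prof = interaction_probability_profile([table_from_script(com, present)], GRID)
    p = prof.probability[0]
    ok = ~np.isnan(p)
    assert np.all(p[ok] >= 0) and np.all(p[ok] <= 1)
    assert np.all(prof.present_counts[0] <= prof.occupancy)
    assert prof.occupancy.sum() + prof.overflow == 200


def test_keys_pool_over_chains():
    t1 = table_from_script([0.5] * 10, range(5), partner="A:10:SER")
    t2 = table_from_script([0.5] * 10, range(5), partner="B:10:SER")
    prof = interaction_probability_profile([t1, t2], GRID)
    assert prof.keys == [("HB", "backbone", "SER10")]
    assert prof.probability[0, GRID.index(np.array([0.5]))[0]] == pytest.approx(0.5)


def test_occupancy_profile_and_boundary():
    # COM exactly on a slice edge belongs to the upper slice [1, 2)
    table = table_from_script([1.0] * 7 + [0.999] * 3, [])
    counts, overflow = occupancy_profile([table], GRID)
    k_upper = GRID.index(np.array([1.0]))[0]
    assert counts[k_upper] == 7
    assert counts[k_upper - 1] == 3
    assert overflow == 0
    # scripted dwell: 20 frames at z = 0.5 → slice [0, 1) counts 20
    table = table_from_script([0.5] * 20, [])
    counts, _ = occupancy_profile([table], GRID)
    assert counts[GRID.index(np.array([0.5]))[0]] == 20


def test_uniform_sweep_fills_slices_evenly():
    z = np.repeat(np.arange(-15, 15, 1.0) + 0.5, 10)  # 300 frames, 10 per slice
    counts, overflow = occupancy_profile([table_from_script(z, [])], GRID)
    assert overflow == 0
    np.testing.assert_array_equal(counts, 10)


# ---------------------------------------------------------------------------
# RMSD / RMSF


def ligand_protein_model():
    return build_model(
        [
            ("CA", "C", "PRO1", 1, "A", (0, 0, 0)),
            ("CB", "C", "PRO1", 1, "A", (3, 0, 0)),
            ("CC", "C", "PRO1", 2, "A", (0, 3, 0)),
            ("CD", "C", "PRO1", 2, "A", (0, 0, 3)),
            ("C1", "C", "LIG", 9, "L", (1, 1, 1)),
            ("C2", "C", "LIG", 9, "L", (2, 1, 1)),
            ("N1", "N", "LIG", 9, "L", (1, 2, 1)),
        ],
        ligand=["C1", "C2", "N1"],
        protein=["CA", "CB", "CC", "CD"],
    )


def test_ligand_rmsd_identity_and_translation():
    model = ligand_protein_model()
    ref = model.positions
    frames = [ref.copy(), ref.copy()]
    # frame 1: ligand rigidly displaced by (3, 4, 0) with the protein fixed
    lig_idx = model.selection_indices("ligand")
    frames[1][lig_idx] += np.array([3.0, 4.0, 0.0])
    traj = Trajectory(model=model, frames=frames)
    series = ligand_rmsd_trace(traj, ref)
    assert series[0] == pytest.approx(0.0, abs=1e-12)
    assert series[1] == pytest.approx(5.0, abs=1e-12)  # only carbons, all shifted


def test_ligand_rmsd_translation_registration():
    """A joint protein+ligand translation is removed by COM registration."""
    model = ligand_protein_model()
    ref = model.positions
    traj = Trajectory(model=model, frames=[ref + np.array([10.0, -4.0, 2.0])])
    assert ligand_rmsd_trace(traj, ref)[0] == pytest.approx(0.0, abs=1e-9)


def test_ligand_rmsd_matches_direct_formula():
    rng = np.random.default_rng(3)
    model = ligand_protein_model()
    ref = model.positions
    frames = [ref + rng.normal(size=ref.shape) for _ in range(5)]
    traj = Trajectory(model=model, frames=frames)
    series = ligand_rmsd_trace(traj, ref)
    pro = model.selection_indices("protein")
    carbons = np.array([i for i in model.selection_indices("ligand")
                        if model.atoms[i].element == "C"])
    masses = model.masses[pro]
    for f, frame in enumerate(frames):
        com_f = (frame[pro] * masses[:, None]).sum(0) / masses.sum()
        com_r = (ref[pro] * masses[:, None]).sum(0) / masses.sum()
        diff = (frame[carbons] - com_f) - (ref[carbons] - com_r)
        expect = np.sqrt((diff ** 2).sum(axis=1).mean())
        assert series[f] == pytest.approx(expect, abs=1e-9)


def test_histogram_counts_and_block_se():
    series = np.full(60, 1.0)
    hist = rmsd_occurrence_histogram(series, bin_width=0.5, n_blocks=3)
    assert hist.counts.sum() == 60
    assert (hist.counts > 0).sum() == 1  # single nonzero bin
    np.testing.assert_allclose(hist.se, 0.0)  # block-identical data
    # conservation on arbitrary input and bin width
    rng = np.random.default_rng(8)
    values = rng.uniform(0, 5, size=123)
    for bw in (0.2, 0.5, 1.1):
        hist = rmsd_occurrence_histogram(values, bin_width=bw, n_blocks=3)
        assert hist.counts.sum() == 123
    with pytest.raises(EmptyInputError):
        rmsd_occurrence_histogram(np.array([]), 0.5, 3)


def test_protein_rmsd_removes_rigid_motion():
    rng = np.random.default_rng(9)
    model = ligand_protein_model()
    ref = model.positions
    rot, trans = random_rigid_transform(rng)
    traj = Trajectory(model=model, frames=[ref @ rot.T + trans])
    series = protein_rmsd_trace(traj, ref, selection=model.selection_indices("protein"))
    assert series[0] == pytest.approx(0.0, abs=1e-6)


def test_protein_rmsd_excludes_missing_reference_residues():
    model = ligand_protein_model()
    ref = model.positions.copy().astype(float)
    ref[3] = np.nan  # residue unresolved in the reference
    moved = model.positions.copy()
    moved[3] += 100.0  # would dominate if wrongly included
    traj = Trajectory(model=model, frames=[moved])
    series = protein_rmsd_trace(traj, ref, selection=model.selection_indices("protein"))
    assert series[0] == pytest.approx(0.0, abs=1e-6)


def test_kabsch_matches_mdanalysis_qcp():
    """Independent quaternion-based superposition agrees with our Kabsch."""
    from MDAnalysis.analysis.rms import rmsd as mda_rmsd

    rng = np.random.default_rng(12)
    for _ in range(5):
        ref = rng.normal(size=(20, 3)) * 5
        mob = ref + 0.3 * rng.normal(size=ref.shape)
        rot, trans = random_rigid_transform(rng)
        mob = mob @ rot.T + trans
        r, t = kabsch(mob, ref)
        ours = np.sqrt((((mob @ r.T + t) - ref) ** 2).sum(axis=1).mean())
        theirs = mda_rmsd(mob, ref, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-8)


def test_rmsf_static_and_oscillating():
    model = ligand_protein_model()
    base = model.positions
    static = Trajectory(model=model, frames=[base] * 5)
    sel = model.selection_indices("protein")
    np.testing.assert_allclose(rmsf_profile(static, selection=sel), 0.0, atol=1e-12)

    # a symmetric breathing pair oscillates radially by ±a: zero net
    # translation and torque, so the superposition stays the identity and
    # the RMSF is exactly the RMS of the displacement series (a/2 around
    # the mean for alternating frames)
    a = 0.7
    pair = build_model(
        [
            ("C1", "C", "PRO1", 1, "A", (4.0, 0, 0)),
            ("C2", "C", "PRO1", 1, "A", (-4.0, 0, 0)),
            ("C3", "C", "PRO1", 1, "A", (0, 4.0, 0)),
            ("C4", "C", "PRO1", 1, "A", (0, -4.0, 0)),
        ],
        protein=["C1", "C2", "C3", "C4"],
    )
    frames = []
    for on in (0, 1, 0, 1, 0, 1):
        f = pair.positions.copy()
        f[0, 0] += on * a
        f[1, 0] -= on * a
        frames.append(f)
    traj = Trajectory(model=pair, frames=frames)
    rmsf = rmsf_profile(traj, selection=np.arange(4))
    np.testing.assert_allclose(rmsf[:2], a / 2, atol=1e-9)
    np.testing.assert_allclose(rmsf[2:], 0.0, atol=1e-9)


def test_rmsf_invariant_under_global_rigid_motion():
    rng = np.random.default_rng(4)
    model = ligand_protein_model()
    base = model.positions
    frames = [base + 0.2 * rng.normal(size=base.shape) for _ in range(6)]
    sel = model.selection_indices("protein")
    ref_rmsf = rmsf_profile(Trajectory(model=model, frames=frames), selection=sel)
    rot, trans = random_rigid_transform(rng)
    moved = [f @ rot.T + trans for f in frames]
    got = rmsf_profile(Trajectory(model=model, frames=moved), selection=sel)
    np.testing.assert_allclose(got, ref_rmsf, atol=1e-9)


def test_restraint_potential_schedule():
    model = ligand_protein_model()
    base = model.positions
    sel = model.selection_indices("protein")
    rng = np.random.default_rng(2)
    frames = [base + 0.5 * rng.normal(size=base.shape) for _ in range(10)]
    traj = Trajectory(model=model, frames=frames)
    series = target_rmsd_trace(traj, base, sel)
    # on-schedule trace → zero energy everywhere
    t = np.linspace(0, 1.0, series.size)
    on_schedule = series[0] * (1 - t)
    np.testing.assert_allclose(
        restraint_potential(on_schedule, k=200.0, t_total=1.0, n_atoms=sel.size),
        0.0, atol=1e-12,
    )
    # constant offset c above the schedule → U ≡ k c² / (2N)
    c = 0.3
    u = restraint_potential(on_schedule + c, k=200.0, t_total=1.0,
                            n_atoms=sel.size, rmsd0=on_schedule[0])
    np.testing.assert_allclose(u, 200.0 * c ** 2 / (2 * sel.size), atol=1e-12)
    # final frame equal to the target → RMSD(T) = 0
    traj2 = Trajectory(model=model, frames=frames[:-1] + [base])
    assert target_rmsd_trace(traj2, base, sel)[-1] == pytest.approx(0.0, abs=1e-9)
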