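"""PDB I/O, Kabsch superposition and trajectory fitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from caspflex import (
    FluctuationSpec,
    fit_trajectory,
    gen_trajectory,
    kabsch_superpose,
    read_structure,
    superpose_structures,
    write_bfactor_pdb,
    write_structure,
)
from caspflex.flexibility import residue_bfactors
from caspflex.trajectory import PDBFormatError, SuperpositionError, Trajectory


@pytest.fixture
def toy_system():
    return gen_trajectory(FluctuationSpec(sigmas=(0.2, 0.4, 0.3), n_frames=3, seed=1))


# ---------------------------------------------------------------------------
# PDB reading / writing


def test_multi_model_round_trip_preserves_order_and_coords(toy_system, tmp_path):
    top, traj = toy_system
    path = tmp_path / "toy.pdb"
    write_structure(top, traj, path)
    top2, traj2 = read_structure(path)
    assert traj2.n_frames == 3
    assert np.array_equal(top2.atom_name, top.atom_name)
    assert np.array_equal(top2.res_id, top.res_id)
    assert np.array_equal(top2.chain_id, top.chain_id)
    # PDB stores 3 decimals
    assert np.abs(traj2.coords - traj.coords).max() < 1e-3


def test_single_model_file_yields_one_frame(toy_system, tmp_path):
    top, traj = toy_system
    path = tmp_path / "single.pdb"
    write_structure(top, Trajectory(coords=traj.coords[:1]), path)
    _, traj2 = read_structure(path)
    assert traj2.n_frames == 1


def test_altloc_resolved_to_highest_occupancy(tmp_path):
    pdb = tmp_path / "altloc.pdb"
    pdb.write_text(
        "ATOM      1  N  AGLY A   1       0.000   0.000   0.000  0.40 10.00           N\n"
        "ATOM      2  N  BGLY A   1       1.000   0.000   0.000  0.60 10.00           N\n"
        "ATOM      3  CA  GLY A   1       2.000   0.000   0.000  1.00 10.00           C\n"
        "END\n"
    )
    with pytest.warns(UserWarning, match="occupancy"):
        top, traj = read_structure(pdb)
    assert top.n_atoms == 2
    # the B conformer (occupancy 0.60) survives
    assert traj.coords[0, 0, 0] == pytest.approx(1.0, abs=1e-3)


def test_inconsistent_model_atom_counts_names_model(tmp_path):
    pdb = tmp_path / "bad.pdb"
    pdb.write_text(
        "MODEL        1\n"
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C\n"
        "ENDMDL\n"
        "MODEL        2\n"
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ENDMDL\n"
    )
    with pytest.raises(PDBFormatError, match="MODEL 2"):
        read_structure(pdb)


def test_missing_element_inferred_with_warning(tmp_path):
    pdb = tmp_path / "noel.pdb"
    pdb.write_text(
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00\n"
        "ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00  0.00\n"
        "END\n"
    )
    with pytest.warns(UserWarning, match="guessed|inferred"):
        top, _ = read_structure(pdb)
    assert list(top.element) == ["C", "N"]


def test_bfactor_column_fixed_point_and_default(toy_system, tmp_path):
    top, traj = toy_system
    path = tmp_path / "b.pdb"
    # residue A1 gets the S3 subpocket value, everything else defaults to 0.00
    write_bfactor_pdb(top, traj.coords[0], {("A", 1): 2.658}, path)
    lines = [l for l in path.read_text().splitlines() if l.startswith("ATOM")]
    a1 = [l for l in lines if l[21] == "A" and int(l[22:26]) == 1]
    rest = [l for l in lines if not (l[21] == "A" and int(l[22:26]) == 1)]
    assert all(l[60:66] == "  2.66" for l in a1)
    assert all(l[60:66] == "  0.00" for l in rest)
    top2, _ = read_structure(path)  # round-trips
    assert top2.b_factor.max() == pytest.approx(2.66)


def test_bfactor_out_of_field_clamped(toy_system, tmp_path):
    top, traj = toy_system
    with pytest.warns(UserWarning, match="clamped"):
        write_bfactor_pdb(top, traj.coords[0], {("A", 1): 1e5}, tmp_path / "c.pdb")


# ---------------------------------------------------------------------------
# Kabsch superposition


def test_identical_sets_give_zero_rmsd_identity_rotation():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    res = kabsch_superpose(pts, pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-10)


def test_pure_translation_recovered():
    pts = np.random.default_rng(1).normal(size=(8, 3))
    res = kabsch_superpose(pts + np.array([5.0, 0.0, 0.0]), pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-10)
    assert res.translation == pytest.approx([-5.0, 0.0, 0.0], abs=1e-10)


def test_planar_square_rotated_90_degrees_recovered():
    square = np.array(
        [[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]]
    )
    rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    res = kabsch_superpose(square @ rot90.T, square)
    assert res.rmsd == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(res.rotation @ rot90, np.eye(3), atol=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_kabsch_matches_scipy_oracle(seed):
    """Independent oracle: scipy's own least-squares rotation solver."""
    rng = np.random.default_rng(seed)
    ref = rng.normal(size=(6, 3)) * 4
    mob = ref @ Rotation.random(random_state=seed).as_matrix().T + rng.normal(size=3)
    mob = mob + rng.normal(scale=0.3, size=mob.shape)  # imperfect match
    res = kabsch_superpose(mob, ref)
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    rot_or, rssd = Rotation.align_vectors(ref_c, mob_c)
    oracle_rmsd = rssd / np.sqrt(len(ref))
    assert res.rmsd == pytest.approx(oracle_rmsd, abs=1e-6)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)


def test_too_few_or_collinear_pairs_rejected():
    with pytest.raises(SuperpositionError, match="3 pairs"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
    with pytest.raises(SuperpositionError, match="collinear"):
        kabsch_superpose(line, line)


def test_refinement_drops_single_outlier():
    rng = np.random.default_rng(3)
    ref = rng.normal(size=(20, 3)) * 5
    mob = ref.copy()
    mob[0] += np.array([8.0, 0, 0])  # one gross outlier
    res = kabsch_superpose(mob, ref, refine_cycles=5, refine_cutoff=2.0)
    assert res.n_pairs_refined == 19
    assert res.rmsd_refined < 0.5 < res.rmsd


# ---------------------------------------------------------------------------
# trajectory fitting


def test_rigid_translations_collapse_to_identical_frames():
    base = np.random.default_rng(4).normal(size=(12, 3)) * 3
    frames = np.stack([base + np.array([i * 2.0, -i, 0.5 * i]) for i in range(5)])
    fitted = fit_trajectory(Trajectory(coords=frames), np.arange(12))
    assert np.abs(fitted.coords - fitted.coords[0]).max() < 1e-9


def test_fit_changes_bfactors_under_one_percent_on_drift_free_data():
    top, traj = gen_trajectory(
        FluctuationSpec(sigmas=(0.3,) * 150, n_frames=300, seed=5)
    )
    fitted = fit_trajectory(traj, top.ca_indices())
    raw = residue_bfactors(traj, top)
    fit = residue_bfactors(fitted, top)
    assert fit.protein_average_b == pytest.approx(raw.protein_average_b, rel=0.01)


def test_fit_is_idempotent(toy_system):
    top, traj = gen_trajectory(FluctuationSpec(sigmas=(0.4, 0.2), n_frames=30, seed=6))
    once = fit_trajectory(traj, top.ca_indices())
    twice = fit_trajectory(once, top.ca_indices())
    assert np.abs(twice.coords - once.coords).max() < 1e-9


def test_fit_requires_frames_and_selection(toy_system):
    top, traj = toy_system
    with pytest.raises(ValueError, match="selection"):
        fit_trajectory(traj, np.array([], dtype=int))
    with pytest.raises(ValueError, match="frames"):
        fit_trajectory(Trajectory(coords=traj.coords[:1]), top.ca_indices())


# ---------------------------------------------------------------------------
# cross-structure superposition


def test_sequence_matched_superposition_recovers_transform():
    top_a, traj_a = gen_trajectory(FluctuationSpec(sigmas=(0.0,) * 25, n_frames=1, seed=1))
    top_b, traj_b = gen_trajectory(FluctuationSpec(sigmas=(0.0,) * 25, n_frames=1, seed=2))
    rot = Rotation.from_euler("xyz", [15, -40, 70], degrees=True).as_matrix()
    moved = traj_b.coords[0] @ rot.T + np.array([3.0, -7.0, 1.0])
    res = superpose_structures(top_a, traj_a.coords[0], top_b, moved)
    assert res.n_pairs == 50  # 25 residues x 2 chains
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
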