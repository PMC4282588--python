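"""Hydrogen-bond detection/occupancy and distance statistics."""

import math

import numpy as np
import pytest

from caspflex import (
    HBondCriteria,
    HBondGrouping,
    HBondReport,
    HBondSeriesSpec,
    assign_donors_acceptors,
    distance_stats,
    distance_stats_from_series,
    gen_distance_series,
    gen_hbond_series,
    hbond_occupancy,
    hbonds_in_frame,
)
from caspflex.interactions import _geometry_is_bond
from caspflex.synthetic import _acceptor_position
from caspflex.trajectory import Topology, Trajectory


def _linear_system(da_distance, dha_angle):
    """Donor N(+H), one ligand acceptor O at a prescribed geometry."""
    top = Topology(
        atom_name=np.array(["N", "H", "CA", "O"], dtype=object),
        element=np.array(["N", "H", "C", "O"], dtype=object),
        res_name=np.array(["GLY", "GLY", "GLY", "GLY"], dtype=object),
        res_id=np.array([1, 1, 1, 1], dtype=int),
        chain_id=np.array(["A", "A", "A", "L"], dtype=object),
        ins_code=np.array([""] * 4, dtype=object),
    )
    coords = np.array(
        [[0.0, 0, 0], [1.0, 0, 0], [-1.0, -1.0, 0], list(_acceptor_position(da_distance, dha_angle))]
    )
    return top, coords


GROUPING = HBondGrouping(
    protein_subpockets={("A", 1): "S3"},
    ligand_positions={("L", 1): "P3"},
    protomer_of_chain={"A": "1"},
)


# ---------------------------------------------------------------------------
# donor/acceptor assignment


def test_nh_is_donor_and_carbonyl_o_is_acceptor():
    top, coords = _linear_system(2.9, 180.0)
    sets = assign_donors_acceptors(top, coords)
    assert sets.donors == [(0, 1)]
    assert set(sets.acceptors) == {0, 3}  # N and O; carbon never


def test_multiple_hydrogens_give_multiple_donor_entries():
    # lysine-like N with three hydrogens
    top = Topology(
        atom_name=np.array(["NZ", "HZ1", "HZ2", "HZ3"], dtype=object),
        element=np.array(["N", "H", "H", "H"], dtype=object),
        res_name=np.array(["LYS"] * 4, dtype=object),
        res_id=np.array([1] * 4, dtype=int),
        chain_id=np.array(["A"] * 4, dtype=object),
        ins_code=np.array([""] * 4, dtype=object),
    )
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [-0.5, 0.87, 0], [-0.5, -0.87, 0]])
    sets = assign_donors_acceptors(top, coords)
    assert len(sets.donors) == 3
    assert all(heavy == 0 for heavy, _ in sets.donors)


def test_structure_without_hydrogens_rejected():
    top, coords = _linear_system(2.9, 180.0)
    mask = np.asarray(top.element) != "H"
    stripped = Topology(
        atom_name=np.asarray(top.atom_name)[mask],
        element=np.asarray(top.element)[mask],
        res_name=np.asarray(top.res_name)[mask],
        res_id=np.asarray(top.res_id)[mask],
        chain_id=np.asarray(top.chain_id)[mask],
        ins_code=np.asarray(top.ins_code)[mask],
    )
    with pytest.raises(ValueError, match="hydrogens"):
        assign_donors_acceptors(stripped, coords[mask])


# ---------------------------------------------------------------------------
# per-frame detection


@pytest.mark.parametrize(
    "distance, angle, bonded",
    [
        (2.9, 180.0, True),    # comfortable bond
        (3.05, 180.0, False),  # distance just over the cutoff
        (2.8, 130.0, False),   # angle under the cutoff
        (3.0, 135.0, True),    # both exactly at the boundary: inclusive
    ],
)
def test_criteria_boundaries(distance, angle, bonded):
    top, coords = _linear_system(distance, angle)
    sets = assign_donors_acceptors(top, coords)
    found = hbonds_in_frame(coords, sets)
    assert (len(found) == 1) is bonded
    assert _geometry_is_bond(distance, angle, HBondCriteria()) is bonded


def test_realized_geometry_matches_construction():
    top, coords = _linear_system(3.0, 135.0)
    d = np.linalg.norm(coords[3] - coords[0])
    v1, v2 = coords[0] - coords[1], coords[3] - coords[1]
    ang = math.degrees(
        math.acos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    )
    assert d == pytest.approx(3.0, abs=1e-9)
    assert ang == pytest.approx(135.0, abs=1e-9)


def test_brute_force_pair_scan_equivalence():
    """Exhaustive all-pairs oracle on a random 40-atom system."""
    rng = np.random.default_rng(12)
    n = 40
    elements = rng.choice(["N", "O", "C", "H"], size=n, p=[0.2, 0.2, 0.3, 0.3])
    top = Topology(
        atom_name=np.array([f"X{i}" for i in range(n)], dtype=object),
        element=np.array(elements, dtype=object),
        res_name=np.array(["GLY"] * n, dtype=object),
        res_id=np.array(np.arange(n) // 4 + 1, dtype=int),
        chain_id=np.array(["A"] * n, dtype=object),
        ins_code=np.array([""] * n, dtype=object),
    )
    coords = rng.uniform(0, 8, size=(n, 3))
    sets = assign_donors_acceptors(top, coords)
    got = set(hbonds_in_frame(coords, sets))

    expected = set()
    crit = HBondCriteria()
    for heavy, h in sets.donors:
        for a in sets.acceptors:
            if a == heavy:
                continue
            if (top.chain_id[a], top.res_id[a]) == (top.chain_id[heavy], top.res_id[heavy]):
                continue
            dist = np.linalg.norm(coords[a] - coords[heavy])
            v1, v2 = coords[heavy] - coords[h], coords[a] - coords[h]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if dist <= crit.max_heavy_distance and ang >= crit.min_dha_angle:
                expected.add((heavy, h, a))
    assert got == expected


def test_loosening_criteria_never_decreases_count():
    rng = np.random.default_rng(7)
    top, coords = _linear_system(2.9, 180.0)
    for _ in range(20):
        jitter = coords + rng.normal(scale=0.8, size=coords.shape)
        sets = assign_donors_acceptors(top, coords)  # bonds from reference
        tight = len(hbonds_in_frame(jitter, sets, HBondCriteria(3.0, 135.0)))
        loose = len(hbonds_in_frame(jitter, sets, HBondCriteria(3.5, 120.0)))
        assert loose >= tight


# ---------------------------------------------------------------------------
# occupancy over trajectories


def test_occupancy_reproduces_constructed_value_exactly():
    top, traj = gen_hbond_series(HBondSeriesSpec(occupancy=0.5, n_frames=1000, seed=1))
    sets = assign_donors_acceptors(top, traj.coords[0])
    report = hbond_occupancy(traj, sets, GROUPING)
    assert report.groups[("S3", "P3")] == 0.500
    assert report.total == 0.500


def test_frame_permutation_leaves_occupancy_unchanged():
    top, traj = gen_hbond_series(HBondSeriesSpec(occupancy=0.3, n_frames=200, seed=2))
    sets = assign_donors_acceptors(top, traj.coords[0])
    before = hbond_occupancy(traj, sets, GROUPING)
    shuffled = Trajectory(coords=traj.coords[np.random.default_rng(0).permutation(200)])
    after = hbond_occupancy(shuffled, sets, GROUPING)
    assert before.groups == after.groups


def test_two_saturated_pairs_sum_to_two():
    """Group values are sums of pair occupancies, hence may exceed 1."""
    base_top, base_coords = _linear_system(2.9, 180.0)
    # duplicate the donor/acceptor pair as residue 2 far away
    shift = np.array([30.0, 0.0, 0.0])
    top = Topology(
        atom_name=np.concatenate([base_top.atom_name] * 2),
        element=np.concatenate([base_top.element] * 2),
        res_name=np.concatenate([base_top.res_name] * 2),
        res_id=np.concatenate([base_top.res_id, base_top.res_id + 1]),
        chain_id=np.concatenate([base_top.chain_id] * 2),
        ins_code=np.concatenate([base_top.ins_code] * 2),
    )
    coords = np.vstack([base_coords, base_coords + shift])
    traj = Trajectory(coords=np.stack([coords] * 10))
    sets = assign_donors_acceptors(top, coords)
    grouping = HBondGrouping(
        protein_subpockets={("A", 1): "S1", ("A", 2): "S1"},
        ligand_positions={("L", 1): "P1", ("L", 2): "P1"},
        protomer_of_chain={"A": "1"},
    )
    report = hbond_occupancy(traj, sets, grouping)
    assert report.groups[("S1", "P1")] == pytest.approx(2.0)


def test_protomer_occupancies_are_averaged():
    base_top, base_coords = _linear_system(2.9, 180.0)
    # same pair in a second protomer (chains B/M), but permanently broken there
    top = Topology(
        atom_name=np.concatenate([base_top.atom_name] * 2),
        element=np.concatenate([base_top.element] * 2),
        res_name=np.concatenate([base_top.res_name] * 2),
        res_id=np.concatenate([base_top.res_id] * 2),
        chain_id=np.array(["A", "A", "A", "L", "B", "B", "B", "M"], dtype=object),
        ins_code=np.concatenate([base_top.ins_code] * 2),
    )
    far = base_coords + np.array([40.0, 0.0, 0.0])
    far[3] += np.array([10.0, 0.0, 0.0])  # acceptor out of reach
    coords = np.vstack([base_coords, far])
    traj = Trajectory(coords=np.stack([coords] * 8))
    sets = assign_donors_acceptors(top, coords)
    grouping = HBondGrouping(
        protein_subpockets={("A", 1): "S1", ("B", 1): "S1"},
        ligand_positions={("L", 1): "P1", ("M", 1): "P1"},
        protomer_of_chain={"A": "1", "B": "2"},
    )
    report = hbond_occupancy(traj, sets, grouping)
    # protomer 1 at occupancy 1, protomer 2 at 0 -> dimer average 0.5
    assert report.per_protomer["1"][("S1", "P1")] == pytest.approx(1.0)
    assert report.groups[("S1", "P1")] == pytest.approx(0.5)


def test_grouping_with_unknown_residue_rejected():
    top, traj = gen_hbond_series(HBondSeriesSpec(occupancy=1.0, n_frames=5, seed=0))
    sets = assign_donors_acceptors(top, traj.coords[0])
    bad = HBondGrouping(
        protein_subpockets={("A", 99): "S1"},
        ligand_positions={("L", 1): "P1"},
        protomer_of_chain={"A": "1"},
    )
    with pytest.raises(ValueError, match="99"):
        hbond_occupancy(traj, sets, bad)


def test_report_total_is_sum_of_groups():
    report = HBondReport.from_group_values(
        {("S4", "P4"): 1.37, ("S3", "P3"): 2.46, ("S2", "P2"): 0.00, ("S1", "P1"): 3.04}
    )
    assert report.total == pytest.approx(6.87)


# ---------------------------------------------------------------------------
# distance statistics


def test_constant_distance_gives_zero_sd():
    stats = distance_stats_from_series(np.full(100, 5.31))
    assert stats.mean == pytest.approx(5.31)
    assert stats.sd_percent == pytest.approx(0.0, abs=1e-9)


def test_recovers_prescribed_cv_from_generator():
    series = gen_distance_series(5.62, 19.84, 50000, seed=3)
    stats = distance_stats_from_series(series)
    assert stats.mean == pytest.approx(5.62, abs=0.05)
    assert stats.sd_percent == pytest.approx(19.84, abs=0.5)


def test_single_observation_warns_and_reports_zero_sd():
    with pytest.warns(UserWarning, match="single"):
        stats = distance_stats_from_series(np.array([4.2]))
    assert stats.sd_percent == 0.0 and stats.n == 1


def test_pooled_protomer_distances_two_point_oracle():
    # protomers at constant distances 5 and 6: pooled mean 5.5, SD% = 100*0.5/5.5
    top = Topology(
        atom_name=np.array(["CA", "CB", "CA", "CB"], dtype=object),
        element=np.array(["C", "C", "C", "C"], dtype=object),
        res_name=np.array(["GLY"] * 4, dtype=object),
        res_id=np.array([1, 2, 1, 2], dtype=int),
        chain_id=np.array(["A", "A", "B", "B"], dtype=object),
        ins_code=np.array([""] * 4, dtype=object),
    )
    frame = np.array([[0.0, 0, 0], [5.0, 0, 0], [0.0, 20, 0], [6.0, 20, 0]])
    traj = Trajectory(coords=np.stack([frame] * 7))
    stats = distance_stats(
        traj, top, [(("A", 1, "CA"), ("A", 2, "CB")), (("B", 1, "CA"), ("B", 2, "CB"))]
    )
    assert stats.mean == pytest.approx(5.5)
    assert stats.sd_percent == pytest.approx(100 * 0.5 / 5.5)


def test_missing_atom_named_in_error():
    top, traj = gen_hbond_series(HBondSeriesSpec(occupancy=1.0, n_frames=3, seed=0))
    with pytest.raises(ValueError, match="CG"):
        distance_stats(traj, top, [(("A", 1, "CG"), ("L", 1, "O"))])
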