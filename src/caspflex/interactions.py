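"""Hydrogen-bond occupancy and distance statistics over trajectories.

A hydrogen bond is counted in a frame when the donor–acceptor heavy-atom
distance is at most 3.0 Å and the donor–hydrogen–acceptor angle is at least
135° (deviation from linearity ≤ 45°); both boundaries are inclusive so that
counts are bit-reproducible. Donors are N/O atoms with at least one bonded
hydrogen (one donor entry per hydrogen), acceptors are all N/O atoms, and
pairs within the same residue are never candidates.

Occupancy of a donor–acceptor pair is the fraction of frames in which the
bond is realized; subpocket–ligand-position group values are *sums* of pair
occupancies (and may therefore exceed 1), protomer values are averaged, and
the total is the sum over the groups.

Distances are reported as mean (Å) and standard deviation as percent of the
mean (population σ), pooled over frames and over the equivalent pair in each
protomer of a dimer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "DonorAcceptorSets",
    "HBondGrouping",
    "HBondReport",
    "DistanceStats",
    "assign_donors_acceptors",
    "hbonds_in_frame",
    "hbond_occupancy",
    "distance_stats",
    "distance_stats_from_series",
]

H_COVALENT_CUTOFF = 1.2  # Å, H belongs to the nearest N/O within this distance

# Boundary inclusivity must survive floating-point round-off: a geometry
# constructed to sit exactly on a cutoff may evaluate a few ulp past it.
_BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (defaults: 3.0 Å, 135°)."""

    max_heavy_distance: float = 3.0
    min_dha_angle: float = 135.0

    def __post_init__(self) -> None:
        if self.max_heavy_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")


def _geometry_is_bond(distance: float, angle_deg: float, criteria: HBondCriteria) -> bool:
    return (
        distance <= criteria.max_heavy_distance + _BOUNDARY_EPS
        and angle_deg >= criteria.min_dha_angle - _BOUNDARY_EPS
    )


@dataclass
class DonorAcceptorSets:
    """Indices of donor (heavy, hydrogen) pairs and acceptor heavy atoms."""

    donors: list[tuple[int, int]]   # (heavy atom index, hydrogen index)
    acceptors: list[int]
    topology: Topology

    def residue_of(self, atom_index: int) -> tuple[str, int, str]:
        t = self.topology
        return (
            str(t.chain_id[atom_index]),
            int(t.res_id[atom_index]),
            str(t.ins_code[atom_index]),
        )


def assign_donors_acceptors(
    topology: Topology, reference: np.ndarray
) -> DonorAcceptorSets:
    """Classify N/O atoms into donors (with bonded H) and acceptors.

    Hydrogen attachment is inferred from the reference frame: each hydrogen
    belongs to the nearest N/O within 1.2 Å. Structures without explicit
    hydrogens are rejected, since the angular criterion needs them.
    """
    reference = np.asarray(reference, dtype=float)
    elements = np.asarray(topology.element)
    h_idx = np.where(elements == "H")[0]
    if h_idx.size == 0:
        raise ValueError(
            "structure has no hydrogens; the H-bond criteria require explicit "
            "hydrogens (protonate the structure first)"
        )
    no_idx = np.where((elements == "N") | (elements == "O"))[0]
    if no_idx.size == 0:
        raise ValueError("structure has no N/O atoms")

    donors: list[tuple[int, int]] = []
    for h in h_idx:
        d = np.linalg.norm(reference[no_idx] - reference[h], axis=1)
        j = int(np.argmin(d))
        if d[j] <= H_COVALENT_CUTOFF:
            donors.append((int(no_idx[j]), int(h)))
    return DonorAcceptorSets(
        donors=donors, acceptors=[int(i) for i in no_idx], topology=topology
    )


def hbonds_in_frame(
    coords: np.ndarray,
    sets: DonorAcceptorSets,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[tuple[int, int, int]]:
    """All (donor heavy, hydrogen, acceptor) triples bonded in one frame.

    Realized iff d(D, A) ≤ cutoff and the D–H···A angle ≥ cutoff, both
    inclusive; same-residue pairs are excluded.
    """
    coords = np.asarray(coords, dtype=float)
    out: list[tuple[int, int, int]] = []
    acceptors = np.array(sets.acceptors, dtype=int)
    acc_res = [sets.residue_of(a) for a in acceptors]
    for heavy, h in sets.donors:
        don_res = sets.residue_of(heavy)
        delta_da = coords[acceptors] - coords[heavy]
        dist = np.linalg.norm(delta_da, axis=1)
        v1 = coords[heavy] - coords[h]
        v2 = coords[acceptors] - coords[h]
        n1 = np.linalg.norm(v1)
        n2 = np.linalg.norm(v2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (v2 @ v1) / (n1 * n2)
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        for k, a in enumerate(acceptors):
            if acc_res[k] == don_res or int(a) == heavy:
                continue
            if _geometry_is_bond(dist[k], angle[k], criteria):
                out.append((heavy, h, int(a)))
    return out


# ---------------------------------------------------------------------------
# occupancy grouping


@dataclass
class HBondGrouping:
    """Maps protein residues to subpockets and ligand residues to P-positions.

    ``protomer_of_chain`` assigns each protein chain to a protomer so that
    per-protomer occupancies can be averaged, as for a dimer.
    """

    protein_subpockets: dict[tuple[str, int], str]   # (chain, res) -> "S3"
    ligand_positions: dict[tuple[str, int], str]     # (chain, res) -> "P3"
    protomer_of_chain: dict[str, str]

    def known_residues(self) -> set[tuple[str, int]]:
        return set(self.protein_subpockets) | set(self.ligand_positions)


@dataclass
class HBondReport:
    """Occupancy sums per (subpocket, ligand position) group.

    Group values are sums of pair occupancies and may exceed 1; the total
    is the sum over groups. Protomer values are retained before averaging.
    """

    groups: dict[tuple[str, str], float]
    per_protomer: dict[str, dict[tuple[str, str], float]]
    pair_occupancies: dict[tuple[int, int, int], float]
    n_frames: int

    @property
    def total(self) -> float:
        return float(sum(self.groups.values()))

    @classmethod
    def from_group_values(cls, groups: dict[tuple[str, str], float]) -> "HBondReport":
        """Build a report directly from per-group occupancy sums.

        Used to ingest published per-subpocket occupancies and recompute
        derived quantities (the total) with the same machinery.
        """
        return cls(groups=dict(groups), per_protomer={}, pair_occupancies={}, n_frames=0)

    def as_frame(self) -> pd.DataFrame:
        rows = sorted(self.groups, key=lambda g: g[0], reverse=True)  # S4 … S1
        return pd.DataFrame(
            {
                "group": [f"{s}-{p}" for s, p in rows] + ["Total"],
                "occupancy": [self.groups[g] for g in rows] + [self.total],
            }
        )


def hbond_occupancy(
    traj: Trajectory,
    sets: DonorAcceptorSets,
    grouping: HBondGrouping,
    criteria: HBondCriteria = HBondCriteria(),
) -> HBondReport:
    """Per-(subpocket, position) hydrogen-bond occupancy sums over a trajectory.

    Pair occupancy = frames-with-bond / frames. A pair contributes to the
    group (subpocket of its protein residue, position of its ligand residue);
    bonds not crossing the protein–ligand divide are ignored. Group values
    are computed per protomer (by the protein chain's protomer) and averaged.
    """
    t = sets.topology
    known = grouping.known_residues()
    for chain, res in known:
        if not np.any((np.asarray(t.chain_id) == chain) & (np.asarray(t.res_id) == res)):
            raise ValueError(f"grouping references unknown residue ({chain}, {res})")

    counts: dict[tuple[int, int, int], int] = {}
    for f in range(traj.n_frames):
        for triple in hbonds_in_frame(traj.coords[f], sets, criteria):
            counts[triple] = counts.get(triple, 0) + 1
    occupancies = {k: v / traj.n_frames for k, v in counts.items()}

    protomers = sorted(set(grouping.protomer_of_chain.values()))
    group_keys: set[tuple[str, str]] = set()
    per_protomer: dict[str, dict[tuple[str, str], float]] = {p: {} for p in protomers}
    for (heavy, h, acc), occ in occupancies.items():
        res_d = sets.residue_of(heavy)[:2]
        res_a = sets.residue_of(acc)[:2]
        if res_d in grouping.protein_subpockets and res_a in grouping.ligand_positions:
            prot_res, lig_res = res_d, res_a
        elif res_a in grouping.protein_subpockets and res_d in grouping.ligand_positions:
            prot_res, lig_res = res_a, res_d
        else:
            continue
        key = (
            grouping.protein_subpockets[prot_res],
            grouping.ligand_positions[lig_res],
        )
        protomer = grouping.protomer_of_chain.get(prot_res[0])
        if protomer is None:
            raise ValueError(f"chain {prot_res[0]} has no protomer assignment")
        per_protomer[protomer][key] = per_protomer[protomer].get(key, 0.0) + occ
        group_keys.add(key)

    groups = {
        key: float(np.mean([per_protomer[p].get(key, 0.0) for p in protomers]))
        for key in group_keys
    }
    return HBondReport(
        groups=groups,
        per_protomer=per_protomer,
        pair_occupancies=occupancies,
        n_frames=traj.n_frames,
    )


# ---------------------------------------------------------------------------
# distance statistics


@dataclass
class DistanceStats:
    """Pooled distance mean (Å) and standard deviation as percent of mean."""

    pair: str
    mean: float
    sd_percent: float
    n: int


def distance_stats_from_series(series: np.ndarray, pair: str = "") -> DistanceStats:
    """Mean and CV (population σ as % of mean) of a scalar distance series."""
    series = np.asarray(series, dtype=float).ravel()
    if series.size == 0:
        raise ValueError("empty distance series")
    mean = float(series.mean())
    if mean <= 0:
        raise ValueError(f"non-positive mean distance {mean}")
    if series.size == 1:
        warnings.warn("single observation: SD reported as 0%", stacklevel=2)
        return DistanceStats(pair=pair, mean=mean, sd_percent=0.0, n=1)
    sd = float(series.std(ddof=0))
    return DistanceStats(pair=pair, mean=mean, sd_percent=100.0 * sd / mean, n=series.size)


AtomSpec = tuple[str, int, str]  # (chain, residue number, atom name)


def _atom_index(topology: Topology, spec: AtomSpec) -> int:
    chain, res, name = spec
    hits = np.where(
        (np.asarray(topology.chain_id) == str(chain))
        & (np.asarray(topology.res_id) == int(res))
        & (np.asarray(topology.atom_name) == name)
    )[0]
    if hits.size == 0:
        raise ValueError(f"atom {spec} not found in topology")
    return int(hits[0])


def distance_stats(
    traj: Trajectory,
    topology: Topology,
    pairs: list[tuple[AtomSpec, AtomSpec]],
) -> DistanceStats:
    """Distance statistics pooled over frames and equivalent protomer pairs.

    ``pairs`` holds one (atom, atom) specification per protomer; all their
    per-frame distances are pooled before the mean and SD(%) are taken.
    """
    if not pairs:
        raise ValueError("no atom pairs given")
    series = []
    for a_spec, b_spec in pairs:
        ia, ib = _atom_index(topology, a_spec), _atom_index(topology, b_spec)
        series.append(
            np.linalg.norm(traj.coords[:, ia, :] - traj.coords[:, ib, :], axis=1)
        )
    label = "; ".join(
        f"{a[0]}{a[1]}:{a[2]}–{b[0]}{b[1]}:{b[2]}" for a, b in pairs
    )
    return distance_stats_from_series(np.concatenate(series), pair=label)
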