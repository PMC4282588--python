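"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shapes of the real inputs — substrate cleavage
tables, dimeric trajectories, protein–ligand hydrogen-bond geometries and
scalar distance series — with prescribed statistics, so that entropy,
B-factor, occupancy and correlation recovery can be tested without MD runs
or database downloads:

* substrate windows are independent draws from per-position amino-acid
  distributions, so the analytic cleavage entropy of each position is known;
* toy trajectories displace each residue rigidly by isotropic Gaussian noise
  of per-residue σ (Å), so the Cα B-factor is analytically 8π²σ²;
* hydrogen-bond series toggle one donor–acceptor pair between a geometry
  satisfying the acceptance criteria and one violating them, hitting a target
  occupancy exactly by construction;
* distance series are Gaussian with prescribed mean and coefficient of
  variation.

All generators are deterministic given their seed; there is no global
random state. Toy topologies use valid PDB atom/residue naming so the real
readers and writers are exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .substrates import (
    AMINO_ACIDS,
    WINDOW_POSITIONS,
    SubstrateRecord,
    SubstrateSet,
)
from .trajectory import Topology, Trajectory

__all__ = [
    "PositionDistributionSpec",
    "FluctuationSpec",
    "HBondSeriesSpec",
    "gen_substrates",
    "gen_trajectory",
    "gen_hbond_series",
    "gen_distance_series",
]


@dataclass(frozen=True)
class PositionDistributionSpec:
    """Amino-acid distribution at one subsite (P4…P4')."""

    position: str
    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        if self.position not in WINDOW_POSITIONS:
            raise ValueError(f"unknown position label {self.position!r}")
        bad = [a for a in self.probabilities if a not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"{self.position}: non-canonical codes {bad}")
        probs = np.array(list(self.probabilities.values()), dtype=float)
        if np.any(probs < 0):
            raise ValueError(f"{self.position}: negative probabilities")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.position}: probabilities sum to {probs.sum():.12f}, not 1"
            )

    @classmethod
    def point_mass(cls, position: str, residue: str) -> "PositionDistributionSpec":
        return cls(position, {residue: 1.0})

    @classmethod
    def uniform(cls, position: str) -> "PositionDistributionSpec":
        return cls(position, {a: 1.0 / 20.0 for a in AMINO_ACIDS})

    def vector(self) -> np.ndarray:
        """Probability vector in canonical amino-acid order."""
        return np.array([self.probabilities.get(a, 0.0) for a in AMINO_ACIDS])

    def analytic_entropy(self) -> float:
        """Cleavage entropy (base-20 Shannon entropy) of this distribution."""
        p = self.vector()
        nz = p[p > 0]
        s = float(-(nz * np.log(nz)).sum() / math.log(20.0))
        return 0.0 if s == 0 else s


def gen_substrates(
    specs: list[PositionDistributionSpec],
    n: int,
    seed: int,
    protease: str = "synthetic",
) -> SubstrateSet:
    """Draw ``n`` eight-residue cleavage windows from per-position distributions.

    Positions without a spec default to the uniform distribution. Records are
    full eight-mers with the scissile bond between positions 4 and 5.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    seen: set[str] = set()
    for spec in specs:
        if spec.position in seen:
            raise ValueError(f"position {spec.position} specified twice")
        seen.add(spec.position)
    by_pos = {s.position: s for s in specs}
    rng = np.random.default_rng(seed)
    aa = np.array(AMINO_ACIDS)
    columns = {}
    for pos in WINDOW_POSITIONS:
        spec = by_pos.get(pos, PositionDistributionSpec.uniform(pos))
        columns[pos] = rng.choice(aa, size=n, p=spec.vector())
    records = [
        SubstrateRecord(
            identifier=f"{protease}_{i:06d}",
            sequence="".join(columns[pos][i] for pos in WINDOW_POSITIONS),
            p1_position=4,
        )
        for i in range(n)
    ]
    return SubstrateSet(records=records, protease=protease)


# ---------------------------------------------------------------------------
# toy trajectories

#: idealised in-residue offsets (Å) relative to Cα, enough to look like a
#: backbone without pretending to be one
_RESIDUE_ATOMS = (
    ("N", "N", np.array([-1.20, 0.60, 0.00])),
    ("CA", "C", np.array([0.00, 0.00, 0.00])),
    ("C", "C", np.array([1.20, 0.60, 0.00])),
    ("O", "O", np.array([1.30, 1.80, 0.20])),
)
_CA_SPACING = 3.8       # Å between consecutive residues along the chain
_CHAIN_OFFSET = 20.0    # Å between the two protomers


@dataclass(frozen=True)
class FluctuationSpec:
    """Per-residue isotropic Gaussian fluctuation amplitudes for one protomer.

    ``sigmas[j]`` is the standard deviation (Å) of the positional noise of
    residue j+1 in each Cartesian component; the analytic Cα B-factor is
    8π²σ². All atoms of a residue move rigidly together.
    """

    sigmas: tuple[float, ...]
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigmas):
            raise ValueError("fluctuation sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if not self.sigmas:
            raise ValueError("need at least one residue per chain")


def _toy_topology(n_residues: int, chains: tuple[str, ...]) -> tuple[Topology, np.ndarray]:
    names, elements, res_names, res_ids, chain_ids, ref = [], [], [], [], [], []
    for c, chain in enumerate(chains):
        for j in range(n_residues):
            base = np.array([j * _CA_SPACING, c * _CHAIN_OFFSET, 0.0])
            for name, elem, offset in _RESIDUE_ATOMS:
                names.append(name)
                elements.append(elem)
                res_names.append("GLY")
                res_ids.append(j + 1)
                chain_ids.append(chain)
                ref.append(base + offset)
    n = len(names)
    top = Topology(
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        res_name=np.array(res_names, dtype=object),
        res_id=np.array(res_ids, dtype=int),
        chain_id=np.array(chain_ids, dtype=object),
        ins_code=np.array([""] * n, dtype=object),
    )
    return top, np.array(ref)


def gen_trajectory(
    spec: FluctuationSpec, chains: tuple[str, ...] = ("A", "B")
) -> tuple[Topology, Trajectory]:
    """Dimeric toy trajectory with prescribed per-residue fluctuations.

    Every chain carries the same residue-wise σ but independent noise; frame
    coordinates are reference + Gaussian noise, with no rigid-body drift
    added, so B-factors can be computed with or without prior fitting.
    """
    if len(chains) < 1:
        raise ValueError("need at least one chain")
    top, ref = _toy_topology(len(spec.sigmas), tuple(chains))
    rng = np.random.default_rng(spec.seed)
    n_res = len(spec.sigmas)
    atoms_per_res = len(_RESIDUE_ATOMS)
    coords = np.empty((spec.n_frames, top.n_atoms, 3))
    for c in range(len(chains)):
        for j, sigma in enumerate(spec.sigmas):
            # one rigid displacement per residue per frame
            noise = rng.normal(0.0, sigma, size=(spec.n_frames, 1, 3))
            start = (c * n_res + j) * atoms_per_res
            sl = slice(start, start + atoms_per_res)
            coords[:, sl, :] = ref[sl][None, :, :] + noise
    return top, Trajectory(coords=coords)


# ---------------------------------------------------------------------------
# hydrogen-bond series


@dataclass(frozen=True)
class HBondSeriesSpec:
    """Target occupancy plus the bonded/broken geometries used to realize it.

    Geometries are (donor–acceptor heavy-atom distance Å, D–H···A angle °).
    The bonded geometry must satisfy the detection criteria and the broken
    one must violate them; this is validated at generation time.
    """

    occupancy: float
    bonded_geometry: tuple[float, float] = (2.8, 180.0)
    broken_geometry: tuple[float, float] = (4.5, 180.0)
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


_NH_LENGTH = 1.0  # Å, donor-H covalent distance in the toy geometry


def _acceptor_position(distance: float, angle_deg: float) -> np.ndarray:
    """Place the acceptor at the given D–A distance and D–H···A angle.

    Donor N sits at the origin, H at (1, 0, 0); the acceptor lies in the
    xy-plane on the far side of H.
    """
    theta = math.radians(angle_deg)
    disc = math.cos(theta) ** 2 - 1.0 + (distance / _NH_LENGTH) ** 2
    if disc < 0:
        raise ValueError(
            f"geometry (d={distance}, angle={angle_deg}) is unrealizable"
        )
    s = math.cos(theta) + math.sqrt(disc)
    direction = np.array([-math.cos(theta), math.sin(theta), 0.0])
    return np.array([_NH_LENGTH, 0.0, 0.0]) + s * _NH_LENGTH * direction


def gen_hbond_series(spec: HBondSeriesSpec) -> tuple[Topology, Trajectory]:
    """One protein donor and one ligand acceptor toggling in and out of a bond.

    Exactly round(occupancy · frames) frames use the bonded geometry; the
    bonded frame indices are a seed-determined permutation, so the measured
    occupancy is reproduced exactly, not just in expectation.
    """
    from .interactions import HBondCriteria, _geometry_is_bond  # deferred: avoids cycle

    criteria = HBondCriteria()
    if not _geometry_is_bond(*spec.bonded_geometry, criteria):
        raise ValueError(
            f"bonded geometry {spec.bonded_geometry} fails the H-bond criteria"
        )
    if _geometry_is_bond(*spec.broken_geometry, criteria):
        raise ValueError(
            f"broken geometry {spec.broken_geometry} satisfies the H-bond criteria"
        )

    # chain A: donor residue (N, H, CA, C); chain L: acceptor residue (CA, O)
    atom_name = np.array(["N", "H", "CA", "C", "CA", "O"], dtype=object)
    element = np.array(["N", "H", "C", "C", "C", "O"], dtype=object)
    res_name = np.array(["GLY"] * 4 + ["GLY"] * 2, dtype=object)
    res_id = np.array([1, 1, 1, 1, 1, 1], dtype=int)
    chain_id = np.array(["A", "A", "A", "A", "L", "L"], dtype=object)
    top = Topology(
        atom_name=atom_name,
        element=element,
        res_name=res_name,
        res_id=res_id,
        chain_id=chain_id,
        ins_code=np.array([""] * 6, dtype=object),
    )
    static = np.array(
        [
            [0.0, 0.0, 0.0],        # N  (donor heavy)
            [_NH_LENGTH, 0.0, 0.0], # H
            [-0.8, -1.2, 0.0],      # CA
            [-2.1, -0.9, 0.3],      # C
            [5.5, 2.5, 0.0],        # ligand CA (repositioned per frame below)
        ]
    )
    bonded_pos = _acceptor_position(*spec.bonded_geometry)
    broken_pos = _acceptor_position(*spec.broken_geometry)

    n_bonded = int(round(spec.occupancy * spec.n_frames))
    rng = np.random.default_rng(spec.seed)
    bonded_frames = set(rng.permutation(spec.n_frames)[:n_bonded].tolist())

    coords = np.empty((spec.n_frames, 6, 3))
    for f in range(spec.n_frames):
        acceptor = bonded_pos if f in bonded_frames else broken_pos
        coords[f, :5] = static
        coords[f, 4] = acceptor + np.array([1.4, 0.3, 0.0])  # ligand CA follows its O
        coords[f, 5] = acceptor
    return top, Trajectory(coords=coords)


# ---------------------------------------------------------------------------
# distance series


def gen_distance_series(
    mean: float, cv_percent: float, n: int, seed: int
) -> np.ndarray:
    """Gaussian distance series with prescribed mean and coefficient of variation."""
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if cv_percent < 0:
        raise ValueError(f"cv_percent must be >= 0, got {cv_percent}")
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    return rng.normal(mean, mean * cv_percent / 100.0, size=n)
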