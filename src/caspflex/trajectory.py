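"""Structures and trajectories: PDB I/O, Kabsch superposition, trajectory fitting.

The mandatory trajectory format is multi-model PDB (MODEL/ENDMDL blocks, one
frame each); a single-model file is a one-frame trajectory. Coordinates are in
Å, residue numbers 1-based per PDB convention. Before fluctuation analysis,
frames must be least-squares fitted (usually on Cα atoms) so that rigid-body
motion does not inflate B-factors; :func:`fit_trajectory` implements an
iterated fit onto the running time-average structure.

Superposition uses the Kabsch algorithm (proper rotation, det = +1) with
optional iterative outlier rejection (default 5 cycles, 2.0 Å cutoff — the
defaults common to structure viewers' ``align`` commands).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Topology",
    "Trajectory",
    "SuperpositionResult",
    "SuperpositionError",
    "PDBFormatError",
    "read_structure",
    "write_bfactor_pdb",
    "kabsch_superpose",
    "apply_superposition",
    "fit_trajectory",
    "chain_sequences",
    "align_ca_pairs",
    "superpose_structures",
]


class PDBFormatError(ValueError):
    """Malformed PDB input (e.g. inconsistent atom counts across models)."""


class SuperpositionError(ValueError):
    """Superposition has no unique solution (too few or degenerate pairs)."""


@dataclass
class Topology:
    """Ordered atom metadata; arrays are aligned with trajectory atom order."""

    atom_name: np.ndarray   # str
    element: np.ndarray     # str, upper-case
    res_name: np.ndarray    # str, 3-letter
    res_id: np.ndarray      # int, 1-based
    chain_id: np.ndarray    # str
    ins_code: np.ndarray    # str, "" when absent
    hetero: np.ndarray | None = None  # bool, HETATM flag
    b_factor: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        if self.hetero is None:
            self.hetero = np.zeros(n, dtype=bool)
        keys = list(zip(self.chain_id, self.res_id, self.ins_code, self.atom_name))
        if len(set(keys)) != n:
            raise ValueError("(chain, residue, insertion code, atom name) must be unique")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def ca_indices(self, protein_only: bool = True) -> np.ndarray:
        """Indices of Cα atoms (carbon only, excluding e.g. calcium HETATMs)."""
        mask = (self.atom_name == "CA") & (self.element == "C")
        if protein_only:
            mask &= ~self.hetero
        return np.where(mask)[0]

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique (chain, res_id, ins_code) keys in order of first appearance."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, i in zip(self.chain_id, self.res_id, self.ins_code):
            seen.setdefault((str(c), int(r), str(i)), None)
        return list(seen)


@dataclass
class Trajectory:
    """Per-frame Cartesian coordinates (Å), frame axis first."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_spacing_ps: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mobile → reference and its residuals."""

    rotation: np.ndarray        # (3, 3), proper (det = +1)
    translation: np.ndarray     # (3,); x_fit = R @ x + t
    rmsd: float                 # over all matched pairs, after the final fit
    rmsd_refined: float         # over the pairs surviving outlier rejection
    n_pairs: int                # pairs matched initially
    n_pairs_refined: int        # pairs surviving rejection
    cycles: list[dict] = field(default_factory=list)  # per-cycle log


# ---------------------------------------------------------------------------
# PDB reading / writing


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    # two-letter elements in common PDB usage start in column 13 (e.g. FE, ZN)
    stripped = name.lstrip("0123456789")
    if len(name) == 4 and name[0].isdigit():
        return stripped[0].upper()
    if stripped[:2].upper() in {"FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "SE"}:
        return stripped[:2].upper()
    return stripped[0].upper()


def _model_atom_counts(text: str) -> list[int]:
    counts, current, in_model = [], 0, False
    for line in text.splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            in_model, current = True, 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM  ", "HETATM") and in_model:
            current += 1
    return counts


def read_structure(path) -> tuple[Topology, Trajectory]:
    """Read a (multi-model) PDB file into a topology and trajectory.

    MODEL/ENDMDL blocks become frames; a single-model file yields one frame.
    Alternate locations are resolved to the highest-occupancy conformer (ties
    to altloc 'A'); insertion codes are preserved in the residue key. Missing
    element columns are inferred from the atom name with a warning.
    """
    with open(path) as fh:
        text = fh.read()
    pdb = PDBFile.read(io.StringIO(text))
    try:
        atoms = pdb.get_structure(
            model=None, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:
        counts = _model_atom_counts(text)
        if counts and len(set(counts)) > 1:
            bad = next(
                i + 1 for i, c in enumerate(counts) if c != counts[0]
            )
            raise PDBFormatError(
                f"{path}: inconsistent atom count in MODEL {bad} "
                f"({counts[bad - 1]} atoms vs {counts[0]} in MODEL 1)"
            ) from exc
        raise PDBFormatError(f"{path}: {exc}") from exc

    # altloc presence check on the raw text (column 17)
    if any(
        line[16] not in (" ", "")
        for line in text.splitlines()
        if line[:6] in ("ATOM  ", "HETATM") and len(line) > 16
    ):
        warnings.warn(
            f"{path}: alternate locations present; kept highest occupancy",
            stacklevel=2,
        )

    element = np.array([e.upper() for e in atoms.element], dtype=object)
    blank = np.array([e == "" for e in element])
    if blank.any():
        for i in np.where(blank)[0]:
            element[i] = _infer_element(atoms.atom_name[i])
        warnings.warn(
            f"{path}: {int(blank.sum())} atoms without element column; "
            "inferred from atom names",
            stacklevel=2,
        )

    topology = Topology(
        atom_name=np.array(atoms.atom_name, dtype=object),
        element=np.array(element, dtype=object),
        res_name=np.array(atoms.res_name, dtype=object),
        res_id=np.array(atoms.res_id, dtype=int),
        chain_id=np.array(atoms.chain_id, dtype=object),
        ins_code=np.array(atoms.ins_code, dtype=object),
        hetero=np.array(atoms.hetero, dtype=bool),
        b_factor=np.array(atoms.get_annotation("b_factor"), dtype=float),
    )
    coords = np.asarray(atoms.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    return topology, Trajectory(coords=coords)


def _to_atom_array(topology: Topology, coords: np.ndarray) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.asarray(topology.atom_name, dtype="U6")
    arr.element = np.asarray(topology.element, dtype="U2")
    arr.res_name = np.asarray(topology.res_name, dtype="U5")
    arr.res_id = np.asarray(topology.res_id, dtype=int)
    arr.chain_id = np.asarray(topology.chain_id, dtype="U4")
    arr.ins_code = np.asarray(topology.ins_code, dtype="U1")
    arr.hetero = np.asarray(topology.hetero, dtype=bool)
    arr.set_annotation("b_factor", np.zeros(n))
    arr.set_annotation("occupancy", np.ones(n))
    return arr


def write_structure(topology: Topology, traj: Trajectory, path) -> None:
    """Write a topology + trajectory as a (multi-model) PDB file."""
    if traj.n_frames == 1:
        model = _to_atom_array(topology, traj.coords[0])
        if topology.b_factor is not None:
            model.set_annotation("b_factor", np.round(topology.b_factor, 2))
        pdb = PDBFile()
        pdb.set_structure(model)
    else:
        template = _to_atom_array(topology, traj.coords[0])
        stack = struc.AtomArrayStack(traj.n_frames, topology.n_atoms)
        for cat in template.get_annotation_categories():
            stack.set_annotation(cat, template.get_annotation(cat))
        stack.coord = np.asarray(traj.coords, dtype=np.float32)
        pdb = PDBFile()
        pdb.set_structure(stack)
    pdb.write(path)


def write_bfactor_pdb(
    topology: Topology,
    frame: np.ndarray,
    values: dict[tuple[str, int], float],
    path,
) -> None:
    """Write one frame with per-residue values in the B-factor column.

    ``values`` is keyed by (chain, residue number); every atom of a residue
    gets the residue's value, residues without one get 0.00. The column is
    fixed-point with two decimals (PDB columns 61–66), so values outside
    [-999.99, 9999.99] are clamped with a warning. Output round-trips through
    :func:`read_structure`.
    """
    arr = _to_atom_array(topology, frame)
    b = np.zeros(topology.n_atoms)
    for i, (c, r) in enumerate(zip(topology.chain_id, topology.res_id)):
        b[i] = values.get((str(c), int(r)), 0.0)
    lo, hi = -99.99, 999.99  # %6.2f field: sign + 2 or 3 integer digits
    if np.any(b < lo) or np.any(b > hi):
        warnings.warn(
            "B-factor values outside the %6.2f PDB field were clamped", stacklevel=2
        )
        b = np.clip(b, lo, hi)
    arr.set_annotation("b_factor", np.round(b, 2))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)


# ---------------------------------------------------------------------------
# Kabsch superposition


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t: x → R @ x + t."""
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, rc - rot @ mc


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    pairs: np.ndarray | None = None,
    refine_cycles: int = 0,
    refine_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Optimal rigid-body superposition of paired coordinates.

    ``pairs`` is an optional (k, 2) index array mapping mobile rows to
    reference rows; by default row i pairs with row i. With ``refine_cycles``
    > 0, pairs deviating more than ``refine_cutoff`` Å after a fit are dropped
    and the fit repeated (at most the given number of cycles), and both the
    all-pair and the refined RMSD are reported.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pairs is None:
        if len(mobile) != len(reference):
            raise SuperpositionError("unequal coordinate counts and no pairing given")
        pairs = np.column_stack([np.arange(len(mobile))] * 2)
    pairs = np.asarray(pairs, dtype=int)
    m_all, r_all = mobile[pairs[:, 0]], reference[pairs[:, 1]]
    if len(m_all) < 3:
        raise SuperpositionError(f"need >= 3 pairs, got {len(m_all)}")
    if np.linalg.matrix_rank(r_all - r_all.mean(axis=0), tol=1e-8) < 2:
        raise SuperpositionError("reference pairs are collinear")

    keep = np.arange(len(m_all))
    cycles: list[dict] = []
    rot, trans = _kabsch(m_all, r_all)
    for cycle in range(max(refine_cycles, 0)):
        rot, trans = _kabsch(m_all[keep], r_all[keep])
        dev = np.linalg.norm((m_all[keep] @ rot.T + trans) - r_all[keep], axis=1)
        drop = dev > refine_cutoff
        cycles.append(
            {"cycle": cycle + 1, "kept": int(keep.size), "dropped": int(drop.sum())}
        )
        if not drop.any():
            break
        if (keep.size - drop.sum()) < 3:
            break
        keep = keep[~drop]

    fitted = m_all @ rot.T + trans
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd=_rmsd(fitted, r_all),
        rmsd_refined=_rmsd(fitted[keep], r_all[keep]),
        n_pairs=len(m_all),
        n_pairs_refined=int(keep.size),
        cycles=cycles,
    )


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply a fitted rigid transform to an arbitrary coordinate array."""
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


# ---------------------------------------------------------------------------
# trajectory fitting


def fit_trajectory(
    traj: Trajectory,
    selection: np.ndarray,
    max_passes: int = 10,
    tol: float = 1e-10,
) -> Trajectory:
    """Remove rigid-body motion by fitting every frame onto the time-average.

    Each frame is superposed (no outlier rejection) on the selection's
    time-average structure; the average is then recomputed from the fitted
    frames and the fit repeated, until self-consistent (at least two passes).
    The operation is idempotent at convergence.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("fit selection is empty")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to fit a trajectory")

    coords = traj.coords.copy()
    for _ in range(max_passes):
        mean = coords[:, selection].mean(axis=0)
        shift = 0.0
        for f in range(coords.shape[0]):
            rot, trans = _kabsch(coords[f, selection], mean)
            new = coords[f] @ rot.T + trans
            shift = max(shift, float(np.abs(new - coords[f]).max()))
            coords[f] = new
        if shift < tol:
            break
    return Trajectory(coords=coords, frame_spacing_ps=traj.frame_spacing_ps)


# ---------------------------------------------------------------------------
# cross-structure Cα matching (sequence alignment based)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def chain_sequences(topology: Topology) -> dict[str, tuple[str, np.ndarray]]:
    """One-letter sequence and Cα atom indices per protein chain."""
    out: dict[str, tuple[str, np.ndarray]] = {}
    ca = topology.ca_indices()
    for chain in dict.fromkeys(topology.chain_id[ca]):
        idx = ca[topology.chain_id[ca] == chain]
        letters = [_THREE_TO_ONE.get(topology.res_name[i], "X") for i in idx]
        out[str(chain)] = ("".join(letters), idx)
    return out


def align_ca_pairs(
    top_a: Topology,
    top_b: Topology,
    chain_map: dict[str, str] | None = None,
) -> np.ndarray:
    """Match Cα atoms of two proteins via pairwise sequence alignment.

    Chains are paired either explicitly (``chain_map``: chain of A → chain of
    B) or greedily by alignment score. Returns a (k, 2) array of (atom index
    in A, atom index in B) for aligned, non-gap positions.
    """
    from biotite.sequence import ProteinSequence
    from biotite.sequence.align import SubstitutionMatrix, align_optimal

    seqs_a, seqs_b = chain_sequences(top_a), chain_sequences(top_b)
    matrix = SubstitutionMatrix.std_protein_matrix()

    def _align(sa: str, sb: str):
        return align_optimal(
            ProteinSequence(sa.replace("X", "A")),
            ProteinSequence(sb.replace("X", "A")),
            matrix,
            gap_penalty=(-10, -1),
        )[0]

    if chain_map is None:
        chain_map = {}
        used: set[str] = set()
        for ca_chain, (sa, _) in seqs_a.items():
            best, best_score = None, -np.inf
            for cb_chain, (sb, _) in seqs_b.items():
                if cb_chain in used:
                    continue
                score = _align(sa, sb).score
                if score > best_score:
                    best, best_score = cb_chain, score
            if best is not None:
                chain_map[ca_chain] = best
                used.add(best)

    pairs: list[tuple[int, int]] = []
    for ca_chain, cb_chain in chain_map.items():
        sa, idx_a = seqs_a[ca_chain]
        sb, idx_b = seqs_b[cb_chain]
        ali = _align(sa, sb)
        for i, j in ali.trace:
            if i != -1 and j != -1:
                pairs.append((int(idx_a[i]), int(idx_b[j])))
    if not pairs:
        raise SuperpositionError("sequence alignment produced no Cα pairs")
    return np.array(pairs, dtype=int)


def superpose_structures(
    top_mobile: Topology,
    frame_mobile: np.ndarray,
    top_ref: Topology,
    frame_ref: np.ndarray,
    chain_map: dict[str, str] | None = None,
    refine_cycles: int = 5,
    refine_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Sequence-align two proteins' chains and superpose them on matched Cα."""
    pairs = align_ca_pairs(top_mobile, top_ref, chain_map)
    return kabsch_superpose(
        frame_mobile,
        frame_ref,
        pairs=pairs,
        refine_cycles=refine_cycles,
        refine_cutoff=refine_cutoff,
    )
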