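"""Substrate cleavage-site tables, scissile-bond alignment and cleavage entropy.

Protease specificity is quantified per subpocket by the *cleavage entropy*:
the Shannon entropy of the amino-acid frequencies observed at one substrate
position (P4…P1, P1'…P4' in Schechter–Berger nomenclature) across all known
cleavage events, normalized to log base 20 so that a point mass scores 0
(fully specific) and the uniform distribution over the 20 canonical residues
scores 1 (fully promiscuous):

    S_i = - sum_a p_a(i) * log20 p_a(i),   with 0 * log 0 := 0.

Substrates are aligned at the scissile bond (the peptide bond between P1 and
P1'); positions falling outside a substrate's sequence are gaps and never
enter the frequency denominators, and neither do non-canonical residue codes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical amino acids, one-letter codes, fixed order.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Default window around the scissile bond, N- to C-terminal.
WINDOW_POSITIONS: tuple[str, ...] = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")

GAP = "-"


class SubstrateFormatError(ValueError):
    """Raised when a substrate table misses required columns."""


@dataclass(frozen=True)
class SubstrateRecord:
    """One cleavage event: a substrate and the 1-based position of its P1 residue."""

    identifier: str
    sequence: str
    p1_position: int
    flagged: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.identifier}: empty sequence")
        if not (1 <= self.p1_position < len(self.sequence)):
            raise ValueError(
                f"{self.identifier}: scissile index {self.p1_position} out of range "
                f"for sequence of length {len(self.sequence)} (need 1 <= i < length)"
            )

    def window(self, positions: tuple[str, ...] = WINDOW_POSITIONS) -> dict[str, str]:
        """Residues at the requested subsites; gaps where the sequence ends."""
        out = {}
        for pos in positions:
            offset = _position_offset(pos)
            idx = self.p1_position - 1 + offset
            out[pos] = self.sequence[idx] if 0 <= idx < len(self.sequence) else GAP
        return out


def _position_offset(pos: str) -> int:
    """Offset of a subsite label relative to P1 (0); P1' is +1, P4 is -3."""
    if pos not in WINDOW_POSITIONS:
        raise ValueError(f"unknown position label {pos!r}")
    k = int(pos.rstrip("'")[1])
    return k if pos.endswith("'") else -(k - 1)


@dataclass
class SubstrateSet:
    """A collection of cleavage events for one protease."""

    records: list[SubstrateRecord]
    protease: str = ""
    skipped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PositionalMatrix:
    """Residues observed at each window position across all records.

    Columns may contain the gap character for records whose sequence does not
    extend to that position; gaps are never counted as residues downstream.
    """

    columns: dict[str, list[str]]
    n_records: int

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(self.columns)


@dataclass
class SpecificityProfile:
    """Per-position cleavage entropy on [0, 1] with the observation counts."""

    entropies: dict[str, float]
    counts: dict[str, int]
    protease: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": list(self.entropies),
                "cleavage_entropy": [self.entropies[p] for p in self.entropies],
                "n": [self.counts[p] for p in self.entropies],
            }
        )


# ---------------------------------------------------------------------------
# parsing

_FULL_COLUMNS = ("id", "sequence", "p1_position")
_WINDOW_COLUMNS = ("id", "p4", "p3", "p2", "p1", "p1p", "p2p", "p3p", "p4p")


def parse_substrate_table(path, dialect: str = "auto", sep: str = "\t") -> SubstrateSet:
    """Read a substrate table (TSV by default) into a validated SubstrateSet.

    Two dialects are supported: ``full`` (columns id, sequence, p1_position —
    the 1-based index of the P1 residue) and ``window`` (columns id, p4…p4p
    holding a pre-aligned eight-residue window, gap ``-`` allowed). Rows whose
    scissile index is out of range are skipped and reported in ``skipped``;
    rows with non-canonical residues inside the window are kept but flagged.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if dialect == "auto":
        if set(_FULL_COLUMNS) <= set(df.columns):
            dialect = "full"
        elif set(_WINDOW_COLUMNS) <= set(df.columns):
            dialect = "window"
        else:
            raise SubstrateFormatError(
                "substrate table needs columns "
                f"{_FULL_COLUMNS} or {_WINDOW_COLUMNS}; found {tuple(df.columns)}"
            )
    required = _FULL_COLUMNS if dialect == "full" else _WINDOW_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SubstrateFormatError(
            f"missing columns {missing}; found {tuple(df.columns)}"
        )

    records: list[SubstrateRecord] = []
    skipped: list[str] = []
    for i, row in df.iterrows():
        ident = str(row["id"])
        try:
            if dialect == "full":
                seq = str(row["sequence"]).strip().upper()
                rec = SubstrateRecord(ident, seq, int(row["p1_position"]))
            else:
                window = "".join(
                    (str(row[c]).strip().upper() or GAP) for c in _WINDOW_COLUMNS[1:]
                )
                rec = SubstrateRecord(ident, window, 4)
        except (ValueError, TypeError) as exc:
            skipped.append(f"row {i} ({ident}): {exc}")
            continue
        flagged = any(
            r not in AA_INDEX and r != GAP for r in rec.window().values()
        )
        if flagged:
            rec = SubstrateRecord(rec.identifier, rec.sequence, rec.p1_position, flagged=True)
        records.append(rec)

    if not records and not skipped:
        warnings.warn(f"{path}: empty substrate table", stacklevel=2)
    return SubstrateSet(records=records, skipped=skipped)


def write_substrate_table(substrates: SubstrateSet, path, sep: str = "\t") -> None:
    """Write a SubstrateSet in the ``full`` dialect (id, sequence, p1_position)."""
    pd.DataFrame(
        {
            "id": [r.identifier for r in substrates.records],
            "sequence": [r.sequence for r in substrates.records],
            "p1_position": [r.p1_position for r in substrates.records],
        }
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# alignment and entropy

def align_at_scissile(
    substrates: SubstrateSet, window: tuple[str, ...] = WINDOW_POSITIONS
) -> PositionalMatrix:
    """Stack the records' residues at each subsite, gap-padding short substrates.

    Column P1 holds the residue immediately N-terminal of the cut, P1' the one
    immediately C-terminal.
    """
    for pos in window:
        _position_offset(pos)  # validates labels
    columns: dict[str, list[str]] = {pos: [] for pos in window}
    for rec in substrates.records:
        w = rec.window(tuple(window))
        for pos in window:
            columns[pos].append(w[pos])
    return PositionalMatrix(columns=columns, n_records=len(substrates.records))


class UndefinedFrequencies(ValueError):
    """No canonical residues observed at a position: frequencies are undefined."""


def positional_frequencies(matrix: PositionalMatrix, position: str) -> np.ndarray:
    """Frequency vector over the 20 canonical residues at one window position.

    Gaps and non-canonical codes are excluded from the denominator. Raises
    :class:`UndefinedFrequencies` when nothing canonical was observed — this is
    deliberately distinct from returning a zero vector.
    """
    if position not in matrix.columns:
        raise KeyError(f"position {position!r} not in matrix {matrix.positions}")
    counts = np.zeros(len(AMINO_ACIDS))
    for residue in matrix.columns[position]:
        idx = AA_INDEX.get(residue)
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise UndefinedFrequencies(f"no canonical residues observed at {position}")
    return counts / total


def cleavage_entropy(freqs: np.ndarray) -> float:
    """Normalized Shannon entropy of a frequency vector, log base 20.

    0 for a point mass, 1 for the uniform distribution over the 20-letter
    alphabet; zero frequencies contribute 0 by the 0·log 0 convention.
    """
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or np.any(p < -1e-12) or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("frequencies must be a 1-D probability vector")
    nz = p[p > 0]
    s = float(-(nz * np.log(nz)).sum() / math.log(20.0))
    return 0.0 if s == 0 else s  # avoid -0.0 for point masses


def observation_counts(matrix: PositionalMatrix, position: str) -> int:
    """Number of canonical (non-gap) observations at a position."""
    return sum(1 for r in matrix.columns[position] if r in AA_INDEX)


MIN_SUBSTRATES = 50  # inclusion threshold used for the caspase profiles


def specificity_profile(
    substrates: SubstrateSet,
    window: tuple[str, ...] = WINDOW_POSITIONS,
    min_substrates: int = MIN_SUBSTRATES,
) -> SpecificityProfile:
    """Per-subsite cleavage entropies for one protease's substrate set.

    Sets with fewer than ``min_substrates`` records are profiled anyway but
    trigger a warning, mirroring the >50-substrates inclusion rule used for
    the caspase analysis. Positions with no canonical observation are omitted
    (entropy undefined there).
    """
    if len(substrates) < 1:
        raise ValueError("need at least one substrate record")
    if len(substrates) < min_substrates:
        warnings.warn(
            f"{substrates.protease or 'substrate set'}: only {len(substrates)} records "
            f"(< {min_substrates}); entropies may be noisy",
            stacklevel=2,
        )
    matrix = align_at_scissile(substrates, window)
    entropies: dict[str, float] = {}
    counts: dict[str, int] = {}
    for pos in window:
        n = observation_counts(matrix, pos)
        if n == 0:
            continue
        entropies[pos] = cleavage_entropy(positional_frequencies(matrix, pos))
        counts[pos] = n
    return SpecificityProfile(entropies=entropies, counts=counts, protease=substrates.protease)
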