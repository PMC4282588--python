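"""Specificity–flexibility correlation and report assembly.

The headline analysis pairs each subpocket's cleavage entropy (specificity of
substrate readout at position P_i) with its normalized flexibility (S_i), the
standard Schechter–Berger correspondence S_i ↔ P_i, and computes the Spearman
rank correlation over the pockets. Because only four pockets (S1–S4) enter,
coefficients are descriptive, not inferential: no p-value is attached and
n ≤ 4 results carry an explicit flag. A variant excluding the apolar S2
pocket — which binds hydrophobic residues without hydrogen bonds and is known
to oppose the rigidity–specificity trend — is computed alongside on request.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .flexibility import SubpocketFlexibility
from .interactions import DistanceStats, HBondReport
from .substrates import SpecificityProfile

__all__ = [
    "CorrelationResult",
    "CorrelationSet",
    "spearman",
    "correlate_profiles",
    "landscape_values",
    "build_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1"


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks).

    Returns NaN with a warning when either vector has zero rank variance
    (the coefficient is undefined, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D vectors with >= 2 entries")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("zero rank variance: Spearman rho undefined", stacklevel=2)
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class CorrelationResult:
    """Spearman ρ over matched (entropy, flexibility) subpocket pairs."""

    rho: float
    n: int
    subpockets: list[str]
    pairs: list[tuple[float, float]]  # (entropy, flexibility) per subpocket
    descriptive_only: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class CorrelationSet:
    """All-pocket result plus the optional exclusion variant."""

    all: CorrelationResult
    excluded: CorrelationResult | None = None
    excluded_subpockets: list[str] = field(default_factory=list)


def _position_for(subpocket: str) -> str:
    # Schechter–Berger correspondence: S_i binds P_i
    return "P" + subpocket[1:]


def correlate_profiles(
    specificity: SpecificityProfile,
    flexibility: SubpocketFlexibility,
    exclude: list[str] | None = None,
) -> CorrelationSet:
    """Correlate per-subpocket cleavage entropy with normalized flexibility.

    Pairs are matched S_i ↔ P_i. With ``exclude`` given (e.g. ``["S2"]``),
    the exclusion variant is computed alongside the all-pocket result.
    """

    def _result(pockets: list[str]) -> CorrelationResult:
        if len(pockets) < 3:
            raise ValueError(
                f"only {len(pockets)} shared subpockets {pockets}; need >= 3"
            )
        ent = [specificity.entropies[_position_for(s)] for s in pockets]
        flex = [flexibility.values[s] for s in pockets]
        flags = []
        if len(pockets) <= 4:
            flags.append("descriptive only (n <= 4)")
        if len(pockets) == 3:
            flags.append("weakly informative (n = 3)")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            rho = spearman(ent, flex)
        if caught:
            flags.extend(str(w.message) for w in caught)
        return CorrelationResult(
            rho=rho,
            n=len(pockets),
            subpockets=pockets,
            pairs=list(zip(ent, flex)),
            flags=flags,
        )

    shared = [
        s
        for s in sorted(flexibility.values)
        if _position_for(s) in specificity.entropies
    ]
    if not shared:
        raise ValueError(
            f"no shared subpockets between profiles "
            f"(flexibility has {sorted(flexibility.values)}, "
            f"specificity has {sorted(specificity.entropies)})"
        )
    out = CorrelationSet(all=_result(shared))
    if exclude:
        kept = [s for s in shared if s not in set(exclude)]
        out.excluded = _result(kept)
        out.excluded_subpockets = list(exclude)
    return out


# ---------------------------------------------------------------------------
# landscapes and reports


def landscape_values(
    resolved_subpockets: dict[str, dict[str, list[tuple[str, int]]]],
    values: dict[str, float],
) -> dict[tuple[str, int], float]:
    """Spread per-subpocket values onto (chain, residue) keys for PDB mapping.

    ``resolved_subpockets`` is the output of SubpocketDefinition.resolve();
    the returned mapping feeds write_bfactor_pdb so entropy or flexibility
    landscapes can be inspected on the structure.
    """
    out: dict[tuple[str, int], float] = {}
    for pockets in resolved_subpockets.values():
        for pocket, keys in pockets.items():
            if pocket not in values:
                continue
            for key in keys:
                out[key] = values[pocket]
    return out


def _corr_to_dict(res: CorrelationResult) -> dict:
    return {
        "rho": None if np.isnan(res.rho) else res.rho,
        "n": res.n,
        "subpockets": res.subpockets,
        "pairs": res.pairs,
        "descriptive_only": res.descriptive_only,
        "flags": res.flags,
    }


def build_report(
    specificity: dict[str, SpecificityProfile] | None = None,
    flexibility: dict[str, SubpocketFlexibility] | None = None,
    hbonds: dict[str, HBondReport] | None = None,
    distances: dict[str, DistanceStats] | None = None,
    correlations: dict[str, CorrelationSet] | None = None,
) -> dict:
    """Assemble a machine-readable report of all computed profiles.

    Sections are keyed by system label and omitted when the corresponding
    analysis was not run. Correlation entries must reference flexibility
    labels present in the report.
    """
    if not any([specificity, flexibility, hbonds, distances, correlations]):
        raise ValueError("nothing to report")
    if correlations and flexibility is not None:
        unknown = [k for k in correlations if k not in flexibility]
        if unknown:
            raise ValueError(
                f"correlation labels {unknown} not among flexibility systems "
                f"{sorted(flexibility)}"
            )
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION}
    if specificity:
        report["specificity"] = {
            label: {
                "protease": p.protease,
                "cleavage_entropy": p.entropies,
                "n": p.counts,
            }
            for label, p in specificity.items()
        }
    if flexibility:
        report["flexibility"] = {
            label: {
                "normalized_b": f.values,
                "per_protomer": f.per_protomer,
                "normalization_b_A2": f.normalization_b,
            }
            for label, f in flexibility.items()
        }
    if hbonds:
        report["hbonds"] = {
            label: {
                "groups": {f"{s}-{p}": v for (s, p), v in r.groups.items()},
                "total": r.total,
                "n_frames": r.n_frames,
            }
            for label, r in hbonds.items()
        }
    if distances:
        report["distances"] = {
            label: {
                "pair": d.pair,
                "mean_A": d.mean,
                "sd_percent": d.sd_percent,
                "n": d.n,
            }
            for label, d in distances.items()
        }
    if correlations:
        report["correlations"] = {
            label: {
                "all": _corr_to_dict(c.all),
                **(
                    {
                        "excluding_" + "_".join(c.excluded_subpockets): _corr_to_dict(
                            c.excluded
                        )
                    }
                    if c.excluded is not None
                    else {}
                ),
            }
            for label, c in correlations.items()
        }
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
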