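"""Per-residue Cα B-factors and subpocket-wise normalized flexibility.

For a fitted trajectory, the mean-square fluctuation of a residue's Cα about
its time-average position is converted to a crystallographic-style B-factor,

    B = (8π²/3) · ⟨Δr²⟩   (Å²),

so that an isotropic Gaussian fluctuation of per-component σ gives
B = 8π²σ² analytically. Binding-site residues are grouped into subpockets
(S1…S4, Schechter–Berger), each protomer's subpocket mean is normalized by
the protein-wide average Cα B-factor (one pooled constant per system), and
the two protomer values are averaged: a value of 1 means average flexibility
within the protein. Native-vs-mutant comparisons are reported as signed
percent change, rounded to the nearest integer for display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .trajectory import Topology, Trajectory

__all__ = [
    "FlexibilityProfile",
    "SubpocketDefinition",
    "SubpocketFlexibility",
    "PercentChange",
    "residue_bfactors",
    "subpocket_flexibility",
    "percent_change",
    "load_subpocket_definition",
]

B_FACTOR_PREFACTOR = 8.0 * math.pi**2 / 3.0


@dataclass
class FlexibilityProfile:
    """Cα mean-square fluctuations and B-factors keyed by (chain, residue)."""

    msf: dict[tuple[str, int], float]
    bfactor: dict[tuple[str, int], float]
    protein_average_b: float
    excluded: list[tuple[str, int]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        keys = sorted(self.bfactor)
        return pd.DataFrame(
            {
                "chain": [k[0] for k in keys],
                "res_id": [k[1] for k in keys],
                "msf_A2": [self.msf[k] for k in keys],
                "bfactor_A2": [self.bfactor[k] for k in keys],
            }
        )


def residue_bfactors(
    traj: Trajectory,
    topology: Topology,
    ligand_chains: set[str] = frozenset(),
) -> FlexibilityProfile:
    """Cα fluctuation B-factors from an already-fitted trajectory.

    Residues without a Cα (ligands, caps, ions) are excluded and reported in
    ``excluded``. The protein-wide average is taken over the Cα of all
    protein chains — HETATM records and ``ligand_chains`` never enter it.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for fluctuations")
    ca = topology.ca_indices()
    ca = ca[[topology.chain_id[i] not in ligand_chains for i in ca]]

    msf: dict[tuple[str, int], float] = {}
    bfac: dict[tuple[str, int], float] = {}
    for i in ca:
        key = (str(topology.chain_id[i]), int(topology.res_id[i]))
        xyz = traj.coords[:, i, :]
        dev = xyz - xyz.mean(axis=0)
        m = float(np.mean(np.sum(dev**2, axis=1)))
        msf[key] = m
        bfac[key] = B_FACTOR_PREFACTOR * m

    ca_residues = set(msf)
    excluded = [
        (c, r)
        for (c, r, _ins) in topology.residue_keys()
        if (c, r) not in ca_residues
    ]
    if excluded:
        warnings.warn(
            f"{len(excluded)} residues without Cα excluded from the profile",
            stacklevel=2,
        )
    if not bfac:
        raise ValueError("no Cα atoms found in the topology")
    return FlexibilityProfile(
        msf=msf,
        bfactor=bfac,
        protein_average_b=float(np.mean(list(bfac.values()))),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# subpocket grouping


@dataclass
class SubpocketDefinition:
    """Binding-site residues per subpocket plus the dimer chain layout.

    ``subpockets`` lists (residue number, residue name or None) per subpocket
    in protomer-local numbering; ``protomers`` maps a protomer label to its
    chains and an optional residue-number offset (the equivalence map between
    protomers). A residue may belong to only one subpocket.
    """

    subpockets: dict[str, list[tuple[int, str | None]]]
    protomers: dict[str, dict]  # label -> {"chains": [...], "offset": int}

    def __post_init__(self) -> None:
        seen: dict[int, str] = {}
        for name, residues in self.subpockets.items():
            for res_id, _ in residues:
                if res_id in seen:
                    raise ValueError(
                        f"residue {res_id} in both {seen[res_id]} and {name}"
                    )
                seen[res_id] = name
        for label, spec in self.protomers.items():
            if not spec.get("chains"):
                raise ValueError(f"protomer {label} has no chains")
            spec.setdefault("offset", 0)

    def resolve(
        self, topology: Topology
    ) -> dict[str, dict[str, list[tuple[str, int]]]]:
        """Map each (protomer, subpocket) to concrete (chain, residue) keys."""
        available: dict[tuple[str, int], str] = {}
        for i in topology.ca_indices():
            available[(str(topology.chain_id[i]), int(topology.res_id[i]))] = str(
                topology.res_name[i]
            )
        out: dict[str, dict[str, list[tuple[str, int]]]] = {}
        for label, spec in self.protomers.items():
            offset = spec["offset"]
            out[label] = {}
            for pocket, residues in self.subpockets.items():
                keys = []
                for res_id, res_name in residues:
                    hit = None
                    for chain in spec["chains"]:
                        key = (str(chain), res_id + offset)
                        if key in available:
                            if res_name and available[key] != res_name:
                                raise ValueError(
                                    f"{pocket}: residue {key} is "
                                    f"{available[key]}, expected {res_name}"
                                )
                            hit = key
                            break
                    if hit is None:
                        raise ValueError(
                            f"{pocket}: residue {res_id + offset} not found in "
                            f"chains {spec['chains']} of protomer {label}"
                        )
                    keys.append(hit)
                out[label][pocket] = keys
        return out


@dataclass
class SubpocketFlexibility:
    """Dimer-averaged normalized subpocket B-factors."""

    values: dict[str, float]                      # subpocket -> averaged value
    per_protomer: dict[str, dict[str, float]]     # protomer -> subpocket -> value
    normalization_b: float                        # protein-average Cα B used
    system: str = ""

    def as_frame(self) -> pd.DataFrame:
        rows = {"subpocket": list(self.values), "normalized_b": list(self.values.values())}
        for label, vals in self.per_protomer.items():
            rows[f"protomer_{label}"] = [vals[p] for p in self.values]
        return pd.DataFrame(rows)


def subpocket_flexibility(
    profile: FlexibilityProfile,
    definition: SubpocketDefinition,
    topology: Topology,
    system: str = "",
) -> SubpocketFlexibility:
    """Average normalized B-factor per subpocket, averaged over protomers.

    Per protomer, the subpocket value is the mean Cα B-factor over its
    residues divided by the protein-wide average (pooled over both protomers,
    one constant per system); the reported value is the arithmetic mean of
    the protomer values.
    """
    resolved = definition.resolve(topology)
    norm = profile.protein_average_b
    if norm <= 0:
        raise ValueError("protein-average B-factor is zero; cannot normalize")
    per_protomer: dict[str, dict[str, float]] = {}
    for label, pockets in resolved.items():
        per_protomer[label] = {}
        for pocket, keys in pockets.items():
            missing = [k for k in keys if k not in profile.bfactor]
            if missing:
                raise ValueError(f"{pocket}: no B-factor for residues {missing}")
            per_protomer[label][pocket] = float(
                np.mean([profile.bfactor[k] for k in keys]) / norm
            )
    pockets = list(definition.subpockets)
    values = {
        p: float(np.mean([per_protomer[label][p] for label in per_protomer]))
        for p in pockets
    }
    return SubpocketFlexibility(
        values=values, per_protomer=per_protomer, normalization_b=norm, system=system
    )


# ---------------------------------------------------------------------------
# native vs mutant


@dataclass
class PercentChange:
    """Signed percent change per subpocket, mutant relative to native."""

    unrounded: dict[str, float]
    rounded: dict[str, int]
    undefined: list[str] = field(default_factory=list)


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def percent_change(
    native: SubpocketFlexibility | dict[str, float],
    mutant: SubpocketFlexibility | dict[str, float],
) -> PercentChange:
    """100·(mutant − native)/native per subpocket.

    The rounded value (nearest integer, halves away from zero) is the
    display form; the unrounded value is retained. Subpockets whose native
    value is 0 are flagged as undefined.
    """
    nat = native.values if isinstance(native, SubpocketFlexibility) else native
    mut = mutant.values if isinstance(mutant, SubpocketFlexibility) else mutant
    if set(nat) != set(mut):
        raise ValueError(
            f"subpocket names differ: {sorted(nat)} vs {sorted(mut)}"
        )
    unrounded: dict[str, float] = {}
    rounded: dict[str, int] = {}
    undefined: list[str] = []
    for pocket in nat:
        if nat[pocket] == 0:
            undefined.append(pocket)
            continue
        delta = 100.0 * (mut[pocket] - nat[pocket]) / nat[pocket]
        unrounded[pocket] = delta
        rounded[pocket] = _round_half_away(delta)
    if undefined:
        warnings.warn(
            f"percent change undefined for {undefined} (native value 0)",
            stacklevel=2,
        )
    return PercentChange(unrounded=unrounded, rounded=rounded, undefined=undefined)


# ---------------------------------------------------------------------------
# config


def load_subpocket_definition(path) -> SubpocketDefinition:
    """Load a subpocket definition from YAML.

    Schema::

        subpockets:
          S1: [{res: 64, name: ARG}, {res: 161}]
          ...
        protomers:
          A: {chains: [A], offset: 0}
          B: {chains: [B], offset: 0}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    subpockets = {
        name: [(int(e["res"]), e.get("name")) for e in entries]
        for name, entries in raw["subpockets"].items()
    }
    protomers = {
        str(label): {
            "chains": [str(c) for c in spec["chains"]],
            "offset": int(spec.get("offset", 0)),
        }
        for label, spec in raw["protomers"].items()
    }
    return SubpocketDefinition(subpockets=subpockets, protomers=protomers)
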