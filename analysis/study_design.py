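"""Study conditions shared by the numbered analysis scripts.

Two model effector proteases are simulated as a matched pair:

* ``flexible`` — promiscuous P3/P4 readout and elevated S3/S4 subpocket
  fluctuations (caspase-3-like behaviour);
* ``rigid`` — narrower P3/P4 readout and a stiffer S3/S4 region
  (caspase-7-like behaviour);

plus an S3-exchange mutant of each (the flexible protease rigidified, the
rigid one mobilized), mirroring a Ser/Pro swap in the S3 pocket.

Substrate readout at each subsite is a uniform distribution over the first k
canonical residues, so the analytic cleavage entropy is log20(k). The S2
subsite is deliberately discordant in both systems: broadly promiscuous
(hydrophobic-style readout without hydrogen bonds) yet nearly as rigid as
S1, the configuration that depresses the all-pocket specificity–flexibility
correlation and motivates the S2-exclusion variant.

Toy dimer protomers carry eight residues: residues 1–4 host subpockets
S1–S4, residues 5–8 are background. Per-residue fluctuation amplitudes are
chosen so that the *normalized* subpocket B-factors of each system come out
near the flexibility levels observed for the corresponding real systems
(protein-wide average of sigma^2 equals one normalization unit).
"""

from __future__ import annotations

import numpy as np

from caspflex import FluctuationSpec, PositionDistributionSpec, SubpocketDefinition

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

BASE_SEED = 20140546
N_SUBSTRATES = 5000
N_FRAMES = 3000
SIGMA_UNIT = 0.3  # Å per sqrt(normalized-B unit)

#: uniform-alphabet sizes per subsite: P1 strictly Asp-specific, P2 broadly
#: promiscuous, P3/P4 distinguishing flexible from rigid readout
SUBSTRATE_ALPHABET_SIZES = {
    "flexible": {"P1": 1, "P2": 16, "P3": 15, "P4": 8},
    "rigid": {"P1": 1, "P2": 16, "P3": 10, "P4": 7},
}

#: target normalized subpocket B-factors per system (holo state)
TARGET_NORMALIZED_B = {
    "flexible": {"S1": 0.578, "S2": 1.055, "S3": 2.658, "S4": 2.068},
    "flexible_mut": {"S1": 0.750, "S2": 1.037, "S3": 1.947, "S4": 1.348},
    "rigid": {"S1": 0.447, "S2": 0.970, "S3": 1.285, "S4": 1.221},
    "rigid_mut": {"S1": 0.578, "S2": 0.827, "S3": 1.577, "S4": 1.182},
}

SUBPOCKETS = SubpocketDefinition(
    subpockets={f"S{i}": [(i, None)] for i in range(1, 5)},
    protomers={"1": {"chains": ["A"]}, "2": {"chains": ["B"]}},
)


def substrate_specs(system: str) -> list[PositionDistributionSpec]:
    sizes = SUBSTRATE_ALPHABET_SIZES[system]
    if sizes["P1"] == 1:
        specs = [PositionDistributionSpec.point_mass("P1", "D")]
    else:
        specs = [
            PositionDistributionSpec(
                "P1", {a: 1 / sizes["P1"] for a in ALPHABET[: sizes["P1"]]}
            )
        ]
    for pos in ("P2", "P3", "P4"):
        k = sizes[pos]
        specs.append(PositionDistributionSpec(pos, {a: 1 / k for a in ALPHABET[:k]}))
    return specs


def fluctuation_spec(system: str, seed_offset: int) -> FluctuationSpec:
    """Eight-residue sigma profile realizing the system's target normalized B.

    Background residues 5-8 absorb the remainder so the protein-wide mean of
    sigma^2 is exactly one unit, making the targets the expected normalized
    values.
    """
    targets = TARGET_NORMALIZED_B[system]
    pocket_b = [targets[f"S{i}"] for i in range(1, 5)]
    background_b = (8.0 - sum(pocket_b)) / 4.0
    if background_b <= 0:
        raise ValueError("subpocket targets exceed the normalization budget")
    b_units = pocket_b + [background_b] * 4
    sigmas = tuple(SIGMA_UNIT * float(np.sqrt(b)) for b in b_units)
    return FluctuationSpec(sigmas=sigmas, n_frames=N_FRAMES, seed=BASE_SEED + seed_offset)


SYSTEM_SEED_OFFSETS = {"flexible": 1, "flexible_mut": 2, "rigid": 3, "rigid_mut": 4}

#: published complexed-state S3 distance conditions (mean Å, SD %) used as
#: generator inputs for the distance-recovery analysis
DISTANCE_CONDITIONS = {
    "flexible_com": (5.62, 19.84),
    "rigid_com": (5.31, 11.71),
    "flexible_mut_com": (5.65, 13.25),
    "rigid_mut_com": (5.33, 17.17),
}

#: published per-subpocket hydrogen-bond occupancy sums for the complexed
#: systems (inputs to the total-recomputation analysis)
HBOND_TABLE = {
    "flexible_com": {"S4": 1.37, "S3": 2.46, "S2": 0.00, "S1": 3.04},
    "rigid_com": {"S4": 1.99, "S3": 2.99, "S2": 0.00, "S1": 3.30},
    "flexible_mut_com": {"S4": 1.38, "S3": 3.34, "S2": 0.00, "S1": 3.13},
    "rigid_mut_com": {"S4": 2.03, "S3": 3.03, "S2": 0.00, "S1": 3.17},
}
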