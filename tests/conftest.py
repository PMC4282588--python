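import numpy as np
import pytest

from caspflex import (
    FluctuationSpec,
    PositionDistributionSpec,
    SubpocketDefinition,
    gen_substrates,
    gen_trajectory,
)


@pytest.fixture
def dimer_definition():
    """Four single-residue subpockets (residues 1-4) on a two-chain dimer."""
    return SubpocketDefinition(
        subpockets={f"S{i}": [(i, None)] for i in range(1, 5)},
        protomers={"1": {"chains": ["A"]}, "2": {"chains": ["B"]}},
    )


@pytest.fixture
def uniform_dimer():
    """Dimer trajectory where every residue fluctuates with the same sigma."""
    spec = FluctuationSpec(sigmas=(0.4,) * 6, n_frames=4000, seed=11)
    return gen_trajectory(spec)


@pytest.fixture
def graded_sigmas():
    """Per-residue sigmas increasing with pocket index (S1 most rigid)."""
    return (0.10, 0.20, 0.30, 0.40)


@pytest.fixture
def devd_substrates():
    """Substrate set with the canonical Asp-Glu-Val-Asp P4-P1 readout."""
    specs = [
        PositionDistributionSpec.point_mass("P4", "D"),
        PositionDistributionSpec.point_mass("P3", "E"),
        PositionDistributionSpec.point_mass("P2", "V"),
        PositionDistributionSpec.point_mass("P1", "D"),
    ]
    return gen_substrates(specs, n=60, seed=5, protease="toy_caspase")
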