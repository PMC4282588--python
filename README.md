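# caspflex

Subpocket-resolved **specificity vs. flexibility** profiling for proteases,
built around the analysis that explains why two closely related effector
caspases read their substrates with different stringency.

## The problem

Proteases recognize peptide substrates in a groove of subpockets S4…S1
(binding substrate residues P4…P1, Schechter–Berger nomenclature) on the
N-terminal side of the scissile bond. Effector caspases 3 and 7 cleave the
same canonical DEVD motif, yet degradomics shows caspase 3 to be the more
promiscuous enzyme, particularly at P3/P4. A static structure comparison
does not explain this; the dynamics of the binding-site subpockets do:
flexible subpockets present more receptor conformations and therefore admit
more diverse substrates (conformational selection).

`caspflex` implements both sides of that analysis and the statistic linking
them:

* **Cleavage entropy** (specificity). For substrate position *i* with
  amino-acid frequencies *p_a*:

  `S_i = − Σ_a p_a · log₂₀ p_a`, with 0·log 0 := 0,

  so a strictly conserved position scores 0 and a fully promiscuous one
  scores 1. Substrate tables are aligned at the scissile bond; gaps and
  non-canonical residues never enter the denominators.

* **Subpocket flexibility.** From a (multi-model PDB) trajectory, fitted
  per frame onto the time-average Cα structure, per-residue B-factors
  `B = (8π²/3)⟨Δr²⟩` are averaged over each subpocket's residues, divided
  by the protein-wide average Cα B-factor, and dimer-averaged over the two
  protomers — a value of 1 means average flexibility within the protein.

* **Interactions.** Hydrogen bonds are counted under inclusive geometric
  criteria (donor–acceptor ≤ 3.0 Å, donor–H···acceptor angle ≥ 135°);
  per-pair occupancies are summed into subpocket–position groups (values may
  exceed 1) and totalled. Distances are reported as mean (Å) and SD as % of
  mean, pooled over both protomers.

* **Correlation.** Spearman rank correlation of per-subpocket entropy vs.
  normalized flexibility (S_i ↔ P_i), with an optional variant excluding the
  apolar S2 pocket, whose promiscuity is driven by the *absence* of
  hydrogen-bond readout rather than by flexibility.

A synthetic-data module generates every input shape with known ground truth
(per-position substrate distributions, per-residue isotropic Gaussian
fluctuations with analytic B = 8π²σ², hydrogen-bond series hitting a target
occupancy exactly, Gaussian distance series), so the full pipeline is
testable without MD runs or database downloads.

## Worked example

```python
from caspflex import (
    PositionDistributionSpec, FluctuationSpec, SubpocketDefinition,
    gen_substrates, gen_trajectory, specificity_profile,
    residue_bfactors, subpocket_flexibility, correlate_profiles,
)

aa = "ACDEFGHIKLMNPQRSTVWY"
specs = [
    PositionDistributionSpec.point_mass("P1", "D"),          # Asp-specific S1
    PositionDistributionSpec("P2", {a: 1/16 for a in aa[:16]}),  # promiscuous S2
    PositionDistributionSpec("P3", {a: 1/15 for a in aa[:15]}),
    PositionDistributionSpec("P4", {a: 1/8 for a in aa[:8]}),
]
entropy = specificity_profile(gen_substrates(specs, n=5000, seed=1))

top, traj = gen_trajectory(FluctuationSpec(
    sigmas=(0.23, 0.31, 0.49, 0.43, 0.19, 0.19, 0.19, 0.19),  # S1..S4 + background
    n_frames=3000, seed=2))
pockets = SubpocketDefinition(
    subpockets={f"S{i}": [(i, None)] for i in range(1, 5)},
    protomers={"1": {"chains": ["A"]}, "2": {"chains": ["B"]}})
flex = subpocket_flexibility(residue_bfactors(traj, top), pockets, top)

result = correlate_profiles(entropy, flex, exclude=["S2"])
print(f"rho(all) = {result.all.rho:+.2f}, rho(no S2) = {result.excluded.rho:+.2f}")
```

prints

```
rho(all) = +0.40, rho(no S2) = +1.00
```

All four pockets yield a positive but imperfect rank correlation because S2
is rigid yet promiscuous; dropping S2 exposes the perfect rank agreement
between substrate readout and local dynamics in the remaining pockets.

The numbered scripts under `analysis/` run the full study — synthetic input
generation, entropy profiles, subpocket flexibility with S3-exchange mutant
percent changes, hydrogen-bond/distance statistics, and the correlation
report — writing tables under `results/` (regenerable intermediates go to
`scratch/`). A `caspflex` console command exposes the individual steps
(`simulate`, `entropy`, `flexibility`, `hbonds`, `distances`, `superpose`,
`map`, `correlate`).

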