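# Methods

## Cleavage entropy

Substrate tables (TSV; either `id, sequence, p1_position` with a 1-based P1
index, or a pre-aligned eight-column window) are validated row-wise: rows
with an out-of-range scissile index are skipped and reported, rows with
non-canonical residues are kept but flagged. Records are aligned at the
scissile bond into a positional matrix over P4…P4'; positions outside a
substrate's sequence become gaps.

Per position, frequencies are taken over the 20 canonical residues only —
gaps and non-canonical codes are excluded from the denominator, so they
neither dilute nor inflate the entropy. The entropy is Shannon entropy in
log base 20, which makes the [0, 1] range exact: 0 for a point mass, 1 for
the uniform distribution. No pseudo-counts and no small-sample correction
are applied; the per-position observation count is always reported alongside
so users can judge the sampling. Duplicate windows count as independent
cleavage events (database rows are events, not substrates); profiles built
from fewer than 50 records trigger a warning rather than an error, matching
the inclusion threshold used for the caspase substrate sets.

## Trajectories and superposition

The mandatory trajectory format is multi-model PDB; binary formats are out
of scope so the core stays dependency-light. Reading resolves alternate
locations to the highest-occupancy conformer, preserves insertion codes,
and infers missing element columns from atom names (with a warning).
Writing round-trips atom order, residue keys and coordinates at PDB
precision (1e-3 Å). Per-residue values can be written into the B-factor
column (%6.2f, clamped to the representable [-99.99, 999.99] with a
warning) to paint entropy or flexibility landscapes onto a structure.

Superposition is the Kabsch algorithm (SVD with determinant correction, so
the rotation is always proper). Optional refinement mirrors common viewer
`align` defaults: up to 5 cycles dropping matched pairs deviating by more
than 2.0 Å, re-fitting each cycle; both the all-pair and refined RMSD are
reported, plus a per-cycle log. Cross-protein comparison extracts per-chain
sequences, pairs chains greedily by pairwise alignment score (BLOSUM62,
affine gaps −10/−1), and pairs Cα atoms at aligned non-gap positions.

Before fluctuation analysis, frames are least-squares fitted on a selection
(normally all Cα) onto the selection's time-average structure. Without this,
rigid-body diffusion dominates B-factors. The average is recomputed from the
fitted frames and the fit repeated until self-consistent (at least two
passes, tolerance 1e-10 Å, capped at 10 passes); at the fixed point the
operation is idempotent, which makes results independent of how often the
fit is applied.

## Flexibility profiles

Per residue, the mean-square fluctuation of the Cα about its time-average
position is converted with the crystallographic relation B = (8π²/3)⟨Δr²⟩
(so an isotropic Gaussian of per-component σ gives B = 8π²σ² exactly).
Residues without a Cα (ligands, caps, ions) are excluded and reported.

Subpocket values are the mean Cα B over the pocket's residues divided by
the protein-wide average Cα B. The normalization constant is pooled over
both protomers — one constant per system — and the two protomer values are
then arithmetically averaged. Pooling first keeps the protomer values on a
common scale; the alternative (per-protomer normalization) differs only
when the protomers' overall mobility differs, which for a symmetric dimer
is sampling noise. Ligand chains and HETATM records never enter the
protein average. Native-vs-mutant changes are reported as
100·(mutant−native)/native, rounded half-away-from-zero to integer percent
for display with the unrounded value retained; a zero native value flags
the pocket as undefined instead of dividing.

The shipped `data/subpockets_caspase.yaml` grouping is a clearly marked,
editable reconstruction (the canonical interface-residue lists are not part
of any machine-readable source); any quantitative subpocket result depends
on the definition supplied, which is why the definition is a config input
rather than code.

## Hydrogen bonds and distances

Donors are N/O atoms with ≥1 bonded hydrogen (one donor entry per
hydrogen; attachment inferred from the reference frame at ≤1.2 Å), and
acceptors are all N/O atoms; same-residue pairs are never candidates, and
structures without explicit hydrogens are rejected with advice to
protonate. A bond is realized when the donor–acceptor heavy-atom distance
is ≤3.0 Å and the D–H···A angle is ≥135° — the convention that "maximum
angle" limits the deviation from linearity to 45°. Both boundaries are
inclusive, with a 1e-9 numerical guard so that geometries constructed
exactly on a cutoff classify deterministically regardless of floating-point
round-off.

Pair occupancy is frames-with-bond over frames. Group values for a
(subpocket, ligand-position) cell are *sums* of the occupancies of all
pairs crossing it — hence may exceed 1 — computed per protomer (assignment
by the protein residue's chain) and averaged; the total is the sum over
groups, an identity that holds exactly by construction and is exploited to
recompute published totals from published group values.

Distance statistics pool the per-frame distances of the equivalent atom
pair in each protomer and report the mean (Å) and the population standard
deviation as a percent of the mean (the tabulated convention). A
single-observation series reports 0% with a warning.

## Correlation

Spearman's ρ is the Pearson correlation of average ranks (computed via
scipy); zero rank variance yields NaN with an explicit "undefined" flag
rather than zero. Profile correlation matches subpockets to substrate
positions by index (S_i ↔ P_i). With only four (or three, after exclusion)
pockets, coefficients are descriptive: results carry an explicit
"descriptive only" flag and no p-value is attached. The S2-exclusion
variant is computed alongside the all-pocket result on request, because the
apolar S2 pocket's promiscuity is not hydrogen-bond driven and is expected
to oppose the rigidity–specificity trend. Reports are versioned JSON; every
numeric section carries the frame or substrate counts it was computed from.

## Synthetic data: what it emulates and what it does not

The generators produce the *shapes* and *sufficient statistics* of the real
inputs, not their physics:

* substrate windows are i.i.d. draws from per-position distributions, so
  the analytic entropy of each position is known and finite-sample recovery
  can be tested (empirical entropy converges from below; at n = 5000 the
  bias is ≲0.001 for the alphabets used);
* toy trajectories displace each residue rigidly by isotropic Gaussian
  noise (per-residue σ, independent frames), so the Cα B-factor is
  analytically 8π²σ². There is no covalent connectivity, no correlated
  motion, no conformational transitions, and no rigid-body drift unless the
  fit is being tested;
* hydrogen-bond series toggle one donor–acceptor pair between a geometry
  satisfying the criteria and one violating them, with exactly
  round(occupancy·frames) bonded frames (a seed-determined permutation), so
  occupancy recovery is exact rather than statistical;
* distance series are Gaussian with prescribed mean and CV.

Passing tests on these inputs therefore validate the *estimators and
bookkeeping* (alignment, grouping, normalization, averaging, boundary
conventions, determinism) — they do not validate force fields, sampling
convergence, or any physical claim about real proteases. All generators
take explicit seeds and are bit-reproducible; there is no global random
state.

## Study conditions of the analysis scripts

The `analysis/` drivers simulate a matched pair of model proteases
("flexible" vs. "rigid") plus an S3-exchange mutant of each. Substrate
readout uses uniform alphabets per position (P1 strictly Asp; P3/P4
alphabets of 15/8 vs. 10/7 letters, giving entropies near the empirically
observed caspase contrast; P2 broad in both), 5000 events per protease.
Fluctuation amplitudes place the normalized subpocket B-factors of each
system near the corresponding published flexibility levels, with four
background residues absorbing the normalization budget; trajectories are
3000 frames of an eight-residue-per-protomer dimer. These sizes keep every
stage's sampling error well inside the effects being demonstrated while the
whole study runs in seconds.

## Numerical choices and limitations

* Superposition requires ≥3 non-collinear pairs; degeneracy is detected by
  the rank of the centered reference coordinates (tolerance 1e-8).
* The empirical entropy estimator is biased low at small n; counts are
  reported, no correction applied.
* Integer-percent rounding is half-away-from-zero, matching how tabulated
  bracketed deltas are conventionally printed (banker's rounding would
  differ on exact halves).
* The refined superposition RMSD depends on the outlier-rejection settings;
  the defaults (5 cycles, 2.0 Å) follow common viewer practice but other
  tools' `align` implementations may retain slightly different pair sets.
* H-bond candidate enumeration is a dense pair scan per donor — appropriate
  for binding-site-scale selections, not for all-atom scans of large
  solvated systems (no cell lists).
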