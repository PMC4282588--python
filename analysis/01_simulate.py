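"""Generate the synthetic study inputs: substrate tables and dimer trajectories.

Writes substrate cleavage tables (TSV) and multi-model PDB trajectories for
the four systems (flexible/rigid protease, native and S3-exchange mutant)
under scratch/synthetic/. These are regenerable intermediates; downstream
scripts re-create them on demand, so this step only needs to be run when the
intermediate files themselves are wanted for inspection.
"""

from pathlib import Path

from caspflex import gen_substrates, gen_trajectory, write_structure, write_substrate_table

from study_design import (
    BASE_SEED,
    N_SUBSTRATES,
    SYSTEM_SEED_OFFSETS,
    fluctuation_spec,
    substrate_specs,
)

OUT = Path("scratch/synthetic")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for system in ("flexible", "rigid"):
        subs = gen_substrates(
            substrate_specs(system),
            n=N_SUBSTRATES,
            seed=BASE_SEED + 100 + SYSTEM_SEED_OFFSETS[system],
            protease=system,
        )
        path = OUT / f"substrates_{system}.tsv"
        write_substrate_table(subs, path)
        print(f"{system}: {len(subs)} cleavage events -> {path}")

    for system, offset in SYSTEM_SEED_OFFSETS.items():
        top, traj = gen_trajectory(fluctuation_spec(system, offset))
        path = OUT / f"trajectory_{system}.pdb"
        write_structure(top, traj, path)
        print(f"{system}: {traj.n_frames}-frame dimer trajectory -> {path}")


if __name__ == "__main__":
    main()
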