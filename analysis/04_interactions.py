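"""Hydrogen-bond occupancies and S3 distance statistics.

Three demonstrations on ground-truth inputs:

1. occupancy recovery — generated donor–acceptor series at prescribed
   occupancies are reproduced exactly by the geometric criteria
   (3.0 Å / 135°, both inclusive);
2. distance statistics — Gaussian series with the published complexed-state
   S3 distance conditions (mean Å, SD %) are recovered within sampling
   error, reproducing the flexibility contrast: the rigid system's S3
   distance fluctuates least, the flexible one's most, and the mutants swap;
3. published table ingestion — the four per-subpocket occupancy sums per
   system are summed by the reporting machinery into the per-system totals.

Writes results/interactions.tsv and results/hbond_totals.tsv.
"""

from pathlib import Path

import pandas as pd

from caspflex import (
    HBondGrouping,
    HBondReport,
    HBondSeriesSpec,
    assign_donors_acceptors,
    distance_stats_from_series,
    gen_distance_series,
    gen_hbond_series,
    hbond_occupancy,
)

from study_design import BASE_SEED, DISTANCE_CONDITIONS, HBOND_TABLE

RESULTS = Path("results")

GROUPING = HBondGrouping(
    protein_subpockets={("A", 1): "S3"},
    ligand_positions={("L", 1): "P3"},
    protomer_of_chain={"A": "1"},
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []

    print("occupancy recovery (2000 frames each):")
    for i, occupancy in enumerate((0.25, 0.5, 0.75, 1.0)):
        top, traj = gen_hbond_series(
            HBondSeriesSpec(occupancy=occupancy, n_frames=2000, seed=BASE_SEED + 300 + i)
        )
        sets = assign_donors_acceptors(top, traj.coords[0])
        report = hbond_occupancy(traj, sets, GROUPING)
        measured = report.groups[("S3", "P3")]
        print(f"  target {occupancy:.2f} -> measured {measured:.4f}")
        rows.append({"analysis": "hbond_occupancy", "label": f"target_{occupancy}",
                     "value": measured})

    print("\nS3 distance statistics (50000-sample series):")
    for i, (label, (mean, cv)) in enumerate(DISTANCE_CONDITIONS.items()):
        series = gen_distance_series(mean, cv, n=50000, seed=BASE_SEED + 400 + i)
        stats = distance_stats_from_series(series, pair=label)
        print(
            f"  {label}: mean {stats.mean:.2f} A (design {mean}), "
            f"SD {stats.sd_percent:.2f}% (design {cv})"
        )
        rows.append({"analysis": "distance_mean_A", "label": label, "value": stats.mean})
        rows.append({"analysis": "distance_sd_pct", "label": label, "value": stats.sd_percent})

    pd.DataFrame(rows).to_csv(RESULTS / "interactions.tsv", sep="\t", index=False)

    print("\npublished per-subpocket occupancy sums -> totals:")
    total_rows = []
    for system, groups in HBOND_TABLE.items():
        report = HBondReport.from_group_values(
            {(s, "P" + s[1:]): v for s, v in groups.items()}
        )
        print(f"  {system}: total {report.total:.2f} H-bonds")
        total_rows.append({"system": system, **groups, "total": report.total})
    pd.DataFrame(total_rows).to_csv(RESULTS / "hbond_totals.tsv", sep="\t", index=False)
    print("\nwrote results/interactions.tsv, results/hbond_totals.tsv")


if __name__ == "__main__":
    main()
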