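#!/usr/bin/env python
"""Compare overall survival between mutated and non-mutated patients.

Groups patients by whether any of their mutations falls inside a
modification region of an identified driver protein, estimates
Kaplan-Meier curves per group, and runs the log-rank test.
"""

from pathlib import Path

import pandas as pd

from lysdriver.regions import partitions_from_intervals
from lysdriver.survival import assign_groups, compare_groups

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    survival = pd.read_csv(ROOT / "synthetic" / "survival.tsv", sep="\t")
    mutations = pd.read_csv(ROOT / "synthetic" / "mutations.tsv", sep="\t")
    partitions = partitions_from_intervals(
        pd.read_csv(ROOT / "regions" / "partitions.tsv", sep="\t")
    )
    drivers = pd.read_csv(ROOT / "drivers" / "driver_results.tsv", sep="\t")
    driver_ids = set(drivers.loc[drivers["driver"].fillna(False), "protein_id"])
    if driver_ids:
        partitions = {pid: p for pid, p in partitions.items() if pid in driver_ids}
    labelled = assign_groups(survival.drop(columns=["group"], errors="ignore"),
                             mutations, partitions)
    curves, lr = compare_groups(labelled)

    out = ROOT / "survival"
    out.mkdir(parents=True, exist_ok=True)
    for name, curve in curves.items():
        curve.to_csv(out / f"km_{name.replace('-', '_')}.tsv", sep="\t", index=False)

    n_mut = int((labelled["group"] == "mutated").sum())
    print(f"patients: {n_mut} mutated vs {len(labelled) - n_mut} non-mutated")
    print(f"log-rank: chi-square = {lr.statistic:.2f}, p = {lr.p_value:.3g}")


if __name__ == "__main__":
    main()
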