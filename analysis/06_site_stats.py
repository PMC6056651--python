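#!/usr/bin/env python
"""Deleteriousness, conservation, and driver-census enrichment.

Scores each mutation by the number of damage predictors calling it
deleterious, compares scores and conservation between modification-related
and other mutations, and evaluates the census-overlap worked example
(13,378 proteins, 699 census drivers, 473 identified, 45 shared).
"""

from pathlib import Path

import pandas as pd

from lysdriver.sitestats import (
    EnrichmentTable,
    compare_conservation,
    compare_deleteriousness,
    deleterious_score,
    score_distribution,
    set_enrichment,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pred = pd.read_csv(ROOT / "synthetic" / "predictors.tsv", sep="\t")
    scores = deleterious_score(pred)
    is_mod = pred["mutation_class"] == "modification-related"

    prop = compare_deleteriousness(scores[is_mod], scores[~is_mod])
    dist = score_distribution(scores[is_mod], scores[~is_mod])
    cons = compare_conservation(pred.loc[is_mod, "conservation"],
                                pred.loc[~is_mod, "conservation"])

    out = ROOT / "site_stats"
    out.mkdir(parents=True, exist_ok=True)
    prop.to_csv(out / "deleteriousness.tsv", sep="\t", index=False)
    dist.to_csv(out / "score_distribution.tsv", sep="\t", index=False)
    cons.cdf.to_csv(out / "conservation_cdf.tsv", sep="\t", index=False)

    row = prop[prop["threshold"] == 3].iloc[0]
    print(f"score >= 3: {row['prop_a']:.2f} (modification-related) vs "
          f"{row['prop_b']:.2f} (other), z = {row['z']:.1f}, p = {row['p_value']:.2e}")
    print(f"conservation KS: D = {cons.statistic:.3f}, p = {cons.p_value:.2e}")

    p = set_enrichment(EnrichmentTable(N=13378, K=699, n=473, k=45))
    print(f"census-overlap worked example: hypergeometric upper-tail p = {p:.2e}")


if __name__ == "__main__":
    main()
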