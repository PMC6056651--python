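"""Functional characterization of modification-related mutations.

Deleteriousness (count of five damage predictors calling a mutation
deleterious, compared between mutation classes by two-proportion z-tests),
conservation (two-sample Kolmogorov-Smirnov on phastCons-like scores),
driver-set and generic gene-set enrichment (exact hypergeometric upper
tail), and a per-compartment subcellular summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, ks_2samp
from statsmodels.stats.proportion import proportions_ztest

PREDICTOR_COLUMNS = ["sift", "pp2_hvar", "pp2_hdiv", "lrt", "fathmm"]


def deleterious_score(calls: pd.DataFrame, columns=None) -> pd.Series:
    """Count of predictors (of exactly five) calling each mutation deleterious.

    Missing calls count as non-deleterious, so the score stays in {0..5}.
    """
    columns = list(columns) if columns is not None else list(PREDICTOR_COLUMNS)
    if len(columns) != 5:
        raise ValueError("exactly five predictor columns required")
    sub = calls[columns].notna() & calls[columns].astype("boolean").fillna(False)
    return sub.sum(axis=1).astype(int)


def compare_deleteriousness(scores_a, scores_b) -> pd.DataFrame:
    """Two-proportion z-test (no continuity correction) per score threshold.

    For each threshold s in 1..5, compares the proportion of mutations with
    score >= s between the two groups; also reports the score counts behind
    each proportion.
    """
    a = np.asarray(scores_a, dtype=int)
    b = np.asarray(scores_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for s in range(1, 6):
        ka, kb = int((a >= s).sum()), int((b >= s).sum())
        if (ka == 0 and kb == 0) or (ka == a.size and kb == b.size):
            z, p = 0.0, 1.0
        else:
            z, p = proportions_ztest([ka, kb], [a.size, b.size])
        rows.append(
            dict(
                threshold=s,
                prop_a=ka / a.size,
                prop_b=kb / b.size,
                n_a=a.size,
                n_b=b.size,
                z=float(z),
                p_value=float(p),
            )
        )
    return pd.DataFrame(rows)


def score_distribution(scores_a, scores_b) -> pd.DataFrame:
    """Share of each deleterious score (0..5) per group."""
    a = np.asarray(scores_a, dtype=int)
    b = np.asarray(scores_b, dtype=int)
    rows = []
    for s in range(6):
        rows.append(
            dict(
                score=s,
                frac_a=float(np.mean(a == s)) if a.size else np.nan,
                frac_b=float(np.mean(b == s)) if b.size else np.nan,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class ConservationComparison:
    statistic: float
    p_value: float
    cdf: pd.DataFrame  # pooled grid with per-group empirical CDFs
    n_skipped: int


def compare_conservation(scores_a, scores_b) -> ConservationComparison:
    """Two-sample KS test on conservation scores, with CDF curves for plotting."""
    a = pd.to_numeric(pd.Series(scores_a), errors="coerce")
    b = pd.to_numeric(pd.Series(scores_b), errors="coerce")
    n_skipped = int(a.isna().sum() + b.isna().sum())
    a = a.dropna().to_numpy()
    b = b.dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("both score samples must be non-empty")
    res = ks_2samp(a, b, method="asymp")
    grid = np.unique(np.concatenate([a, b]))
    cdf = pd.DataFrame(
        {
            "score": grid,
            "cdf_a": np.searchsorted(np.sort(a), grid, side="right") / a.size,
            "cdf_b": np.searchsorted(np.sort(b), grid, side="right") / b.size,
        }
    )
    return ConservationComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        cdf=cdf,
        n_skipped=n_skipped,
    )


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 overlap layout: population N, marked K, drawn n, overlap k."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.n <= self.N and self.K <= self.N):
            raise ValueError("inconsistent enrichment table")


def set_enrichment(table: EnrichmentTable, alternative: str = "greater") -> float:
    """Exact hypergeometric tail probability of the observed overlap.

    ``greater`` (default) gives the upper tail P(X >= k), the one-sided
    enrichment p-value; ``two-sided`` sums all tables with point probability
    at most that of the observed one.
    """
    if alternative == "greater":
        return float(hypergeom.sf(table.k - 1, table.N, table.K, table.n))
    if alternative == "two-sided":
        rv = hypergeom(table.N, table.K, table.n)
        support = np.arange(rv.support()[0], rv.support()[1] + 1)
        pmf = rv.pmf(support)
        return float(pmf[pmf <= pmf[support == table.k] * (1 + 1e-12)].sum())
    raise ValueError(f"unknown alternative {alternative!r}")


def gene_set_enrichment(
    hits: set[str],
    gene_sets: dict[str, set[str]],
    population: set[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``hits`` in each gene set."""
    from .bayes import bh_adjust

    hits = hits & population
    rows = []
    for name, members in gene_sets.items():
        members = members & population
        if not members:
            continue
        table = EnrichmentTable(
            N=len(population), K=len(members), n=len(hits), k=len(hits & members)
        )
        rows.append(
            dict(gene_set=name, N=table.N, K=table.K, n=table.n, k=table.k,
                 p_value=set_enrichment(table))
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def subcellular_summary(
    drivers,
    locations: dict[str, set[str]],
) -> tuple[pd.DataFrame, int]:
    """Per-compartment driver counts and percentages (of all drivers).

    A protein annotated to several compartments counts once in each;
    proteins absent from the location table are reported as unmapped.
    """
    drivers = list(drivers)
    total = len(drivers)
    counts: dict[str, int] = {}
    unmapped = 0
    for pid in drivers:
        comps = locations.get(pid)
        if not comps:
            unmapped += 1
            continue
        for c in comps:
            counts[c] = counts.get(c, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["compartment", "count"],
    )
    table["percent"] = table["count"] / total * 100 if total else np.nan
    return table, unmapped
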