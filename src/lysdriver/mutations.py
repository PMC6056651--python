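"""Parsing, filtering and per-position counting of somatic mutation tables.

Input is a MAF-like TSV with one row per called variant.  Only
non-synonymous single-nucleotide variants are retained; duplicate calls for
the same patient, cancer type, protein, position and substituted residue are
collapsed; and retained records are mapped onto each protein's
modification/background partition to produce the per-position count vectors
consumed by the Bayesian enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import RegionPartition

REQUIRED_COLUMNS = [
    "sample_id",
    "cancer_type",
    "protein_id",
    "position",
    "ref_aa",
    "alt_aa",
    "variant_class",
]

# ANNOVAR calls these "nonsynonymous SNV"; TCGA MAFs use "Missense_Mutation".
DEFAULT_NONSYN_LABELS = frozenset({"Missense_Mutation", "nonsynonymous SNV", "missense_variant"})

DEDUP_KEY = ["sample_id", "cancer_type", "protein_id", "position", "alt_aa"]


@dataclass
class PositionCounts:
    """Per-position mutation counts over one protein's partition.

    ``mod_counts`` follows the sorted motif-region positions (length ``k``),
    ``bg_counts`` the sorted background positions (length ``n - k``).
    """

    protein_id: str
    cancer_type: str
    mod_counts: np.ndarray
    bg_counts: np.ndarray
    k: int
    n: int
    mod_type: str = "all"
    out_of_bounds: int = 0

    def __post_init__(self) -> None:
        self.mod_counts = np.asarray(self.mod_counts, dtype=int)
        self.bg_counts = np.asarray(self.bg_counts, dtype=int)
        if self.mod_counts.size != self.k or self.bg_counts.size != self.n - self.k:
            raise ValueError("count vector lengths must equal k and n-k")
        if (self.mod_counts < 0).any() or (self.bg_counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sum_mod(self) -> int:
        return int(self.mod_counts.sum())

    @property
    def sum_bg(self) -> int:
        return int(self.bg_counts.sum())


def parse_mutations(
    path,
    nonsyn_labels=DEFAULT_NONSYN_LABELS,
) -> tuple[pd.DataFrame, int]:
    """Read a MAF-like TSV, keep non-synonymous SNVs, count malformed rows.

    Returns ``(records, n_malformed)``.  A missing required column is a hard
    error naming the column; rows with unparsable or non-positive positions,
    or with ``ref_aa == alt_aa``, are skipped and counted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")
    df = df[REQUIRED_COLUMNS]
    pos = pd.to_numeric(df["position"], errors="coerce")
    ok = pos.notna() & (pos >= 1) & (pos == pos.round())
    ok &= df[["sample_id", "protein_id", "ref_aa", "alt_aa"]].notna().all(axis=1)
    ok &= df["ref_aa"] != df["alt_aa"]
    n_malformed = int((~ok).sum())
    df = df[ok].copy()
    df["position"] = pos[ok].astype(int)
    df = df[df["variant_class"].isin(nonsyn_labels)].reset_index(drop=True)
    return df, n_malformed


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Drop redundant calls (same patient/cancer/protein/position/alt), keep first."""
    return records.drop_duplicates(subset=DEDUP_KEY, keep="first").reset_index(drop=True)


def count_positions(
    records: pd.DataFrame,
    partition: RegionPartition,
    cancer_type: str = "all",
    mod_type: str = "all",
) -> PositionCounts:
    """Count records per position over one protein's partition.

    ``records`` should already be restricted to the stratum under test; only
    rows for ``partition.protein_id`` are counted.  Records beyond the
    protein length are excluded and tallied in ``out_of_bounds``; in-bounds
    record totals are conserved (``sum_mod + sum_bg`` equals their number).
    """
    sub = records[records["protein_id"] == partition.protein_id]
    positions = sub["position"].to_numpy(dtype=int)
    in_bounds = (positions >= 1) & (positions <= partition.n)
    oob = int((~in_bounds).sum())
    counts = np.bincount(positions[in_bounds], minlength=partition.n + 1)[1:]
    mod_idx = partition.mod_positions - 1
    bg_idx = partition.bg_positions - 1
    return PositionCounts(
        protein_id=partition.protein_id,
        cancer_type=cancer_type,
        mod_type=mod_type,
        mod_counts=counts[mod_idx],
        bg_counts=counts[bg_idx],
        k=partition.k,
        n=partition.n,
        out_of_bounds=oob,
    )


def count_all(
    records: pd.DataFrame,
    partitions: dict[str, RegionPartition],
    cancer_type: str = "all",
    mod_type: str = "all",
) -> tuple[list[PositionCounts], int]:
    """Counts for every partitioned protein; records naming unpartitioned
    proteins are skipped and counted (non-modified proteins are excluded from
    the test to avoid systematic bias)."""
    known = records["protein_id"].isin(partitions)
    skipped = int((~known).sum())
    out = [
        count_positions(records, part, cancer_type, mod_type)
        for part in partitions.values()
    ]
    return out, skipped


def counts_to_frame(counts_list) -> pd.DataFrame:
    """Summary TSV layout: protein_id, cancer_type, mod_type, k, n, sum_mod, sum_bg."""
    return pd.DataFrame(
        [
            dict(
                protein_id=c.protein_id,
                cancer_type=c.cancer_type,
                mod_type=c.mod_type,
                k=c.k,
                n=c.n,
                sum_mod=c.sum_mod,
                sum_bg=c.sum_bg,
            )
            for c in counts_list
        ]
    )
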