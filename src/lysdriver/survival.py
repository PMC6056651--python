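"""Overall-survival comparison of patients with vs without motif mutations.

Kaplan-Meier product-limit curves per group and a log-rank test between the
group of patients carrying at least one mutation inside a lysine
modification region and the group carrying only other mutations.  Estimation
and testing are delegated to lifelines; this module owns record validation,
grouping, and tabular output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

GROUP_MUTATED = "mutated"
GROUP_OTHER = "non-mutated"


def validate_records(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records with missing or non-positive times; return (kept, n_dropped)."""
    t = pd.to_numeric(records["time"], errors="coerce")
    e = pd.to_numeric(records["event"], errors="coerce")
    ok = t.notna() & (t > 0) & e.isin([0, 1])
    kept = records[ok].copy()
    kept["time"] = t[ok].astype(float)
    kept["event"] = e[ok].astype(int)
    return kept.reset_index(drop=True), int((~ok).sum())


def assign_groups(
    survival: pd.DataFrame,
    mutations: pd.DataFrame,
    partitions,
) -> pd.DataFrame:
    """Label each patient mutated/non-mutated from the mutation table.

    A patient is "mutated" when any of their mutations falls inside any
    protein's modification region (pooled mode, the default downstream).
    """
    mutated: set[str] = set()
    for row in mutations.itertuples(index=False):
        part = partitions.get(row.protein_id)
        if part is None:
            continue
        pos = int(row.position)
        if 1 <= pos <= part.n and np.isin(pos, part.mod_positions):
            mutated.add(row.sample_id)
    out = survival.copy()
    out["group"] = np.where(
        out["patient_id"].isin(mutated), GROUP_MUTATED, GROUP_OTHER
    )
    return out


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit curve for one group.

    Returns a step table (time, at_risk, events, survival) with S(0) = 1 and
    steps only at event times; events precede censorings at tied times.
    """
    records, _ = validate_records(records)
    if records.empty:
        raise ValueError("no valid survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"])
    table = kmf.event_table
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(dtype=float),
        }
    )
    return out


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogrankResult:
    """Log-rank chi-square (1 df) between two survival samples.

    Observed-minus-expected event counts over pooled event times with
    hypergeometric variance; symmetric in the group labels.  With zero
    pooled events the test is undefined and p = 1 is returned with a
    warning.
    """
    a, _ = validate_records(group_a)
    b, _ = validate_records(group_b)
    if a.empty or b.empty:
        raise ValueError("both groups need valid records")
    if a["event"].sum() + b["event"].sum() == 0:
        warnings.warn("no observed events in either group; log-rank undefined", stacklevel=2)
        return LogrankResult(statistic=0.0, p_value=1.0, n_a=len(a), n_b=len(b))
    res = _ll_logrank(a["time"], b["time"], a["event"], b["event"])
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_a=len(a),
        n_b=len(b),
    )


def compare_groups(labelled: pd.DataFrame) -> tuple[dict[str, pd.DataFrame], LogrankResult]:
    """KM curves per group plus the mutated vs non-mutated log-rank test."""
    groups = {
        name: grp for name, grp in labelled.groupby("group")
    }
    if GROUP_MUTATED not in groups or GROUP_OTHER not in groups:
        raise ValueError("need both mutated and non-mutated patients")
    curves = {name: km_estimate(grp) for name, grp in groups.items()}
    result = logrank_test(groups[GROUP_MUTATED], groups[GROUP_OTHER])
    return curves, result
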