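"""Domain-vs-disorder comparison of modification-related mutation rates.

Per protein, the Pfam/SMART-style domain intervals are merged into a domain
region and the remainder is the disorder region; each region's
modification-related mutation burden is expressed per thousand amino acids.
The two per-protein rate samples are compared with a centered two-sample
bootstrap: both samples are translated to share the pooled mean, ``B``
resamples are drawn with replacement, and a studentized mean difference is
referred to its own bootstrap null distribution (two-tailed).  A per-domain
hypergeometric test then flags individual named domains concentrated with
modification-related mutated positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .bayes import bh_adjust

DEFAULT_B = 1000


def per_kaa_rate(count: float, length: float) -> float:
    """Mutations per 1,000 amino acids of region."""
    if length <= 0:
        raise ValueError("region length must be positive")
    return count / length * 1000.0


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent 1-based inclusive intervals per protein."""
    rows = []
    for pid, grp in intervals.groupby("protein_id"):
        ivs = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                rows.append((pid, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((pid, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["protein_id", "start", "end"])


def center_transform(xs, ys) -> tuple[np.ndarray, np.ndarray, float]:
    """Translate both samples to the pooled center z.

    ``z`` is the grand mean of all observations; each sample is shifted by
    its own mean so that ``mean(x~) = mean(y~) = z`` exactly while the
    within-sample spread is untouched.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    z = (xs.sum() + ys.sum()) / (xs.size + ys.size)
    return xs - xs.mean() + z, ys - ys.mean() + z, float(z)


@dataclass
class BootstrapResult:
    t_obs: float
    p_value: float
    B: int
    seed: int


def _t_stat(x_mean, y_mean, x_var, y_var, m, n, printed_denominator: bool):
    # Welch convention divides each variance by its own sample size; the
    # printed_denominator switch swaps the pairing instead.
    if printed_denominator:
        denom = np.sqrt(x_var / n + y_var / m)
    else:
        denom = np.sqrt(x_var / m + y_var / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (x_mean - y_mean) / denom
    return np.where(denom == 0, 0.0, t)


def bootstrap_test(
    xs,
    ys,
    B: int = DEFAULT_B,
    seed: int = 0,
    printed_denominator: bool = False,
) -> BootstrapResult:
    """Two-tailed centered bootstrap test of equal mean rates.

    The observed studentized difference is compared against ``B`` bootstrap
    statistics computed on resamples of the center-shifted samples; the
    p-value is the fraction of bootstrap statistics at least as extreme.
    Degenerate zero-variance, equal-mean data yields t = 0 and p = 1.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    m, n = xs.size, ys.size
    if m < 2 or n < 2:
        raise ValueError("need at least two observations per sample")
    if B < 1:
        raise ValueError("B must be >= 1")
    t_obs = float(
        _t_stat(xs.mean(), ys.mean(), xs.var(ddof=1), ys.var(ddof=1), m, n, printed_denominator)
    )
    x_c, y_c, _ = center_transform(xs, ys)
    rng = np.random.default_rng(seed)
    xb = rng.choice(x_c, size=(B, m), replace=True)
    yb = rng.choice(y_c, size=(B, n), replace=True)
    tb = _t_stat(
        xb.mean(axis=1),
        yb.mean(axis=1),
        xb.var(axis=1, ddof=1),
        yb.var(axis=1, ddof=1),
        m,
        n,
        printed_denominator,
    )
    p = float(np.mean(np.abs(tb) >= abs(t_obs)))
    return BootstrapResult(t_obs=t_obs, p_value=p, B=B, seed=seed)


def domain_disorder_rates(
    domains: pd.DataFrame,
    mutated_positions: dict[str, np.ndarray],
    protein_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-protein per-kAA rates in merged domain vs disorder regions.

    ``mutated_positions`` maps protein id to the (1-based) positions of its
    modification-related mutations, with multiplicity.  Proteins lacking
    either region (zero-length domain or disorder part) are excluded.
    """
    merged = merge_intervals(domains) if len(domains) else domains
    rows = []
    for pid, length in protein_lengths.items():
        ivs = merged[merged["protein_id"] == pid] if len(merged) else merged
        dom_mask = np.zeros(length, dtype=bool)
        for s, e in zip(ivs["start"], ivs["end"]) if len(ivs) else []:
            dom_mask[max(int(s), 1) - 1 : min(int(e), length)] = True
        l1 = int(dom_mask.sum())
        l2 = length - l1
        if l1 == 0 or l2 == 0:
            continue
        pos = np.asarray(mutated_positions.get(pid, []), dtype=int)
        pos = pos[(pos >= 1) & (pos <= length)]
        in_dom = dom_mask[pos - 1].sum() if pos.size else 0
        rows.append(
            dict(
                protein_id=pid,
                domain_count=int(in_dom),
                disorder_count=int(pos.size - in_dom),
                domain_length=l1,
                disorder_length=l2,
                domain_rate=per_kaa_rate(in_dom, l1),
                disorder_rate=per_kaa_rate(pos.size - in_dom, l2),
            )
        )
    return pd.DataFrame(rows)


def domain_hypergeom(
    domains: pd.DataFrame,
    mutated_positions: dict[str, np.ndarray],
    protein_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-named-domain enrichment of modification-related mutated positions.

    Sampling frame: population = all residues of the analyzed proteins (N),
    of which the tested domain's residues are the marked class (K); the
    modification-related mutated positions are the draw (n) and those inside
    the domain the successes (k).  Upper-tail p per domain, BH across
    domains.  With no mutations at all, every p is 1.
    """
    N = int(sum(protein_lengths.values()))
    all_pos = {
        pid: np.unique(np.asarray(p, dtype=int)) for pid, p in mutated_positions.items()
    }
    n_draw = int(sum(p.size for p in all_pos.values()))
    rows = []
    for (pid, name), grp in domains.groupby(["protein_id", "domain_name"]):
        if pid not in protein_lengths:
            continue
        length = protein_lengths[pid]
        mask = np.zeros(length, dtype=bool)
        for s, e in zip(grp["start"].astype(int), grp["end"].astype(int)):
            mask[max(s, 1) - 1 : min(e, length)] = True
        K = int(mask.sum())
        if K == 0:
            raise ValueError(f"domain {name} in {pid} covers no residue")
        pos = all_pos.get(pid, np.array([], dtype=int))
        pos = pos[(pos >= 1) & (pos <= length)]
        k = int(mask[pos - 1].sum()) if pos.size else 0
        p = 1.0 if n_draw == 0 else float(hypergeom.sf(k - 1, N, K, n_draw))
        rows.append(dict(protein_id=pid, domain_name=name, N=N, K=K, n=n_draw, k=k, p_value=p))
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
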