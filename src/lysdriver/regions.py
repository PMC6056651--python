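"""Motif-region construction around lysine-modification sites.

Each modified lysine is summarized by a flanking sequence window.  Windows of
one modification type are clustered into consensus groups (enzyme
recognition motifs differ, so one type can carry several motifs), each group
gets a position-specific scoring matrix, the informative half-width of each
motif is selected from the PSSM's information profile, and every protein is
partitioned into a merged modification region (union of the per-site motif
intervals) and the complementary background region.  The partition supplies
the ``k`` motif positions and ``n - k`` background positions of the
Poisson-Gamma enrichment model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"

DEFAULT_HALF_WIDTH = 10  # standard PTM flanking window
DEFAULT_INFO_THRESHOLD = 0.2  # bits
MIN_WIDTH = 1  # a motif always covers the modified lysine's neighbours


@dataclass(frozen=True)
class SiteWindow:
    protein_id: str
    position: int  # 1-based residue index of the modified lysine
    mod_type: str
    window: str  # length 2h+1, '-'-padded at sequence ends

    def __post_init__(self) -> None:
        if len(self.window) % 2 != 1:
            raise ValueError("window length must be odd")


@dataclass
class MotifModel:
    """Log-odds PSSM of one consensus group, 20 x (2h+1)."""

    mod_type: str
    cluster_id: int
    pssm: np.ndarray
    pseudocount: float
    half_width: int = 0  # selected informative half-width; 0 = not yet selected
    n_windows: int = 0  # windows behind the matrix; drives the bias correction


@dataclass
class RegionPartition:
    """Disjoint cover of a protein's positions by motif region and background."""

    protein_id: str
    n: int
    mod_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.mod_positions = np.unique(np.asarray(self.mod_positions, dtype=int))
        if self.mod_positions.size and (
            self.mod_positions[0] < 1 or self.mod_positions[-1] > self.n
        ):
            raise ValueError("mod positions outside [1, n]")

    @property
    def k(self) -> int:
        return int(self.mod_positions.size)

    @property
    def bg_positions(self) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[self.mod_positions - 1] = False
        return np.nonzero(mask)[0] + 1

    def intervals(self) -> pd.DataFrame:
        """1-based inclusive (region, start, end) rows covering [1, n]."""
        rows = []
        labels = np.zeros(self.n, dtype=bool)
        labels[self.mod_positions - 1] = True
        start = 0
        for i in range(1, self.n + 1):
            if i == self.n or labels[i] != labels[start]:
                rows.append(
                    dict(
                        protein_id=self.protein_id,
                        region="mod" if labels[start] else "bg",
                        start=start + 1,
                        end=i,
                    )
                )
                start = i
        return pd.DataFrame(rows)


def partitions_from_intervals(intervals: pd.DataFrame) -> dict[str, "RegionPartition"]:
    """Rebuild partitions from the (protein_id, region, start, end) TSV layout."""
    out: dict[str, RegionPartition] = {}
    for pid, grp in intervals.groupby("protein_id"):
        n = int(grp["end"].max())
        mod_rows = grp[grp["region"] == "mod"]
        mod = (
            np.concatenate(
                [np.arange(int(s), int(e) + 1) for s, e in zip(mod_rows["start"], mod_rows["end"])]
            )
            if len(mod_rows)
            else np.array([], dtype=int)
        )
        out[pid] = RegionPartition(protein_id=pid, n=n, mod_positions=mod)
    return out


def extract_windows(
    sites: pd.DataFrame,
    sequences: dict[str, str],
    h: int = DEFAULT_HALF_WIDTH,
) -> tuple[list[SiteWindow], int]:
    """Cut a 2h+1 window around each site, '-'-padded at sequence ends.

    Sites beyond the sequence end (or on unknown proteins) are skipped and
    counted; a summary warning is emitted when any are skipped.
    """
    out: list[SiteWindow] = []
    skipped = 0
    for row in sites.itertuples(index=False):
        seq = sequences.get(row.protein_id)
        pos = int(row.position)
        if seq is None or pos < 1 or pos > len(seq):
            skipped += 1
            continue
        lo, hi = pos - 1 - h, pos - 1 + h + 1
        left_pad = max(0, -lo)
        right_pad = max(0, hi - len(seq))
        win = GAP * left_pad + seq[max(lo, 0) : min(hi, len(seq))] + GAP * right_pad
        out.append(SiteWindow(row.protein_id, pos, row.mod_type, win))
    if skipped:
        warnings.warn(f"skipped {skipped} site(s) beyond sequence bounds", stacklevel=2)
    return out, skipped


def _one_hot(windows: list[SiteWindow]) -> np.ndarray:
    # gap columns encode as the zero vector
    width = len(windows[0].window)
    X = np.zeros((len(windows), width * 20))
    for i, w in enumerate(windows):
        for j, a in enumerate(w.window):
            idx = AA_INDEX.get(a)
            if idx is not None:
                X[i, j * 20 + idx] = 1.0
    return X


def cluster_windows(
    windows: list[SiteWindow],
    k_clusters: int,
    seed: int = 0,
    max_iter: int = 300,
) -> np.ndarray:
    """k-means on one-hot window encodings; returns integer labels.

    Lloyd iterations never increase the within-cluster sum of squares, and
    clusters emptied during an iteration are re-seeded from the point
    farthest from its centroid (the library's relocation rule).
    """
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    if len(windows) < k_clusters:
        raise ValueError("need at least k_clusters windows")
    X = _one_hot(windows)
    if k_clusters == 1:
        return np.zeros(len(windows), dtype=int)
    km = KMeans(n_clusters=k_clusters, n_init=10, max_iter=max_iter, random_state=seed)
    return km.fit_predict(X)


def choose_k(
    windows: list[SiteWindow],
    k_max: int = 5,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Pick the cluster count by best mean silhouette over k in {2..k_max}.

    Falls back to one cluster when the windows are too few, carry no
    variance, or no k achieves a positive silhouette.
    """
    n = len(windows)
    if n < 4:
        return 1, np.zeros(n, dtype=int)
    X = _one_hot(windows)
    if np.allclose(X.var(axis=0), 0):
        return 1, np.zeros(n, dtype=int)
    best_k, best_score, best_labels = 1, 0.0, np.zeros(n, dtype=int)
    for k in range(2, min(k_max, n - 1) + 1):
        labels = cluster_windows(windows, k, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_k, best_score, best_labels = k, score, labels
    return best_k, best_labels


def build_pssm(
    windows: list[SiteWindow],
    pseudocount: float = 1.0,
    mod_type: str = "",
    cluster_id: int = 0,
) -> MotifModel:
    """Log-odds PSSM vs a uniform 1/20 background.

    Column probabilities are ``(count(a, j) + c) / (N_j + 20 c)`` over the
    non-gap entries of column ``j``; an all-gap column scores 0.
    """
    if not windows:
        raise ValueError("empty cluster")
    width = len(windows[0].window)
    counts = np.zeros((20, width))
    for w in windows:
        for j, a in enumerate(w.window):
            idx = AA_INDEX.get(a)
            if idx is not None:
                counts[idx, j] += 1
    n_j = counts.sum(axis=0)
    pssm = np.zeros_like(counts)
    for j in range(width):
        if n_j[j] == 0:
            continue
        p = (counts[:, j] + pseudocount) / (n_j[j] + 20 * pseudocount)
        with np.errstate(divide="ignore"):
            col = np.log2(p / (1 / 20))
        pssm[:, j] = np.where(p > 0, col, -np.inf)
    return MotifModel(mod_type=mod_type, cluster_id=cluster_id, pssm=pssm,
                      pseudocount=pseudocount, n_windows=len(windows))


def column_information(motif: MotifModel, n_obs: int | None = None) -> np.ndarray:
    """Per-column information content in bits (KL divergence to uniform).

    With ``n_obs`` given, the Miller-Madow small-sample bias
    ``(20 - 1) / (2 ln 2 n)`` bits is subtracted (floored at 0) so that
    uninformative columns estimated from few windows do not appear
    informative by chance.
    """
    width = motif.pssm.shape[1]
    info = np.zeros(width)
    for j in range(width):
        lo = motif.pssm[:, j]
        p = np.where(np.isfinite(lo), (2.0**lo) / 20.0, 0.0)
        if np.allclose(lo, 0) or p.sum() == 0:  # all-gap column scored 0
            continue
        nz = p > 0
        info[j] = float(np.sum(p[nz] * np.log2(p[nz] * 20)))
    if n_obs is not None and n_obs > 0:
        info = np.maximum(info - 19.0 / (2.0 * np.log(2.0) * n_obs), 0.0)
    return info


def select_width(motif: MotifModel, info_threshold: float = DEFAULT_INFO_THRESHOLD) -> int:
    """Smallest half-width w (>= 1) outside which no column is informative.

    Information is bias-corrected for the cluster size; returns the maximal
    half-width when informative columns extend to the window edge.
    """
    info = column_information(motif, n_obs=motif.n_windows or None)
    h = info.shape[0] // 2
    informative = np.nonzero(info >= info_threshold)[0]
    if informative.size == 0:
        return MIN_WIDTH
    w = int(np.max(np.abs(informative - h)))
    return max(w, MIN_WIDTH)


def build_partition(
    protein_id: str,
    n: int,
    sites_with_widths: list[tuple[int, int]],
) -> RegionPartition | None:
    """Union of clipped [pos - w, pos + w] intervals; None when no sites.

    Proteins without any modification site are excluded from the analysis,
    so an empty site list yields ``None`` rather than an all-background
    partition.
    """
    if not sites_with_widths:
        return None
    mask = np.zeros(n, dtype=bool)
    for pos, w in sites_with_widths:
        if not 1 <= pos <= n:
            raise ValueError(f"site position {pos} outside protein of length {n}")
        mask[max(pos - w, 1) - 1 : min(pos + w, n)] = True
    return RegionPartition(protein_id=protein_id, n=n, mod_positions=np.nonzero(mask)[0] + 1)


def build_partitions(
    sites: pd.DataFrame,
    sequences: dict[str, str],
    h: int = DEFAULT_HALF_WIDTH,
    pseudocount: float = 1.0,
    info_threshold: float = DEFAULT_INFO_THRESHOLD,
    k_max: int = 5,
    seed: int = 0,
) -> dict[str, RegionPartition]:
    """Full region-construction pass for one modification-type stratum.

    Windows are extracted, clustered into consensus groups, a width is
    selected per group from its PSSM, and per-protein partitions are built
    from the sites' group widths.
    """
    windows, _ = extract_windows(sites, sequences, h=h)
    if not windows:
        return {}
    _, labels = choose_k(windows, k_max=k_max, seed=seed)
    widths = {}
    for cid in np.unique(labels):
        members = [w for w, l in zip(windows, labels) if l == cid]
        motif = build_pssm(members, pseudocount=pseudocount, cluster_id=int(cid))
        widths[int(cid)] = select_width(motif, info_threshold=info_threshold)
    per_protein: dict[str, list[tuple[int, int]]] = {}
    for w, l in zip(windows, labels):
        per_protein.setdefault(w.protein_id, []).append((w.position, widths[int(l)]))
    out = {}
    for pid, sw in per_protein.items():
        part = build_partition(pid, len(sequences[pid]), sw)
        if part is not None:
            out[pid] = part
    return out
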