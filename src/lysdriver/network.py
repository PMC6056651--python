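"""Random walk with restart over a merged protein-protein / drug-target network.

The heterogeneous network combines weighted undirected protein-protein
edges with drug-target edges into one graph.  Seeded at the identified
driver proteins, the walk iterates ``p <- (1 - r) W p + r p0`` where ``W``
is the column-normalized weighted adjacency (``W[i, j]`` is the probability
of stepping from node j to node i) and ``p0`` is uniform over the seeds;
the stationary score ranks every node's proximity to the seed set.  The
fixed point is unique for r > 0 and the iteration is cross-checked against
the direct linear solve ``(I - (1 - r) W) p = r p0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

DEFAULT_RESTART = 0.7
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


@dataclass
class HeteroNetwork:
    graph: nx.Graph
    n_self_loops_dropped: int = 0
    n_rejected_rows: int = 0

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def kinds(self) -> dict[str, str]:
        return dict(self.graph.nodes(data="kind"))


def build_network(edges: pd.DataFrame, largest_component: bool = False) -> HeteroNetwork:
    """Assemble the graph from an edge table (source, target, weight, edge_kind).

    Rows with non-positive weight are rejected and counted, self-loops are
    dropped and counted, duplicate edges collapse to the maximum weight.
    Endpoints of ``drug_target`` edges are typed drug (the ``target``
    column) and protein (the ``source`` column); all other endpoints are
    proteins.
    """
    g = nx.Graph()
    rejected = 0
    self_loops = 0
    for row in edges.itertuples(index=False):
        w = float(row.weight)
        if w <= 0 or not np.isfinite(w):
            rejected += 1
            continue
        u, v = str(row.source), str(row.target)
        if u == v:
            self_loops += 1
            continue
        kind = getattr(row, "edge_kind", "ppi")
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w, edge_kind=kind)
        g.nodes[u].setdefault("kind", "protein")
        if kind == "drug_target":
            g.nodes[v]["kind"] = "drug"
        else:
            g.nodes[v].setdefault("kind", "protein")
    for n, kind in g.nodes(data="kind"):
        if kind == "drug":
            bad = [e for e in g.edges(n, data="edge_kind") if e[2] != "drug_target"]
            if bad:
                raise ValueError(f"drug node {n} carries non drug_target edges")
    if largest_component and g.number_of_nodes():
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp).copy()
    return HeteroNetwork(graph=g, n_self_loops_dropped=self_loops, n_rejected_rows=rejected)


def load_network(path, largest_component: bool = False) -> HeteroNetwork:
    edges = pd.read_csv(path, sep="\t", comment="#")
    for col in ("source", "target", "weight", "edge_kind"):
        if col not in edges.columns:
            raise ValueError(f"missing required column: {col}")
    return build_network(edges, largest_component=largest_component)


@dataclass
class RWRResult:
    scores: pd.Series  # indexed by node id
    iterations: int
    residual: float
    seeds: list[str] = field(default_factory=list)
    restart: float = DEFAULT_RESTART


def _transition_matrix(net: HeteroNetwork) -> tuple[sp.csr_matrix, list[str]]:
    nodes = net.nodes
    adj = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, weight="weight", format="csc")
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    col_sums[col_sums == 0] = 1.0  # isolated nodes keep a zero column
    w = adj @ sp.diags(1.0 / col_sums)
    return sp.csr_matrix(w), nodes


def _seed_vector(seeds, nodes: list[str]) -> np.ndarray:
    index = {n: i for i, n in enumerate(nodes)}
    present = [s for s in seeds if s in index]
    if not present:
        raise ValueError("no seed is present in the network")
    p0 = np.zeros(len(nodes))
    p0[[index[s] for s in present]] = 1.0 / len(present)
    return p0


def rwr(
    net: HeteroNetwork,
    seeds,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RWRResult:
    """Power iteration of the restart walk to an L1 residual below ``tol``."""
    if not 0 < r <= 1:
        raise ValueError("restart probability must lie in (0, 1]")
    w, nodes = _transition_matrix(net)
    p0 = _seed_vector(seeds, nodes)
    p = p0.copy()
    for it in range(1, max_iter + 1):
        # w is column-stochastic (w[i, j] = P(j -> i)), so mass is conserved
        p_next = (1 - r) * (w @ p) + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return RWRResult(
                scores=pd.Series(p, index=nodes),
                iterations=it,
                residual=residual,
                seeds=[s for s in seeds if s in set(nodes)],
                restart=r,
            )
    raise RuntimeError(f"RWR did not converge in {max_iter} iterations (residual {residual:.3e})")


def rwr_exact(net: HeteroNetwork, seeds, r: float = DEFAULT_RESTART) -> RWRResult:
    """Direct solve of the stationary system; the iterative solver's oracle."""
    if not 0 < r <= 1:
        raise ValueError("restart probability must lie in (0, 1]")
    w, nodes = _transition_matrix(net)
    p0 = _seed_vector(seeds, nodes)
    n = len(nodes)
    system = sp.identity(n, format="csc") - (1 - r) * w.tocsc()
    p = sp.linalg.spsolve(system, r * p0)
    return RWRResult(
        scores=pd.Series(p, index=nodes),
        iterations=0,
        residual=0.0,
        seeds=[s for s in seeds if s in set(nodes)],
        restart=r,
    )


def top_targets(
    result: RWRResult,
    net: HeteroNetwork,
    k: int = 10,
    exclusions=(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k non-seed protein nodes by stationary score, plus connected drugs.

    Ties break by node id ascending.  Drugs are reported when adjacent to a
    reported target or to a seed.  If fewer than ``k`` candidate proteins
    exist, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kinds = net.kinds()
    excluded = set(result.seeds) | set(exclusions)
    candidates = [
        n for n in result.scores.index if kinds.get(n) == "protein" and n not in excluded
    ]
    ranked = sorted(candidates, key=lambda n: (-result.scores[n], n))
    if k > len(ranked):
        import warnings

        warnings.warn(
            f"requested top {k} but only {len(ranked)} non-seed proteins available",
            stacklevel=2,
        )
    chosen = ranked[:k]
    targets = pd.DataFrame(
        {
            "node": chosen,
            "score": [float(result.scores[n]) for n in chosen],
            "rank": np.arange(1, len(chosen) + 1),
        }
    )
    anchor = set(chosen) | set(result.seeds)
    drugs = sorted(
        {
            n
            for n in net.graph.nodes
            if kinds.get(n) == "drug" and any(nb in anchor for nb in net.graph.neighbors(n))
        }
    )
    drug_table = pd.DataFrame(
        {
            "drug": drugs,
            "score": [float(result.scores.get(d, 0.0)) for d in drugs],
            "targets": [
                ",".join(sorted(set(net.graph.neighbors(d)) & anchor)) for d in drugs
            ],
        }
    )
    return targets, drug_table
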