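"""Co-occurrence networks of ASVs with Louvain clique detection.

ASVs surviving a prevalence/abundance filter (> 20 reads total and present
in > 3 samples, both strict) become nodes; an edge joins two ASVs whose
abundance profiles have Spearman's rho strictly above 0.7 (signed rule —
an absolute-value mode is available behind a flag).  "Cliques" here are
Louvain communities of the unweighted edge graph, numbered from 1; each
node additionally carries its Spearman correlation with selected
geochemical variables, and cliques are summarized by the member median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ASVTable, GeochemTable


def filter_asvs(t: ASVTable, min_total: float = 20, min_sites: int = 3) -> ASVTable:
    """Keep ASVs with total reads > ``min_total`` and occurrence in more
    than ``min_sites`` samples (both bounds strict).  Idempotent."""
    totals = t.counts.sum(axis=1)
    occupancy = (t.counts > 0).sum(axis=1)
    keep = (totals > min_total) & (occupancy > min_sites)
    if not keep.any():
        warnings.warn("ASV filter removed every ASV", stacklevel=2)
    return ASVTable(t.counts.loc[keep], normalized=t.normalized)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation (midranks for ties).

    Returns NaN for constant input, which callers must treat as
    "undefined", never as zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length ≥ 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


@dataclass
class CooccurrenceNetwork:
    nodes: list[str]
    edges: list[tuple[str, str, float]]              # (i, j, rho)
    membership: dict[str, int] = field(default_factory=dict)   # node -> clique id (1-based)
    modularity: float = float("nan")
    node_geochem: pd.DataFrame | None = None         # node × variable rho
    clique_geochem: pd.DataFrame | None = None       # clique × variable median rho
    is_global_optimum: bool | None = None   # set only when optimality was checked

    @property
    def n_cliques(self) -> int:
        return len(set(self.membership.values())) if self.membership else 0

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b, _ in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.edges, columns=["source", "target", "rho"]).to_csv(
            outdir / "network_edges.tsv", sep="\t", index=False,
            float_format="%.10g")
        node_tab = pd.DataFrame(
            {"clique": [self.membership.get(v, 0) for v in self.nodes]},
            index=pd.Index(self.nodes, name="asv_id"),
        )
        if self.node_geochem is not None:
            node_tab = node_tab.join(self.node_geochem)
        node_tab.to_csv(outdir / "network_nodes.tsv", sep="\t",
                        float_format="%.10g")


def build_network(
    t: ASVTable, rho_threshold: float = 0.7, absolute: bool = False
) -> CooccurrenceNetwork:
    """Thresholded Spearman co-occurrence graph over all ASV pairs.

    Edge (i, j) iff rho_ij > ``rho_threshold`` (strict; signed unless
    ``absolute``).  Isolated nodes are retained.
    """
    X = t.counts.to_numpy(dtype=float)
    nodes = t.asv_ids
    if len(nodes) < 2:
        return CooccurrenceNetwork(nodes, [])
    if len(nodes) == 2:
        r12 = spearman_rho(X[0], X[1])
        rho = np.array([[1.0, r12], [r12, 1.0]])
    else:
        rho = stats.spearmanr(X.T).statistic
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            r = rho[i, j]
            if np.isnan(r):
                continue
            if (abs(r) if absolute else r) > rho_threshold:
                edges.append((nodes[i], nodes[j], float(r)))
    return CooccurrenceNetwork(nodes, edges)


# ---------------------------------------------------------------------------
# Louvain

def partition_modularity(
    adj: dict[str, set[str]], membership: dict[str, int]
) -> float:
    """Newman-Girvan modularity of a partition of an unweighted graph."""
    m = sum(len(nb) for nb in adj.values()) / 2
    if m == 0:
        return 0.0
    q = 0.0
    for v, nb in adj.items():
        for w in nb:
            if membership[v] == membership[w]:
                q += 1.0            # each ordered pair once => counts 2*A_ij
    q /= 2 * m
    comm_deg: dict[int, float] = {}
    for v, nb in adj.items():
        comm_deg[membership[v]] = comm_deg.get(membership[v], 0.0) + len(nb)
    q -= sum((d / (2 * m)) ** 2 for d in comm_deg.values())
    return q


def _louvain_level(
    nodes: list[int], adj_w: dict[int, dict[int, float]], min_gain: float
) -> dict[int, int]:
    """One local-moving phase on a weighted graph; returns community ids."""
    # self-loop weights are stored as 2×(internal edge weight), so the plain
    # row sum is already the correct degree and Σ degrees = 2m
    m2 = sum(sum(nb.values()) for nb in adj_w.values())
    degree = {v: sum(adj_w[v].values()) for v in nodes}
    comm = {v: v for v in nodes}
    comm_tot = {v: degree[v] for v in nodes}

    improved = True
    while improved:
        improved = False
        for v in nodes:
            cv = comm[v]
            # weights to neighbouring communities (excluding self-loop)
            links: dict[int, float] = {}
            for w, wt in adj_w[v].items():
                if w == v:
                    continue
                links[comm[w]] = links.get(comm[w], 0.0) + wt
            comm_tot[cv] -= degree[v]
            base = links.get(cv, 0.0) - comm_tot[cv] * degree[v] / m2
            best_c, best_gain = cv, 0.0
            for c in sorted(links):
                if c == cv:
                    continue
                gain = links[c] - comm_tot[c] * degree[v] / m2
                if gain - base > best_gain + min_gain:
                    best_c, best_gain = c, gain - base
            comm[v] = best_c
            comm_tot[best_c] += degree[v]
            if best_c != cv:
                improved = True
    return comm


def _set_partitions(elems: list):
    """All partitions of a small set (Bell-number enumeration)."""
    if not elems:
        yield []
        return
    first, rest = elems[0], elems[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def exhaustive_best_modularity(net: CooccurrenceNetwork,
                               max_nodes: int = 10) -> float:
    """Globally optimal modularity by enumerating every partition.

    Diagnostic oracle for tiny graphs only (Bell numbers explode); used to
    certify or refute the optimality of a heuristic partition.
    """
    if len(net.nodes) > max_nodes:
        raise ValueError(f"exhaustive search limited to ≤ {max_nodes} nodes")
    adj = net.adjacency()
    best = -1.0
    for part in _set_partitions(list(net.nodes)):
        membership = {v: i for i, block in enumerate(part) for v in block}
        best = max(best, partition_modularity(adj, membership))
    return best


def _louvain_once(
    n_nodes: int,
    edges: list[tuple[int, int]],
    first_order: list[int],
    min_gain: float,
) -> dict[int, int]:
    """One full Louvain pass (local moving + aggregation until stable)."""
    adj_w: dict[int, dict[int, float]] = {i: {} for i in range(n_nodes)}
    for ia, ib in edges:
        adj_w[ia][ib] = adj_w[ia].get(ib, 0.0) + 1.0
        adj_w[ib][ia] = adj_w[ib].get(ia, 0.0) + 1.0

    membership = {i: i for i in range(n_nodes)}
    if not any(adj_w[i] for i in adj_w):
        return membership
    order = first_order
    while True:
        comm = _louvain_level(order, adj_w, min_gain)
        # relabel communities compactly
        labels: dict[int, int] = {}
        for v in sorted(comm):
            labels.setdefault(comm[v], len(labels))
        comm = {v: labels[c] for v, c in comm.items()}
        membership = {v: comm[membership[v]] for v in membership}
        if len(labels) == len(adj_w):       # no aggregation happened
            return membership
        new_adj: dict[int, dict[int, float]] = {c: {} for c in range(len(labels))}
        for v, nb in adj_w.items():
            cv = comm[v]
            for w, wt in nb.items():
                cw = comm[w]
                new_adj[cv][cw] = new_adj[cv].get(cw, 0.0) + wt
        adj_w = new_adj
        order = sorted(adj_w)


def louvain(
    net: CooccurrenceNetwork,
    seed: int | None = None,
    resolution: float = 1.0,
    min_gain: float = 1e-10,
    n_restarts: int = 10,
    check_optimality: bool = False,
) -> CooccurrenceNetwork:
    """Two-phase Louvain community detection on the unweighted edge graph.

    The first pass sweeps nodes in ascending id order; the local-moving
    heuristic can stall in a sub-optimal partition, so ``n_restarts − 1``
    further passes with seeded-shuffle sweep orders are run and the
    best-modularity partition kept.  The whole procedure is deterministic
    for fixed (seed, n_restarts).  Isolated nodes become singleton cliques;
    clique ids are renumbered 1..K in order of first appearance, and the
    stored modularity is recomputed independently from the membership.

    Louvain is a greedy heuristic and on some graphs no sweep order reaches
    the globally optimal partition.  With ``check_optimality=True`` (tiny
    graphs, ≤ 10 nodes) the result is certified against exhaustive
    partition enumeration and ``is_global_optimum`` records the verdict;
    otherwise the flag stays ``None``.
    """
    if resolution != 1.0:
        raise NotImplementedError("only resolution 1 is supported")
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = net.adjacency()
    edges_idx = [(index[a], index[b]) for a, b, _ in net.edges]
    base_order = list(range(len(nodes)))
    rng = np.random.default_rng(seed)

    best_membership, best_q = None, -np.inf
    for r in range(max(1, n_restarts)):
        order = base_order if r == 0 else list(rng.permutation(base_order))
        membership = _louvain_once(len(nodes), edges_idx, order, min_gain)
        named_r = {nodes[i]: c for i, c in membership.items()}
        q = partition_modularity(adj, named_r)
        if q > best_q + 1e-15:
            best_membership, best_q = membership, q

    named = {nodes[i]: c for i, c in best_membership.items()}
    # renumber cliques 1..K in order of first appearance over net.nodes
    renum: dict[int, int] = {}
    final = {}
    for v in net.nodes:
        c = named[v]
        if c not in renum:
            renum[c] = len(renum) + 1
        final[v] = renum[c]
    mod = partition_modularity(adj, final)
    optimal = None
    if check_optimality:
        optimal = bool(mod >= exhaustive_best_modularity(net) - 1e-9)
    return CooccurrenceNetwork(net.nodes, net.edges, final, mod,
                               net.node_geochem, net.clique_geochem, optimal)


# ---------------------------------------------------------------------------
# geochemistry correlations

def node_geochem_correlation(
    t: ASVTable,
    g: GeochemTable,
    variables: Sequence[str],
    net: CooccurrenceNetwork | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Spearman rho of each ASV's abundance profile with each variable.

    Returns (node table, clique table); the clique table is the median rho
    of member nodes and requires a network with membership.  Constant
    profiles yield NaN (flagged as undefined).
    """
    samples = t.sample_ids
    gv = g.values.loc[samples, list(variables)]
    rows = {}
    for asv in t.asv_ids:
        x = t.counts.loc[asv].to_numpy(dtype=float)
        rows[asv] = [spearman_rho(x, gv[v].to_numpy()) if len(samples) >= 3
                     else float("nan") for v in variables]
    node_tab = pd.DataFrame.from_dict(rows, orient="index", columns=list(variables))
    node_tab.index.name = "asv_id"

    clique_tab = None
    if net is not None and net.membership:
        mem = pd.Series(net.membership, name="clique")
        joined = node_tab.join(mem, how="inner")
        clique_tab = joined.groupby("clique").median()
    return node_tab, clique_tab
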