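"""Signed Spearman co-occurrence networks and their topological indices.

An edge joins two taxa whose abundance profiles across samples are strongly
and significantly rank-correlated; edge sign records the correlation sign.
Topology indices follow the standard definitions used in microbial network
ecology: average degree (1/n) * sum k_i = 2l/n, density 2l/(n(n-1)),
Louvain modularity on |rho|-weighted edges, and module hubs ranked by
within-module degree z-score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .io_tables import FeatureTable, to_relative_abundance

__all__ = [
    "CorrelationNetwork",
    "TopologyReport",
    "spearman_matrix",
    "pearson_matrix",
    "build_network",
    "average_degree",
    "density",
    "detect_modules",
    "modularity",
    "identify_module_hubs",
    "topology_report",
]

log = logging.getLogger(__name__)


@dataclass
class CorrelationNetwork:
    """Thresholded signed correlation graph over taxa.

    ``edges`` holds (i, j, rho, p, q, sign) with i < j indexing ``node_ids``.
    """

    node_ids: tuple[str, ...]
    node_abundance: np.ndarray
    edges: list[tuple]
    modules: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for i, j, rho, p, q, sign in self.edges:
            if not i < j:
                raise ValueError(f"edge ({i},{j}) must have i < j")
            if abs(rho) > 1 + 1e-12:
                raise ValueError("correlation outside [-1, 1]")
            if sign != int(np.sign(rho)):
                raise ValueError("edge sign inconsistent with rho")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        k = np.zeros(self.n_nodes, dtype=int)
        for i, j, *_ in self.edges:
            k[i] += 1
            k[j] += 1
        return k

    def to_igraph_weights(self):
        """(edge index pairs, |rho| weights) for community detection."""
        idx = np.array([(i, j) for i, j, *_ in self.edges], dtype=int).reshape(-1, 2)
        w = np.array([abs(e[2]) for e in self.edges], dtype=float)
        return idx, w

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node, ab in zip(self.node_ids, self.node_abundance):
            g.add_node(node, mean_relative_abundance=float(ab))
        for i, j, rho, p, q, sign in self.edges:
            g.add_edge(self.node_ids[i], self.node_ids[j],
                       rho=float(rho), p=float(p), q=float(q), sign=int(sign),
                       weight=abs(float(rho)))
        return g


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    modularity: float
    n_modules: int
    positive_edge_fraction: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes, "n_edges": self.n_edges,
            "average_degree": self.average_degree, "density": self.density,
            "modularity": self.modularity, "n_modules": self.n_modules,
            "positive_edge_fraction": self.positive_edge_fraction,
        }


def spearman_matrix(ft: FeatureTable):
    """Pairwise Spearman rho (midrank ties) with p from the t-approximation
    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom.

    Zero-variance taxa get NaN correlations (excluded downstream, logged).
    """
    n, m = ft.values.shape
    if n < 4:
        raise ValueError("need at least 4 samples for correlation networks")
    ranks = np.apply_along_axis(stats.rankdata, 0, ft.values)
    sd = ranks.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        bad = [t for t, d in zip(ft.taxon_ids, degenerate) if d]
        log.warning("zero-variance taxa excluded from correlations: %s", bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (ranks - ranks.mean(axis=0)) / sd
        rho = (z.T @ z) / n
    rho[degenerate, :] = np.nan
    rho[:, degenerate] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0  # |rho| = 1: below machine-representable tail mass
    np.fill_diagonal(p, 0.0)
    return rho, p


def pearson_matrix(ft: FeatureTable):
    """Pairwise Pearson correlation (association strength for robustness)."""
    x = ft.values
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - x.mean(axis=0)) / sd
        r = (z.T @ z) / x.shape[0]
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for a flat vector."""
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def build_network(rho: np.ndarray, p: np.ndarray, ft: FeatureTable,
                  rho_min: float = 0.6, alpha: float = 0.05,
                  correction: str = "BH", keep_isolated: bool = False) -> CorrelationNetwork:
    """Threshold a correlation matrix into a signed network.

    An edge is kept iff |rho| >= rho_min and the (optionally BH-corrected)
    p-value is below alpha. Isolated nodes are dropped unless
    ``keep_isolated``; node abundance is the mean relative abundance over the
    table's samples.
    """
    if not (0 <= rho_min < 1.01):
        raise ValueError("rho_min must lie in [0, 1]")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    m = ft.n_taxa
    iu, ju = np.triu_indices(m, k=1)
    rho_f = rho[iu, ju]
    p_f = p[iu, ju]
    valid = ~np.isnan(rho_f)
    q_f = np.full(m * (m - 1) // 2, np.nan)
    if correction == "BH":
        q_f[valid] = _bh_adjust(p_f[valid])
    elif correction == "none":
        q_f[valid] = p_f[valid]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    keep = valid & (np.abs(rho_f) >= rho_min) & (q_f < alpha)

    rel = ft if ft.mode == "relative" else to_relative_abundance(ft)
    mean_ab = rel.values.mean(axis=0)

    touched = np.zeros(m, dtype=bool)
    touched[iu[keep]] = True
    touched[ju[keep]] = True
    if keep_isolated:
        node_mask = ~np.isnan(rho).all(axis=1)
    else:
        node_mask = touched
    if not node_mask.any():
        log.warning("network is empty at rho_min=%.3g, alpha=%.3g", rho_min, alpha)
        return CorrelationNetwork((), np.array([]), [])
    old_to_new = -np.ones(m, dtype=int)
    old_to_new[node_mask] = np.arange(node_mask.sum())
    node_ids = tuple(t for t, k in zip(ft.taxon_ids, node_mask) if k)
    edges = [
        (int(old_to_new[a]), int(old_to_new[b]), float(r), float(pv), float(qv), int(np.sign(r)))
        for a, b, r, pv, qv in zip(iu[keep], ju[keep], rho_f[keep], p_f[keep], q_f[keep])
    ]
    return CorrelationNetwork(node_ids, mean_ab[node_mask], edges)


def average_degree(net: CorrelationNetwork) -> float:
    """Mean node degree, 2l/n."""
    if net.n_nodes == 0:
        return 0.0
    return 2.0 * net.n_edges / net.n_nodes


def density(net: CorrelationNetwork) -> float:
    """Realized fraction of possible links, 2l/(n(n-1))."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2.0 * net.n_edges / (n * (n - 1))


def detect_modules(net: CorrelationNetwork, resolution: float = 1.0, seed: int = 0):
    """Louvain community detection on |rho|-weighted edges.

    Returns (node -> module id mapping, modularity Q). Deterministic for a
    fixed seed; isolated nodes become singleton modules.
    """
    if net.n_edges == 0:
        modules = {node: k for k, node in enumerate(net.node_ids)}
        return modules, 0.0
    # integer node labels: hash(int) is value-based, so Louvain's internal
    # set iteration is identical across processes (string labels are not)
    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    for i, j, rho, *_ in net.edges:
        g.add_edge(i, j, weight=abs(rho))
    communities = nx.community.louvain_communities(g, weight="weight", resolution=resolution, seed=seed)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    modules = {net.node_ids[i]: k for k, comm in enumerate(communities) for i in comm}
    q = modularity(net, modules, resolution=resolution)
    return modules, q


def modularity(net: CorrelationNetwork, modules: dict[str, int], resolution: float = 1.0) -> float:
    """Weighted Newman modularity Q = sum_c [e_c/W - gamma (a_c/2W)^2], with
    e_c the weight inside community c, a_c its total weighted degree and W
    the total edge weight. Deterministic summation in edge/node order."""
    W = sum(abs(e[2]) for e in net.edges)
    if W == 0:
        return 0.0
    mid = np.array([modules[node] for node in net.node_ids])
    n_comm = mid.max() + 1
    e_c = np.zeros(n_comm)
    a_c = np.zeros(n_comm)
    for i, j, rho, *_ in net.edges:
        w = abs(rho)
        if mid[i] == mid[j]:
            e_c[mid[i]] += w
        a_c[mid[i]] += w
        a_c[mid[j]] += w
    return float((e_c / W - resolution * (a_c / (2.0 * W)) ** 2).sum())


def identify_module_hubs(net: CorrelationNetwork, modules: dict[str, int], top_k: int = 5):
    """Rank nodes by within-module degree z-score Zi.

    Zi = (k_i_within - mean_module) / sd_module; singleton modules (sd
    undefined) score -inf. Ties break by total degree, then node id.
    """
    if top_k > net.n_nodes:
        raise ValueError("top_k exceeds number of nodes")
    within = {node: 0 for node in net.node_ids}
    for i, j, *_ in net.edges:
        a, b = net.node_ids[i], net.node_ids[j]
        if modules[a] == modules[b]:
            within[a] += 1
            within[b] += 1
    by_module: dict[int, list] = {}
    for node in net.node_ids:
        by_module.setdefault(modules[node], []).append(node)
    z = {}
    for nodes in by_module.values():
        k = np.array([within[v] for v in nodes], dtype=float)
        sd = k.std()
        if len(nodes) == 1 or sd == 0:
            for v in nodes:
                z[v] = -np.inf if len(nodes) == 1 else 0.0
        else:
            for v, ki in zip(nodes, k):
                z[v] = (ki - k.mean()) / sd
    total = dict(zip(net.node_ids, net.degrees()))
    ranked = sorted(net.node_ids, key=lambda v: (-z[v], -total[v], v))
    return ranked[:top_k]


def topology_report(net: CorrelationNetwork, resolution: float = 1.0, seed: int = 0) -> TopologyReport:
    modules, q = detect_modules(net, resolution=resolution, seed=seed)
    net.modules = modules
    n_pos = sum(1 for e in net.edges if e[5] > 0)
    return TopologyReport(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        average_degree=average_degree(net),
        density=density(net) if net.n_nodes >= 2 else 0.0,
        modularity=q,
        n_modules=len(set(modules.values())),
        positive_edge_fraction=n_pos / net.n_edges if net.n_edges else float("nan"),
    )
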