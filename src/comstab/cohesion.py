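"""Community complexity (cohesion) and stability (robustness).

Cohesion summarizes, per sample, how strongly its members co-vary with the
rest of the community:

    cohesion_pos = sum_i abundance_i * connectedness_pos_i
    cohesion_neg = sum_i abundance_i * connectedness_neg_i

where connectedness_pos_i (resp. neg) is the mean of the retained positive
(resp. negative) correlations of taxon i with other taxa. Total cohesion is
positive cohesion plus the magnitude of negative cohesion. Since abundances
sum to 1 and |connectedness| <= 1, every cohesion value is bounded by 1.

Robustness is the proportion of species remaining in a co-occurrence network
after a perturbation (random removal of a fraction of nodes, or targeted
removal of module hubs) followed by secondary extinctions iterated to a
fixed point: a remaining species goes extinct when it has no remaining
network edges or when its abundance-weighted mean association strength

    sum_{j != i, remaining} b_j s_ij / sum_{j != i, remaining} b_j

is nonpositive. Association strength s_ij is the Pearson correlation of
relative abundances; b_j is mean relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import FeatureTable
from .network import CorrelationNetwork, identify_module_hubs, pearson_matrix

__all__ = [
    "CohesionResult",
    "RobustnessResult",
    "retained_correlation_matrix",
    "null_corrected_matrix",
    "connectedness",
    "cohesion",
    "cohesion_table",
    "robustness",
    "per_sample_stability",
]


@dataclass(frozen=True)
class CohesionResult:
    sample_id: str
    positive_cohesion: float
    negative_cohesion: float

    @property
    def total_cohesion(self) -> float:
        return self.positive_cohesion + abs(self.negative_cohesion)


@dataclass(frozen=True)
class RobustnessResult:
    protocol: str                 # "random_fraction" | "targeted_hubs"
    parameter: float
    n_iterations: int
    seed: int | None
    proportion_remaining: float
    per_iteration: np.ndarray

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol, "parameter": self.parameter,
            "n_iterations": self.n_iterations, "seed": self.seed,
            "proportion_remaining": self.proportion_remaining,
        }


def retained_correlation_matrix(ft: FeatureTable, rho: np.ndarray, p: np.ndarray,
                                corr_source: str = "network_edges",
                                net: CorrelationNetwork | None = None,
                                alpha: float = 0.05) -> np.ndarray:
    """Matrix of correlations entering connectedness; non-retained pairs are NaN.

    ``network_edges`` keeps exactly the edges of a thresholded network (taxa
    absent from the network have no retained correlations);
    ``all_significant`` keeps every pair with raw p < alpha.
    """
    m = ft.n_taxa
    out = np.full((m, m), np.nan)
    if corr_source == "network_edges":
        if net is None:
            raise ValueError("corr_source='network_edges' requires a network")
        tindex = {t: k for k, t in enumerate(ft.taxon_ids)}
        for i, j, r, *_ in net.edges:
            a, b = tindex[net.node_ids[i]], tindex[net.node_ids[j]]
            out[a, b] = out[b, a] = r
    elif corr_source == "all_significant":
        keep = (p < alpha) & ~np.isnan(rho)
        np.fill_diagonal(keep, False)
        out[keep] = rho[keep]
    else:
        raise ValueError(f"unknown corr_source {corr_source!r}")
    return out


def null_corrected_matrix(ft: FeatureTable, retained: np.ndarray,
                          n_null: int = 200, seed: int | None = 0) -> np.ndarray:
    """Subtract the taxon-shuffle null expectation from retained correlations.

    Each null replicate permutes every taxon's abundances independently
    across samples and recomputes the pairwise Spearman matrix; the mean over
    replicates estimates the correlation expected in the absence of real
    co-occurrence structure (nonzero mainly through ties and closure). The
    corrected matrix keeps the NaN pattern of ``retained``.
    """
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    ranks = np.apply_along_axis(rankdata, 0, ft.values)
    sd = ranks.std(axis=0)
    sd[sd == 0] = np.nan
    z = (ranks - ranks.mean(axis=0)) / sd
    n = ft.n_samples
    acc = np.zeros((ft.n_taxa, ft.n_taxa))
    for _ in range(n_null):
        shuffled = np.column_stack([z[rng.permutation(n), j] for j in range(ft.n_taxa)])
        acc += (shuffled.T @ shuffled) / n
    return retained - acc / n_null


def connectedness(retained: np.ndarray):
    """Per-taxon (positive, negative) connectedness from a retained-correlation
    matrix (NaN = pair not retained). A taxon with no retained positive
    (negative) partners gets 0 for that component.
    """
    with np.errstate(invalid="ignore"):
        pos_mask = retained > 0
        neg_mask = retained < 0
    pos = np.where(pos_mask.any(axis=1),
                   np.nansum(np.where(pos_mask, retained, 0.0), axis=1) / np.maximum(pos_mask.sum(axis=1), 1),
                   0.0)
    neg = np.where(neg_mask.any(axis=1),
                   np.nansum(np.where(neg_mask, retained, 0.0), axis=1) / np.maximum(neg_mask.sum(axis=1), 1),
                   0.0)
    return pos, neg


def cohesion(ft: FeatureTable, conn_pos: np.ndarray, conn_neg: np.ndarray) -> list[CohesionResult]:
    """Per-sample cohesion as the abundance-weighted sum of connectedness."""
    if ft.mode != "relative":
        raise ValueError("cohesion requires a relative-abundance table")
    if len(conn_pos) != ft.n_taxa or len(conn_neg) != ft.n_taxa:
        raise ValueError("connectedness length does not match taxa")
    pos = ft.values @ conn_pos
    neg = ft.values @ conn_neg
    return [CohesionResult(s, float(pc), float(nc))
            for s, pc, nc in zip(ft.sample_ids, pos, neg)]


def cohesion_table(results: list[CohesionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {"sample_id": [r.sample_id for r in results],
         "positive_cohesion": [r.positive_cohesion for r in results],
         "negative_cohesion": [r.negative_cohesion for r in results],
         "total_cohesion": [r.total_cohesion for r in results]}
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# robustness


def _adjacency(net: CorrelationNetwork) -> np.ndarray:
    adj = np.zeros((net.n_nodes, net.n_nodes), dtype=bool)
    for i, j, *_ in net.edges:
        adj[i, j] = adj[j, i] = True
    return adj


def _simulate_removal(adj: np.ndarray, strength: np.ndarray, b: np.ndarray,
                      removed: np.ndarray) -> float:
    """Propagate secondary extinctions to a fixed point; return fraction left."""
    n = adj.shape[0]
    alive = np.ones(n, dtype=bool)
    alive[removed] = False
    while True:
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        sub_adj = adj[np.ix_(idx, idx)]
        has_edge = sub_adj.any(axis=1)
        s = strength[np.ix_(idx, idx)].copy()
        np.fill_diagonal(s, 0.0)
        bb = b[idx]
        denom = bb.sum() - bb  # sum_{j != i} b_j among the living
        num = s @ bb
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_strength = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), -np.inf)
        extinct = (~has_edge) | (mean_strength <= 0)
        if not extinct.any():
            break
        alive[idx[extinct]] = False
    return alive.sum() / n


def robustness(net: CorrelationNetwork, strength: np.ndarray,
               protocol: str = "random_fraction", parameter: float = 0.5,
               n_iterations: int = 999, seed: int | None = None,
               modules: dict | None = None, abundances: np.ndarray | None = None) -> RobustnessResult:
    """Proportion of species remaining after node removal plus secondary
    extinctions.

    ``strength`` is the n_nodes x n_nodes Pearson association matrix aligned
    with ``net.node_ids``. Random protocol removes floor(parameter * n)
    uniformly chosen nodes per iteration; targeted protocol removes the top
    ``parameter`` module hubs once (deterministic).
    """
    n = net.n_nodes
    if n == 0:
        raise ValueError("robustness of an empty network is undefined")
    if strength.shape != (n, n):
        raise ValueError("strength matrix does not match network nodes")
    b = np.asarray(net.node_abundance if abundances is None else abundances, dtype=float)
    adj = _adjacency(net)
    s = np.nan_to_num(strength, nan=0.0)

    if protocol == "random_fraction":
        if not (0 < parameter < 1):
            raise ValueError("removal fraction must lie in (0, 1)")
        n_remove = int(np.floor(parameter * n))
        if n_remove < 1:
            raise ValueError("removal fraction removes no node")
        rng = np.random.default_rng(seed)
        per_iter = np.array([
            _simulate_removal(adj, s, b, rng.choice(n, size=n_remove, replace=False))
            for _ in range(n_iterations)
        ])
    elif protocol == "targeted_hubs":
        if modules is None:
            raise ValueError("targeted protocol requires module assignments")
        k = int(parameter)
        if not (0 < k <= n):
            raise ValueError("hub count must lie in [1, n_nodes]")
        hubs = identify_module_hubs(net, modules, top_k=k)
        hub_idx = np.array([net.node_ids.index(h) for h in hubs])
        per_iter = np.array([_simulate_removal(adj, s, b, hub_idx)])
        n_iterations = 1
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    return RobustnessResult(protocol, float(parameter), int(n_iterations), seed,
                            float(per_iter.mean()), per_iter)


def per_sample_stability(ft: FeatureTable, net: CorrelationNetwork,
                         protocol: str = "random_fraction", parameter: float = 0.5,
                         n_iterations: int = 99, seed: int | None = None,
                         modules: dict | None = None,
                         counts: FeatureTable | None = None) -> pd.Series:
    """Per-sample stability: robustness of the subnetwork induced by the taxa
    present (abundance > 0) in that sample.

    The removal protocol and parameter mirror the group-level robustness;
    each sample gets an independent child seed of ``seed`` so the whole
    vector is reproducible. Samples whose induced subnetwork is empty or too
    small for the protocol score 0 (no network to be robust). Association
    strength is computed on ``counts`` when given (the table the network was
    inferred from), otherwise on ``ft``.
    """
    if ft.mode != "relative":
        raise ValueError("per-sample stability requires a relative-abundance table")
    strength_full = np.nan_to_num(pearson_matrix(counts if counts is not None else ft), nan=0.0)
    tindex = {t: k for k, t in enumerate(ft.taxon_ids)}
    node_cols = np.array([tindex[t] for t in net.node_ids])
    strength = strength_full[np.ix_(node_cols, node_cols)]
    edge_lookup = {}
    for e in net.edges:
        edge_lookup.setdefault(e[0], []).append(e)

    children = np.random.SeedSequence(seed).spawn(ft.n_samples)
    out = {}
    for row, sid, child in zip(ft.values, ft.sample_ids, children):
        present = row[node_cols] > 0
        keep = np.flatnonzero(present)
        if keep.size < 2:
            out[sid] = 0.0
            continue
        remap = -np.ones(net.n_nodes, dtype=int)
        remap[keep] = np.arange(keep.size)
        sub_edges = [
            (int(remap[i]), int(remap[j]), r, p, q, sg)
            for i, j, r, p, q, sg in net.edges
            if present[i] and present[j]
        ]
        sub_ab = row[node_cols][keep]
        sub_net = CorrelationNetwork(tuple(net.node_ids[k] for k in keep),
                                     sub_ab / sub_ab.sum(), sub_edges)
        if sub_net.n_edges == 0:
            out[sid] = 0.0
            continue
        if protocol == "random_fraction" and np.floor(parameter * sub_net.n_nodes) < 1:
            out[sid] = 0.0
            continue
        sub_modules = None
        if protocol == "targeted_hubs":
            from .network import detect_modules
            sub_modules, _ = detect_modules(sub_net, seed=int(child.generate_state(1)[0] % (2 ** 31)))
            parameter = min(int(parameter), sub_net.n_nodes)
        res = robustness(sub_net, strength[np.ix_(keep, keep)], protocol=protocol,
                         parameter=parameter, n_iterations=n_iterations,
                         seed=int(child.generate_state(1)[0] % (2 ** 31)),
                         modules=sub_modules)
        out[sid] = res.proportion_remaining
    return pd.Series(out, name="stability")
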