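"""Co-occurrence network construction, module detection, and node roles.

Pipeline: a taxon x taxon correlation matrix (Spearman on relative
abundances by default, or a basic SparCC estimate on counts), an
empirical "pseudo-p" per pair from margin-preserving permutation null
datasets, a strict |r| > 0.6 AND p < 0.05 edge filter, greedy
(Clauset-Newman-Moore) modularity on the resulting unweighted graph, and
the Guimera-Amaral topological roles from within-module connectivity Zi
and among-module connectivity Pi:

    Zi = (k_i,s - mean_s) / sd_s        (z-score of within-module degree)
    Pi = 1 - sum_m (k_i,m / k_i)^2      (participation coefficient)

with the conventional thresholds Zi >= 2.5 and Pi >= 0.62 separating
peripherals, connectors, module hubs and network hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CommunityTable

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_matrix",
    "bootstrap_pseudo_p",
    "build_network",
    "greedy_modularity",
    "zi_pi",
    "classify_roles",
    "network_stats",
    "NetworkStats",
]

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module hub"
ROLE_NETWORK_HUB = "network hub"


# ---------------------------------------------------------------------------
# correlation estimation
# ---------------------------------------------------------------------------


def _nonconstant_rows(values: np.ndarray, ids: list[str]) -> list[int]:
    keep = []
    for i in range(values.shape[0]):
        if np.ptp(values[i]) > 0:
            keep.append(i)
        else:
            logger.warning("excluding zero-variance taxon %r", ids[i])
    return keep


def _spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Rank (midranks for ties) each row across samples, then Pearson."""
    ranks = rankdata(values, axis=1)
    return np.corrcoef(ranks)


def _sparcc_basic(counts: np.ndarray, n_exclude_iter: int = 10) -> np.ndarray:
    """Basic SparCC correlation estimate from log-ratio variances.

    Uses pseudocount-added counts, the variation matrix
    t_ij = var(log(x_i / x_j)), and the sparsity approximation that
    solves (D-2) w_i + sum_j w_j = sum_j t_ij for the component
    variances w. Up to ``n_exclude_iter`` iterations drop the currently
    most-correlated pair (|rho| > 0.1) from the row sums and re-solve,
    the cited algorithm's guard against a few strong correlations
    biasing the basis variances.
    """
    log_x = np.log(counts + 1.0)
    d = log_x.shape[0]
    if d < 4:
        raise ValueError("SparCC needs at least 4 taxa")
    # variation matrix
    t = np.var(log_x[:, None, :] - log_x[None, :, :], axis=2, ddof=1)
    excluded = np.zeros((d, d), dtype=bool)

    def solve() -> np.ndarray:
        m = np.full((d, d), 1.0)
        np.fill_diagonal(m, d - 1.0)
        m = m - excluded.astype(float)  # excluded pairs leave both sums
        t_eff = np.where(excluded, 0.0, t)
        w = np.linalg.solve(m, t_eff.sum(axis=1))
        return np.maximum(w, 1e-12)

    def rho_from(w: np.ndarray) -> np.ndarray:
        outer = np.add.outer(w, w)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (outer - t) / denom
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0)

    rho = rho_from(solve())
    for _ in range(n_exclude_iter):
        masked = np.where(excluded, 0.0, np.abs(rho))
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= 0.1:
            break
        excluded[i, j] = excluded[j, i] = True
        rho = rho_from(solve())
    return rho


def correlation_matrix(table: CommunityTable, method: str = "spearman") -> pd.DataFrame:
    """Taxon x taxon correlation matrix (zero-variance taxa excluded).

    ``method="spearman"`` rank-correlates relative abundances with
    midranks for ties; ``method="sparcc"`` runs the basic SparCC
    log-ratio-variance estimate on pseudocount-added counts. Requires at
    least 4 samples.
    """
    if method not in ("spearman", "sparcc"):
        raise ValueError(f"unknown correlation method {method!r}")
    if table.shape[1] < 4:
        raise ValueError("correlation_matrix needs at least 4 samples")
    if method == "spearman":
        values = table.relative_abundance().to_numpy()
        keep = _nonconstant_rows(values, table.taxon_ids)
        ids = [table.taxon_ids[i] for i in keep]
        r = _spearman_matrix(values[keep])
    else:
        keep = _nonconstant_rows(table.counts, table.taxon_ids)
        ids = [table.taxon_ids[i] for i in keep]
        r = _sparcc_basic(table.counts[keep])
    return pd.DataFrame(r, index=ids, columns=ids)


def bootstrap_pseudo_p(
    table: CommunityTable,
    method: str = "spearman",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical two-sided pseudo-p for every taxon pair.

    Null datasets permute each taxon's values independently across
    samples (margins preserved, all pairwise association destroyed);
    pseudo_p = (1 + #{null |r| >= observed |r|}) / (n_boot + 1).
    Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    r_obs = correlation_matrix(table, method=method)
    ids = list(r_obs.index)
    obs_abs = np.abs(r_obs.to_numpy())
    sub = CommunityTable(table.data.loc[ids])
    rng = np.random.default_rng(seed)
    n_taxa, n_samples = sub.shape
    exceed = np.zeros_like(obs_abs)
    if method == "spearman":
        # permuting values permutes ranks: precompute ranks once
        base = rankdata(sub.relative_abundance().to_numpy(), axis=1)
    else:
        base = sub.counts
    for _ in range(n_boot):
        perm = np.array([base[i, rng.permutation(n_samples)] for i in range(n_taxa)])
        if method == "spearman":
            r_null = np.corrcoef(perm)
        else:
            r_null = _sparcc_basic(perm)
        exceed += np.abs(r_null) >= obs_abs
    p = (1.0 + exceed) / (n_boot + 1.0)
    return pd.DataFrame(p, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# graph construction and module analysis
# ---------------------------------------------------------------------------


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    r_threshold: float = 0.6,
    p_threshold: float = 0.05,
) -> nx.Graph:
    """Undirected simple graph keeping edges with |r| > r_threshold AND
    p < p_threshold (both strict). Isolated nodes are retained; edges
    carry ``r`` and ``pseudo_p`` attributes.
    """
    if list(r.index) != list(r.columns) or list(p.index) != list(p.columns):
        raise ValueError("correlation/p matrices must be square with matching labels")
    if list(r.index) != list(p.index):
        raise ValueError("r and p matrices index different taxa")
    rv, pv = r.to_numpy(), p.to_numpy()
    if np.abs(rv - rv.T).max(initial=0.0) > 1e-10 or np.abs(pv - pv.T).max(initial=0.0) > 1e-10:
        raise ValueError("asymmetric input matrix")
    graph = nx.Graph()
    ids = list(r.index)
    graph.add_nodes_from(ids)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(rv[i, j]) > r_threshold and pv[i, j] < p_threshold:
                graph.add_edge(ids[i], ids[j], r=float(rv[i, j]),
                               pseudo_p=float(pv[i, j]))
    return graph


def greedy_modularity(graph: nx.Graph) -> tuple[dict[str, int], float]:
    """Clauset-Newman-Moore greedy modularity maximization (unweighted).

    Returns ``(node -> module id, Q)``. Module ids are assigned by
    decreasing module size, ties by smallest member node id, so the
    labelling is deterministic. A graph with no edges puts every node in
    its own module with Q = 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    # sorted relabelling makes the CNM heap tie-breaks reproducible
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(graph.nodes()))
    ordered.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in graph.edges()))
    if ordered.number_of_edges() == 0:
        return {node: i for i, node in enumerate(sorted(ordered.nodes()))}, 0.0
    communities = nx.community.greedy_modularity_communities(ordered)
    communities = sorted(
        (sorted(c) for c in communities), key=lambda c: (-len(c), c[0])
    )
    modules = {node: i for i, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(ordered, [set(c) for c in communities])
    return modules, float(q)


def zi_pi(graph: nx.Graph, modules: dict[str, int]) -> pd.DataFrame:
    """Within-module connectivity Zi and among-module connectivity Pi.

    Zi z-scores node i's within-module degree against the within-module
    degrees of all nodes of its module (Zi = 0 when that standard
    deviation is 0). Pi = 1 - sum_m (k_i,m / k_i)^2; Pi = 0 for isolated
    nodes.
    """
    missing = [n for n in graph.nodes() if n not in modules]
    if missing:
        raise ValueError(f"nodes without module assignment: {sorted(missing)[:5]}")
    nodes = list(graph.nodes())
    module_ids = sorted(set(modules[n] for n in nodes))
    # within-module degree per node
    k_within = {
        n: sum(1 for nb in graph.neighbors(n) if modules[nb] == modules[n])
        for n in nodes
    }
    stats = {}
    for m in module_ids:
        members = [n for n in nodes if modules[n] == m]
        vals = np.array([k_within[n] for n in members], dtype=float)
        stats[m] = (vals.mean(), vals.std(ddof=0))
    records = {}
    for n in nodes:
        mean, sd = stats[modules[n]]
        zi = (k_within[n] - mean) / sd if sd > 0 else 0.0
        k_total = graph.degree(n)
        if k_total == 0:
            pi = 0.0
        else:
            per_module = {}
            for nb in graph.neighbors(n):
                per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
            pi = 1.0 - sum((k / k_total) ** 2 for k in per_module.values())
        records[n] = {"module": modules[n], "Zi": zi, "Pi": pi, "degree": k_total}
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "taxon_id"
    return out


def classify_roles(
    zipi: pd.DataFrame, zi_threshold: float = 2.5, pi_threshold: float = 0.62
) -> pd.Series:
    """Four-way topological role per node from (Zi, Pi).

    Boundaries are inclusive upward: Zi >= zi_threshold counts as hub,
    Pi >= pi_threshold counts as connector-like.
    """
    hub = zipi["Zi"] >= zi_threshold
    conn = zipi["Pi"] >= pi_threshold
    roles = np.where(
        hub & conn, ROLE_NETWORK_HUB,
        np.where(hub, ROLE_MODULE_HUB, np.where(conn, ROLE_CONNECTOR, ROLE_PERIPHERAL)),
    )
    return pd.Series(roles, index=zipi.index, name="role")


@dataclass
class NetworkStats:
    """Global attributes: average degree avgK, average path distance GD,
    degree distribution, modularity and module count."""

    n_nodes: int
    n_edges: int
    avg_degree: float                       # avgK = 2E/N
    avg_path_distance: float | None        # GD; None when no connected pairs
    n_unreachable_pairs: int               # ordered pairs excluded from GD
    degree_distribution: dict[int, int]
    modularity: float
    n_modules: int

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avgK": self.avg_degree,
            "GD": self.avg_path_distance,
            "n_unreachable_pairs": self.n_unreachable_pairs,
            "degree_distribution": {str(k): v for k, v in
                                    sorted(self.degree_distribution.items())},
            "modularity": self.modularity,
            "n_modules": self.n_modules,
        }


def network_stats(
    graph: nx.Graph, modules: dict[str, int] | None = None, modularity: float | None = None
) -> NetworkStats:
    """Global network attributes; computes modules via greedy modularity
    when not supplied."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if modules is None or modularity is None:
        modules, modularity = greedy_modularity(graph)
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    degrees = [d for _, d in graph.degree()]
    dist_counts: dict[int, int] = {}
    for d in degrees:
        dist_counts[d] = dist_counts.get(d, 0) + 1
    total = 0.0
    pairs = 0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        for target, length in lengths.items():
            if length > 0:
                total += length
                pairs += 1
    gd = total / pairs if pairs else None
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        avg_degree=2.0 * e / n,
        avg_path_distance=gd,
        n_unreachable_pairs=n * (n - 1) - pairs,
        degree_distribution=dist_counts,
        modularity=float(modularity),
        n_modules=len(set(modules.values())),
    )
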