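"""Correlation-screened co-occurrence networks and their statistics.

Networks are built from pairwise Spearman correlations between features
(taxa relative abundances, or the eight enzyme activities) across samples:
an undirected edge joins two features when |rho| > 0.6 and p < 0.05 (both
configurable). Because the screen typically operates at n = 8 samples per
treatment, p-values use the exact permutation null of the rank statistic
for n <= 9 (the t-approximation is unreliable there); ties, and larger n,
fall back to the t-approximation.

Statistics reported per network:

* complexity — avgK (mean degree 2L/N), avgCC (mean local clustering,
  degree<2 nodes contributing 0), GD (mean shortest-path length over
  reachable ordered pairs, unweighted), Con (connectance L / C(N,2)),
  modularity of a deterministic greedy partition;
* stability — robustness (mean fraction of surviving nodes keeping >=1
  edge after random removal of 50% of nodes) and vulnerability (maximal
  relative drop in global efficiency when a single node is deleted);
* node roles — within-module degree z-score Zi and participation
  coefficient Pi; module hubs (Zi > 2.5), network hubs (Zi > 2.5 and
  Pi > 0.62), connectors (Pi > 0.62), peripherals; all non-peripheral
  nodes count as keystones;
* accounting — positive/negative link counts, modules (communities with
  >= 2 nodes), keystone count.

Path-based metrics ignore edge weights and signs; signs are kept only for
link accounting.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_RHO = 0.6
DEFAULT_ALPHA = 0.05
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class CoNetwork:
    """Signed undirected co-occurrence graph.

    ``graph`` edges carry ``rho`` (Spearman coefficient) and ``sign``
    ('+' or '-'); ``n_samples`` records the sample count used in the
    screen.
    """

    graph: nx.Graph
    n_samples: int = 0

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkMetrics:
    avgK: float = np.nan
    avgCC: float = np.nan
    GD: float = np.nan
    Con: float = np.nan
    modularity: float = np.nan
    robustness: float = np.nan
    vulnerability: float = np.nan
    n_nodes: int = 0
    n_pos_links: int = 0
    n_neg_links: int = 0
    n_modules: int = 0
    n_keystone: int = 0
    partition: list[frozenset] = field(default_factory=list, repr=False)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "n_nodes": self.n_nodes,
                "avgK": self.avgK,
                "avgCC": self.avgCC,
                "GD": self.GD,
                "Con": self.Con,
                "modularity": self.modularity,
                "robustness": self.robustness,
                "vulnerability": self.vulnerability,
                "n_pos_links": self.n_pos_links,
                "n_neg_links": self.n_neg_links,
                "n_modules": self.n_modules,
                "n_keystone": self.n_keystone,
            }
        )


# ---------------------------------------------------------------------------
# Spearman screen

@lru_cache(maxsize=4)
def _exact_null(n: int) -> np.ndarray:
    """Sorted |rho| values of the exact Spearman permutation null (no ties)."""
    ranks = np.array(list(itertools.permutations(range(n))), dtype=np.float64)
    ident = np.arange(n, dtype=np.float64)
    d2 = ((ranks - ident) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    return np.sort(np.abs(rho))


def spearman_pvalue(rho: float, n: int, exact: bool | None = None,
                    ties: bool = False) -> float:
    """Two-sided p-value for an observed Spearman rho at sample size n.

    Exact permutation p when n <= 9 and the data are tie-free; otherwise
    the t-approximation with n-2 degrees of freedom.
    """
    if np.isnan(rho):
        return np.nan
    if exact is None:
        exact = n <= 9 and not ties
    if exact:
        null = _exact_null(n)
        # right-tail count of |rho_null| >= |rho| (small numeric slack)
        k = len(null) - np.searchsorted(null, abs(rho) - 1e-12, side="left")
        return k / len(null)
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def build_network(
    table: pd.DataFrame,
    rho_threshold: float = DEFAULT_RHO,
    alpha: float = DEFAULT_ALPHA,
    min_prevalence: int | None = None,
) -> CoNetwork:
    """Screen all feature pairs and keep edges with |rho| > threshold, p < alpha.

    Zero-variance features and features present (nonzero) in fewer than
    ``min_prevalence`` samples (default: half the samples) are dropped
    before screening; at n = 8 such zero-inflated features generate
    spurious perfect correlations.
    """
    n = table.shape[0]
    if n < 4:
        raise ValidationError("network screen needs at least 4 samples")
    if min_prevalence is None:
        min_prevalence = math.ceil(n / 2)
    x = table.to_numpy(dtype=float)
    prevalence = (x != 0).sum(axis=0)
    variable = np.array([np.ptp(col) > 0 for col in x.T])
    keep = (prevalence >= min_prevalence) & variable
    dropped = int((~keep).sum())
    if dropped:
        logger.info("network screen: dropped %d features (prevalence/variance)",
                    dropped)
    feats = list(table.columns[keep])
    if not feats:
        raise ValidationError("all features dropped before network screen")
    x = x[:, keep]
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    has_ties = [len(np.unique(col)) < n for col in x.T]
    rz = (ranks - ranks.mean(axis=0)) / ranks.std(axis=0)
    rho_mat = rz.T @ rz / n
    g = nx.Graph()
    g.add_nodes_from(feats)
    for i, j in itertools.combinations(range(len(feats)), 2):
        rho = float(np.clip(rho_mat[i, j], -1.0, 1.0))
        if abs(rho) <= rho_threshold:
            continue
        p = spearman_pvalue(rho, n, ties=has_ties[i] or has_ties[j])
        if p < alpha:
            g.add_edge(feats[i], feats[j], rho=rho, sign="+" if rho > 0 else "-")
    return CoNetwork(graph=g, n_samples=n)


# ---------------------------------------------------------------------------
# Topology

def topology(net: CoNetwork) -> NetworkMetrics:
    """Complexity statistics and the deterministic module partition."""
    g = net.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValidationError("topology needs at least 2 nodes")
    L = g.number_of_edges()
    m = NetworkMetrics(n_nodes=n)
    m.avgK = 2.0 * L / n
    m.avgCC = float(np.mean(list(nx.clustering(g).values())))
    m.Con = L / (n * (n - 1) / 2.0)
    # GD: mean shortest-path length over reachable ordered pairs
    total, pairs = 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                total += d
                pairs += 1
    if pairs < n * (n - 1):
        logger.info("GD: %d unreachable ordered pairs excluded",
                    n * (n - 1) - pairs)
    m.GD = total / pairs if pairs else np.nan
    if L:
        comms = nx.community.greedy_modularity_communities(g)
        m.partition = [frozenset(c) for c in comms]
        m.modularity = nx.community.modularity(g, m.partition)
    else:
        m.partition = [frozenset([v]) for v in g.nodes]
        m.modularity = np.nan
    m.n_modules = sum(1 for c in m.partition if len(c) >= 2)
    signs = nx.get_edge_attributes(g, "sign")
    m.n_pos_links = sum(1 for s in signs.values() if s == "+")
    m.n_neg_links = L - m.n_pos_links
    return m


def robustness(net: CoNetwork, remove_fraction: float = 0.5,
               reps: int = 100, seed: int = 1) -> float:
    """Mean fraction of surviving nodes keeping >= 1 edge after removal.

    Each repetition removes floor(remove_fraction * N) uniformly chosen
    nodes; deterministic given ``seed``.
    """
    if not 0 < remove_fraction < 1:
        raise ValidationError("remove_fraction must be in (0, 1)")
    g = net.graph
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 2:
        raise ValidationError("robustness needs at least 2 nodes")
    n_remove = int(remove_fraction * n)
    rng = np.random.default_rng(seed)
    scores = np.empty(reps)
    for r in range(reps):
        removed = set(rng.choice(n, size=n_remove, replace=False))
        survivors = [v for i, v in enumerate(nodes) if i not in removed]
        if not survivors:
            scores[r] = 0.0
            continue
        surv = set(survivors)
        alive = sum(
            1 for v in survivors if any(u in surv for u in g.neighbors(v))
        )
        scores[r] = alive / len(survivors)
    return float(scores.mean())


def global_efficiency(g: nx.Graph) -> float:
    """E = mean over ordered pairs of 1/d(u,v), with 1/inf = 0."""
    return nx.global_efficiency(g)


def vulnerability(net: CoNetwork) -> float:
    """Max over nodes of (E - E_without_node)/E, E the global efficiency."""
    g = net.graph
    e = global_efficiency(g)
    if e <= 0:
        logger.warning("vulnerability undefined: zero global efficiency")
        return np.nan
    worst = -np.inf
    for v in g.nodes:
        h = g.copy()
        h.remove_node(v)
        ev = global_efficiency(h) if h.number_of_nodes() > 1 else 0.0
        worst = max(worst, (e - ev) / e)
    return float(worst)


# ---------------------------------------------------------------------------
# Node roles (Zi-Pi)

def node_roles(net: CoNetwork, partition: list[frozenset]) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi = (k_within - module mean)/module sd (sd 0 -> 0); Pi = 1 - sum over
    modules of (k_in_module/k)^2 (k = 0 -> 0). Roles: network hub
    (Zi > 2.5, Pi > 0.62), module hub (Zi > 2.5), connector (Pi > 0.62),
    else peripheral; keystone = non-peripheral.
    """
    g = net.graph
    covered = set().union(*partition) if partition else set()
    if covered != set(g.nodes):
        raise ValidationError("partition does not cover the node set")
    module_of = {v: i for i, c in enumerate(partition) for v in c}
    k_within = {}
    k_by_module = {}
    for v in g.nodes:
        counts: dict[int, int] = {}
        for u in g.neighbors(v):
            counts[module_of[u]] = counts.get(module_of[u], 0) + 1
        k_by_module[v] = counts
        k_within[v] = counts.get(module_of[v], 0)
    rows = []
    for i, comm in enumerate(partition):
        kw = np.array([k_within[v] for v in comm], dtype=float)
        mean, sd = kw.mean(), kw.std(ddof=0)
        for v in comm:
            zi = (k_within[v] - mean) / sd if sd > 0 else 0.0
            k = g.degree(v)
            pi = 1.0 - sum((c / k) ** 2 for c in k_by_module[v].values()) if k else 0.0
            if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
                role = "network hub"
            elif zi > ZI_THRESHOLD:
                role = "module hub"
            elif pi > PI_THRESHOLD:
                role = "connector"
            else:
                role = "peripheral"
            rows.append((v, i, zi, pi, role, role != "peripheral"))
    df = pd.DataFrame(
        rows, columns=["node", "module", "Zi", "Pi", "role", "keystone"]
    ).set_index("node")
    return df.loc[list(g.nodes)]


def network_summary(
    table: pd.DataFrame,
    rho_threshold: float = DEFAULT_RHO,
    alpha: float = DEFAULT_ALPHA,
    min_prevalence: int | None = None,
    remove_fraction: float = 0.5,
    reps: int = 100,
    seed: int = 1,
) -> tuple[CoNetwork, NetworkMetrics, pd.DataFrame]:
    """Build the network and compute every statistic in one pass."""
    net = build_network(table, rho_threshold, alpha, min_prevalence)
    metrics = topology(net)
    metrics.robustness = robustness(net, remove_fraction, reps, seed)
    metrics.vulnerability = vulnerability(net)
    roles = node_roles(net, metrics.partition)
    metrics.n_keystone = int(roles["keystone"].sum())
    return net, metrics, roles


def edge_list(net: CoNetwork) -> pd.DataFrame:
    """Edge list (node1, node2, rho, sign) for writing as TSV."""
    rows = [
        (u, v, d["rho"], d["sign"]) for u, v, d in net.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node1", "node2", "rho", "sign"])
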