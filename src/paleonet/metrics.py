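"""Topological metrics of co-occurrence networks.

Four whole-network descriptors are computed on the unweighted, unsigned
topology:

* connectance — realized fraction of possible undirected links,
  ``L / (S(S-1)/2)``;
* modularity Q of the best partition found by divisive edge-betweenness
  (Girvan–Newman) community detection, with resolution gamma (default 1);
* mean degree centrality ``2L / S``;
* skewness of the degree distribution, third central moment over
  ``(S-1) * sigma^3`` with sigma the sample standard deviation.

The divisive dendrogram is computed deterministically: at every step the
edge with the highest betweenness is removed, ties broken by lexicographic
edge order, and betweenness is recomputed after each removal.  The
returned partition is the dendrogram cut with maximal modularity; ties go
to the cut with fewer communities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._errors import UsageError
from .network import CoNetwork

logger = logging.getLogger(__name__)

METRIC_NAMES = ("connectance", "modularity", "mean_degree", "skewness")


def _as_graph(net) -> nx.Graph:
    if isinstance(net, CoNetwork):
        return net.graph
    if isinstance(net, nx.Graph):
        return net
    raise UsageError(f"expected a CoNetwork or networkx Graph, got {type(net)}")


@dataclass
class Partition:
    """Community assignment: frozensets of nodes covering the graph."""

    communities: list[frozenset]
    gamma: float = 1.0

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def labels(self) -> dict:
        return {v: i for i, c in enumerate(self.communities) for v in c}


@dataclass
class NetworkMetrics:
    """One row of the per-network summary table."""

    S: int
    L: int
    connectance: float | None = None
    modularity: float | None = None
    mean_degree: float | None = None
    skewness: float | None = None
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "S": self.S, "L": self.L,
            "connectance": self.connectance,
            "modularity": self.modularity,
            "mean_degree": self.mean_degree,
            "skewness": self.skewness,
        }


def connectance(net) -> float:
    """L / (S(S-1)/2): realized over possible undirected links."""
    g = _as_graph(net)
    s = g.number_of_nodes()
    if s < 2:
        raise UsageError("connectance needs at least 2 nodes")
    return g.number_of_edges() / (s * (s - 1) / 2.0)


def mean_degree(net) -> float:
    """Average number of links per node, 2L/S."""
    g = _as_graph(net)
    s = g.number_of_nodes()
    if s < 1:
        raise UsageError("mean degree of an empty node set is undefined")
    return 2.0 * g.number_of_edges() / s


def degree_skewness(net_or_degrees, method: str = "sample") -> float:
    """Skewness of the degree distribution.

    ``method="sample"`` (default) divides the third central moment by
    ``(S-1) * sigma^3`` with sigma the sample (ddof=1) standard deviation.
    ``method="moment"`` is the biased moment-ratio ``m3 / m2^(3/2)`` used
    by some network packages; both are exposed because they disagree for
    small S.  A degenerate (regular-graph) distribution returns 0.
    """
    if isinstance(net_or_degrees, (CoNetwork, nx.Graph)):
        g = _as_graph(net_or_degrees)
        x = np.array([d for _, d in g.degree()], dtype=float)
    else:
        x = np.asarray(net_or_degrees, dtype=float)
    s = len(x)
    if s < 3:
        raise UsageError("skewness needs at least 3 nodes")
    xbar = x.mean()
    dev = x - xbar
    if np.allclose(dev, 0.0):
        logger.debug("degenerate degree distribution (regular graph): skewness 0")
        return 0.0
    if method == "sample":
        sigma = x.std(ddof=1)
        return float((dev ** 3).sum() / ((s - 1) * sigma ** 3))
    if method == "moment":
        m2 = (dev ** 2).mean()
        m3 = (dev ** 3).mean()
        return float(m3 / m2 ** 1.5)
    raise UsageError(f"unknown skewness method {method!r}")


def modularity(net, partition: Partition | list, gamma: float = 1.0) -> float:
    """Newman modularity of a partition.

    ``Q = (1/2L) * sum_ij (A_ij - gamma * k_i k_j / 2L) * delta(c_i, c_j)``
    over ordered node pairs, equivalently
    ``sum_c (L_c / L - gamma * (d_c / 2L)^2)`` with L_c the intra-community
    edge count and d_c the community degree sum.
    """
    g = _as_graph(net)
    L = g.number_of_edges()
    if L == 0:
        raise UsageError("modularity is undefined for an edgeless graph")
    comms = partition.communities if isinstance(partition, Partition) else [
        frozenset(c) for c in partition
    ]
    covered = set().union(*comms) if comms else set()
    if covered != set(g.nodes) or sum(len(c) for c in comms) != g.number_of_nodes():
        raise UsageError("partition must cover every node exactly once")
    q = 0.0
    for c in comms:
        lc = sum(1 for u, v in g.edges(c) if u in c and v in c)
        dc = sum(d for _, d in g.degree(c))
        q += lc / L - gamma * (dc / (2.0 * L)) ** 2
    return float(q)


def _components(g: nx.Graph) -> list[frozenset]:
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: sorted(map(str, c)))


def girvan_newman_cuts(net) -> list[list[frozenset]]:
    """Full divisive dendrogram: the sequence of component partitions.

    Starting from the connected components of the graph, the edge with
    maximal edge betweenness is removed repeatedly (betweenness recomputed
    after every removal, ties broken lexicographically); every time a
    component splits, the new partition is appended.  The last partition is
    all singletons.
    """
    g = _as_graph(net).copy()
    cuts = [_components(g)]
    while g.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(g)
        best = max(eb.values())
        tol = 1e-9 * max(1.0, abs(best))
        cands = [e for e, v in eb.items() if v >= best - tol]
        edge = min(tuple(sorted(e, key=str)) for e in cands)
        g.remove_edge(*edge)
        comps = _components(g)
        if len(comps) > len(cuts[-1]):
            cuts.append(comps)
    return cuts


def girvan_newman(net, gamma: float = 1.0) -> Partition:
    """Partition at the maximum-modularity cut of the divisive dendrogram.

    Ties in Q are broken toward fewer communities.  An edgeless graph
    yields the all-singletons partition.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise UsageError("cannot partition an empty graph")
    if g.number_of_edges() == 0:
        return Partition([frozenset([v]) for v in sorted(g.nodes, key=str)], gamma)
    cuts = girvan_newman_cuts(g)
    best_q, best_cut = -math.inf, None
    for cut in cuts:  # increasing community count: first max wins ties
        q = modularity(g, cut, gamma=gamma)
        if q > best_q + 1e-12:
            best_q, best_cut = q, cut
    return Partition(best_cut, gamma)


def network_summary(
    net, gamma: float = 1.0, metrics=METRIC_NAMES
) -> NetworkMetrics:
    """Assemble S, L and the requested metrics for one network.

    Metrics not requested are left as None.  Degenerate cases are flagged
    rather than fatal: an edgeless graph has no modularity, a regular
    graph has skewness 0.
    """
    g = _as_graph(net)
    s, l = g.number_of_nodes(), g.number_of_edges()
    out = NetworkMetrics(S=s, L=l)
    if "connectance" in metrics:
        out.connectance = connectance(g) if s >= 2 else None
    if "mean_degree" in metrics:
        out.mean_degree = mean_degree(g)
    if "skewness" in metrics:
        degs = np.array([d for _, d in g.degree()], dtype=float)
        if s >= 3 and degs.std(ddof=1) > 0:
            out.skewness = degree_skewness(g)
        else:
            out.skewness = 0.0
            out.flags.append("skewness_degenerate")
    if "modularity" in metrics:
        if l == 0:
            out.modularity = None
            out.flags.append("modularity_undefined")
        else:
            part = girvan_newman(g, gamma=gamma)
            out.modularity = modularity(g, part, gamma=gamma)
    return out


def metrics_table(rows: dict) -> pd.DataFrame:
    """Tabulate ``{label: NetworkMetrics}`` in the standard column layout.

    Values are unrounded; ``round_metrics_table`` applies the report
    precision (3 decimals for connectance, 2 elsewhere).
    """
    recs = []
    for label, m in rows.items():
        rec = {"network": "/".join(map(str, label)) if isinstance(label, tuple) else label}
        rec.update(m.as_dict())
        recs.append(rec)
    return pd.DataFrame(recs)


def round_metrics_table(tab: pd.DataFrame) -> pd.DataFrame:
    out = tab.copy()
    if "connectance" in out:
        out["connectance"] = pd.to_numeric(out["connectance"],
                                           errors="coerce").round(3)
    for col in ("modularity", "mean_degree", "skewness"):
        if col in out:
            out[col] = pd.to_numeric(out[col], errors="coerce").round(2)
    return out
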