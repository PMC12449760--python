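"""Co-occurrence network construction from abundance correlations.

A network is built per sample group (impact class × time slice, or core
zone): Spearman rank correlations between all taxon pairs on the
Hellinger-transformed abundances, then an undirected simple graph keeping
the pairs whose correlation is significant at the chosen level.  Edges are
stored signed and weighted (rho), but the topology used by the network
metrics is unweighted and unsigned — a significant negative association is
a link like any other.

Because Spearman is rank-based it is invariant to any strictly monotone
transform of a column, so the Hellinger step never alters rho; it is kept
for consistency with the multivariate steps of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._errors import UsageError
from .assemblage import AbundanceMatrix, CountMatrix

#: Minimum number of samples for a correlation network.
MIN_SAMPLES = 5


@dataclass
class CorrelationResult:
    """All-pairs Spearman correlations with p-values.

    ``mask`` flags undefined pairs (at least one zero-variance taxon);
    masked entries hold NaN in both ``rho`` and ``p``.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    n_obs: int
    mask: pd.DataFrame

    @property
    def taxa(self) -> list:
        return list(self.rho.columns)


@dataclass
class CoNetwork:
    """Undirected signed co-occurrence graph on taxon nodes.

    ``S`` is the node count (all taxa present in the group, isolated nodes
    included), ``L`` the number of significant edges.  Edge attributes:
    ``rho`` (Spearman coefficient), ``sign`` (+1/-1).
    """

    graph: nx.Graph
    alpha: float | None = None
    label: str | None = None

    @property
    def S(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def L(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> pd.DataFrame:
        nodes = list(self.graph.nodes)
        a = nx.to_numpy_array(self.graph, nodelist=nodes, weight=None)
        return pd.DataFrame(a.astype(int), index=nodes, columns=nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": u, "taxon_b": v,
             "rho": d.get("rho", np.nan),
             "p": d.get("p", np.nan),
             "sign": d.get("sign", 1)}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p", "sign"])


def spearman_matrix(am: AbundanceMatrix) -> CorrelationResult:
    """Spearman rho and p for every taxon pair of a Hellinger matrix.

    Ranks use average-rank tie handling; p-values come from the
    t-approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees of
    freedom, with p = 0 for |rho| = 1.  Taxa with zero variance across the
    samples are masked (no defined correlation).
    """
    if am.transform != "hellinger":
        raise UsageError("spearman_matrix expects a Hellinger-transformed matrix")
    x = am.values.to_numpy(dtype=float)
    n, k = x.shape
    if n < MIN_SAMPLES:
        raise UsageError(
            f"need at least {MIN_SAMPLES} samples for a correlation network, got {n}"
        )
    taxa = am.taxa
    constant = np.array([np.all(col == col[0]) for col in x.T])

    ranks = np.apply_along_axis(stats.rankdata, 0, x)  # average ranks
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    if k == 1:
        rho = np.array([[1.0]])
    rho = np.clip(rho, -1.0, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0

    mask = constant[:, None] | constant[None, :]
    rho[mask] = np.nan
    p[mask] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    np.fill_diagonal(p, np.where(constant, np.nan, 0.0))

    return CorrelationResult(
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        p=pd.DataFrame(p, index=taxa, columns=taxa),
        n_obs=n,
        mask=pd.DataFrame(mask, index=taxa, columns=taxa),
    )


def build_network(
    cr: CorrelationResult,
    alpha: float,
    present_taxa=None,
    label: str | None = None,
) -> CoNetwork:
    """Threshold a correlation matrix into a co-occurrence network.

    Nodes are ``present_taxa`` (default: all taxa of the correlation
    result), including taxa that end up with no significant association.
    Edges are the unmasked pairs with p < alpha; the sign of rho is kept as
    an edge attribute.
    """
    if not 0.0 < alpha < 1.0:
        raise UsageError(f"alpha must be in (0, 1), got {alpha}")
    if present_taxa is None:
        present_taxa = cr.taxa
    present_taxa = list(present_taxa)
    if not present_taxa:
        raise UsageError("present_taxa is empty")
    unknown = set(present_taxa) - set(cr.taxa)
    if unknown:
        raise UsageError(f"taxa not in the correlation result: {sorted(unknown)}")

    g = nx.Graph()
    g.add_nodes_from(present_taxa)
    pres = set(present_taxa)
    for i, a in enumerate(cr.taxa):
        if a not in pres:
            continue
        for b in cr.taxa[i + 1:]:
            if b not in pres or bool(cr.mask.loc[a, b]):
                continue
            pv = float(cr.p.loc[a, b])
            if pv < alpha:
                r = float(cr.rho.loc[a, b])
                g.add_edge(a, b, rho=r, p=pv, sign=1 if r >= 0 else -1)
    return CoNetwork(graph=g, alpha=alpha, label=label)


def network_from_counts(
    cm: CountMatrix, alpha: float, label: str | None = None
) -> CoNetwork:
    """Counts → relative abundance → Hellinger → Spearman → thresholded graph.

    Node set = taxa with a nonzero count in at least one sample of the
    group (presence-based inclusion; isolated nodes kept).
    """
    from .assemblage import hellinger, to_relative_abundance

    present = [t for t in cm.taxa if cm.counts[t].sum() > 0]
    if not present:
        raise UsageError("no taxon is present in this group")
    sub = CountMatrix(cm.counts[present].copy(), cm.meta.copy())
    cr = spearman_matrix(hellinger(to_relative_abundance(sub)))
    return build_network(cr, alpha=alpha, present_taxa=present, label=label)


def subset_by_group(cm: CountMatrix, keys) -> dict[tuple, CountMatrix]:
    """Split a count matrix into one matrix per combination of meta keys.

    ``keys`` is a metadata column name or a sequence of them (e.g.
    ``("group", "time_slice")`` for the top-bottom design, ``"zone"`` for a
    zoned core).  Combinations with no samples are skipped.  Returned keys
    are tuples in the order given.
    """
    if isinstance(keys, str):
        keys = (keys,)
    keys = tuple(keys)
    for k in keys:
        if k not in cm.meta.columns:
            raise UsageError(f"metadata column {k!r} not present")
    levels = [list(pd.unique(cm.meta[k])) for k in keys]
    out: dict[tuple, CountMatrix] = {}
    for combo in product(*levels):
        sel = np.ones(cm.n_samples, dtype=bool)
        for k, v in zip(keys, combo):
            sel &= (cm.meta[k] == v).to_numpy()
        if not sel.any():
            continue
        out[combo] = CountMatrix(
            cm.counts.loc[sel].copy(), cm.meta.loc[sel].copy()
        )
    return out


def write_edge_list(net: CoNetwork, path) -> None:
    """Write the network as a (taxon_a, taxon_b, rho, p, sign) table."""
    net.edge_table().to_csv(path, index=False)


def write_graphml(net: CoNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
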