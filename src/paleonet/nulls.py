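"""Constrained random-graph ensembles and significance tests.

Only one co-occurrence network can be built per sample group, so metric
differences between groups are tested against Erdős–Rényi G(n, p)
ensembles matched to each observed network: n = S (the observed node
count) and p = the observed connectance.  The degree sequence is *not*
preserved — the null only fixes size and density, so metric contrasts
partly reflect the (S, p) differences by construction.

Per metric, replicate values are compared across groups with a one-way
ANOVA followed by Tukey's HSD; p-values are Benjamini–Hochberg adjusted
within the family of tests belonging to one impact class or one lake
(four network metrics plus the rarefied Shannon comparison).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import UsageError
from .metrics import METRIC_NAMES, network_summary
from .network import CoNetwork

logger = logging.getLogger(__name__)

DEFAULT_N_REPS = 30


def erdos_renyi(S: int, p: float, seed) -> CoNetwork:
    """One G(n, p) draw: each of the S(S-1)/2 unordered pairs is an edge
    independently with probability p."""
    if S < 2:
        raise UsageError("need at least 2 nodes")
    if not 0.0 <= p <= 1.0:
        raise UsageError(f"edge probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(S))
    iu, ju = np.triu_indices(S, k=1)
    hit = rng.random(len(iu)) < p
    g.add_edges_from(zip(iu[hit].tolist(), ju[hit].tolist()))
    return CoNetwork(graph=g, label=f"ER(S={S}, p={p:g})")


@dataclass
class NullEnsemble:
    """Replicate-by-metric table of metrics from matched random graphs."""

    group: str
    S: int
    p: float
    replicates: pd.DataFrame
    seed: int | None = None

    @property
    def n_reps(self) -> int:
        return len(self.replicates)


def null_ensemble(
    S: int,
    p: float,
    n_reps: int = DEFAULT_N_REPS,
    seed=None,
    group: str = "",
    gamma: float = 1.0,
    metrics=METRIC_NAMES,
) -> NullEnsemble:
    """Generate ``n_reps`` G(S, p) graphs and summarise each.

    Replicates come from independent child streams of ``seed``.  An
    edgeless replicate has undefined modularity, recorded as missing.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    rows = []
    for child in children:
        net = erdos_renyi(S, p, seed=child)
        m = network_summary(net, gamma=gamma, metrics=metrics)
        rows.append(m.as_dict())
    tab = pd.DataFrame(rows)
    return NullEnsemble(group=group, S=S, p=p, replicates=tab, seed=seed)


@dataclass
class TestResult:
    """One metric's ANOVA + Tukey comparison across groups."""

    metric: str
    F: float
    p_raw: float
    tukey_p: dict[tuple[str, str], float]
    p_fdr: float | None = None
    flags: list = field(default_factory=list)
    n_dropped: int = 0


def anova_tukey(groups: dict[str, np.ndarray], metric: str = "") -> TestResult:
    """One-way fixed-effects ANOVA with Tukey HSD pairwise comparisons.

    Missing replicate values (e.g. modularity of edgeless graphs) are
    dropped per group and the count logged.  A zero pooled variance is
    flagged degenerate with F = 0, p = 1.
    """
    if len(groups) < 2:
        raise UsageError("need at least 2 groups")
    clean, dropped = {}, 0
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        dropped += int(np.isnan(v).sum())
        v = v[~np.isnan(v)]
        if len(v) < 2:
            raise UsageError(f"group {name!r} has fewer than 2 usable values")
        clean[name] = v
    if dropped:
        logger.info("anova_tukey[%s]: dropped %d missing values", metric, dropped)
    names = list(clean)
    arrays = [clean[n] for n in names]
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return TestResult(
            metric=metric, F=0.0, p_raw=1.0,
            tukey_p={pair: 1.0 for pair in combinations(names, 2)},
            flags=["degenerate_zero_variance"], n_dropped=dropped,
        )
    F, p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    tukey = {
        (names[i], names[j]): float(res.pvalue[i, j])
        for i, j in combinations(range(len(names)), 2)
    }
    return TestResult(metric=metric, F=float(F), p_raw=float(p),
                      tukey_p=tukey, n_dropped=dropped)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment of a family of raw p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise UsageError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise UsageError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney–Wilcoxon test.

    Exact p for small samples without ties, normal approximation with tie
    correction otherwise.  Degenerate pooled data (all values equal)
    returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise UsageError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.allclose(pooled, pooled[0]):
        logger.info("mann_whitney: degenerate all-equal data, p = 1")
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    observed: dict[str, tuple[int, float]],
    n_reps: int = DEFAULT_N_REPS,
    seed=None,
    gamma: float = 1.0,
    metrics=METRIC_NAMES,
    extra_p: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Test metric shifts between groups via matched null ensembles.

    ``observed`` maps each group label to its observed (S, connectance).
    One G(S, p) ensemble is built per group; each metric is compared
    across groups by ANOVA + Tukey, and the family of raw omnibus
    p-values (the metrics, plus any ``extra_p`` such as the rarefied
    Shannon Mann-Whitney p) is BH-adjusted together.

    Returns a tidy table with one row per metric: F, raw p, pairwise
    Tukey p per group pair, FDR-adjusted p, and the ensemble means per
    group (for reading the direction of a shift).
    """
    if len(observed) < 2:
        raise UsageError("need at least 2 groups to compare")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(observed))
    ensembles = {
        g: null_ensemble(S, p, n_reps=n_reps, seed=child, group=str(g),
                         gamma=gamma, metrics=metrics)
        for (g, (S, p)), child in zip(observed.items(), children)
    }
    results = []
    for metric in metrics:
        groups = {g: e.replicates[metric].to_numpy() for g, e in ensembles.items()}
        results.append(anova_tukey(groups, metric=metric))

    family = [r.p_raw for r in results]
    labels = [r.metric for r in results]
    if extra_p:
        for name, pv in extra_p.items():
            family.append(pv)
            labels.append(name)
    adjusted = fdr_adjust(family)
    adj_map = dict(zip(labels, adjusted))
    for r in results:
        r.p_fdr = float(adj_map[r.metric])

    rows = []
    for r in results:
        row = {
            "metric": r.metric, "F": r.F, "p_raw": r.p_raw,
            "p_fdr": r.p_fdr, "stars": significance_stars(r.p_fdr),
        }
        for (a, b), pv in r.tukey_p.items():
            row[f"tukey_p[{a}|{b}]"] = pv
        for g, e in ensembles.items():
            row[f"mean[{g}]"] = float(np.nanmean(e.replicates[r.metric]))
        rows.append(row)
    tab = pd.DataFrame(rows)
    if extra_p:
        for name, pv in extra_p.items():
            tab = pd.concat(
                [tab, pd.DataFrame([{
                    "metric": name, "p_raw": pv,
                    "p_fdr": float(adj_map[name]),
                    "stars": significance_stars(float(adj_map[name])),
                }])],
                ignore_index=True,
            )
    return tab


def significance_stars(p: float) -> str:
    """The conventional asterisk coding: * <0.05, ** <0.01, *** <0.001,
    **** <0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return ""
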