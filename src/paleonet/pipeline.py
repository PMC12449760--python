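"""End-to-end orchestration of the two study designs.

``run_topbottom`` compares modern (core-top) and pre-industrial
(core-bottom) assemblages across many lakes grouped by human-impact
class: one co-occurrence network per class x slice at alpha = 0.01,
null-ensemble tests of each metric between slices within a class, and a
rarefied-Shannon Mann-Whitney comparison, all BH-adjusted within the
class family.

``run_fullcore`` analyses one dated core: truncate to the configured
earliest age, delineate zones by CONISS + broken stick (minimum five
intervals per zone), build one network per zone at alpha = 0.05, and run
the same null-ensemble and diversity comparisons across zones.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._errors import ConfigError, UsageError
from .assemblage import (
    CountMatrix, bin_intervals, classify_hii, hellinger, rarefy, shannon,
    to_relative_abundance,
)
from .metrics import METRIC_NAMES, metrics_table, network_summary, round_metrics_table
from .network import CoNetwork, network_from_counts, subset_by_group
from .nulls import compare_groups, mann_whitney
from .zonation import assign_zones, bray_curtis, broken_stick, coniss

logger = logging.getLogger(__name__)

ALPHA_TOPBOTTOM = 0.01
ALPHA_FULLCORE = 0.05


@dataclass
class RunConfig:
    """Knobs of a pipeline run; defaults follow the study conventions."""

    mode: str = "topbottom"            # topbottom | fullcore
    alpha: float | None = None         # default 0.01 topbottom, 0.05 fullcore
    rarefaction_depth: int | None = None  # default: minimum sample total
    min_intervals: int = 5
    n_reps: int = 30
    gamma: float = 1.0
    seed: int = 0
    truncation_age: float = 1750.0
    min_group_samples: int = 5
    metrics: tuple = METRIC_NAMES
    bins: list | None = None           # optional pooling of recent intervals
    zonation_on_hellinger: bool = True

    def resolved_alpha(self) -> float:
        if self.alpha is not None:
            if not 0 < self.alpha < 1:
                raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
            return self.alpha
        return ALPHA_TOPBOTTOM if self.mode == "topbottom" else ALPHA_FULLCORE


@dataclass
class RunReport:
    """Everything a run produces, with provenance."""

    metrics: pd.DataFrame
    networks: dict[object, CoNetwork]
    tests: pd.DataFrame
    diversity: pd.DataFrame
    zones: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        round_metrics_table(self.metrics).to_csv(out / "metrics.csv", index=False)
        self.tests.to_csv(out / "tests.csv", index=False)
        self.diversity.to_csv(out / "diversity.csv", index=False)
        if self.zones is not None:
            self.zones.to_csv(out / "zones.csv", index=False)
        for label, net in self.networks.items():
            tag = "_".join(map(str, label)) if isinstance(label, tuple) else str(label)
            net.edge_table().to_csv(out / f"edges_{tag}.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.provenance, fh, indent=1, default=str)


def _provenance(cfg: RunConfig, extra: dict | None = None) -> dict:
    block = {"software": f"paleonet {__version__}", "config": asdict(cfg)}
    if extra:
        block.update(extra)
    return block


def _resolve_depth(cm: CountMatrix, cfg: RunConfig) -> int:
    if cfg.rarefaction_depth is not None:
        return int(cfg.rarefaction_depth)
    return int(cm.row_totals().min())


def run_topbottom(cm: CountMatrix, cfg: RunConfig | None = None) -> RunReport:
    """Landscape top-bottom comparison across human-impact classes."""
    cfg = cfg or RunConfig(mode="topbottom")
    alpha = cfg.resolved_alpha()
    root = np.random.SeedSequence(cfg.seed)
    s_rarefy, s_nulls = root.spawn(2)

    meta = cm.meta.copy()
    if "group" not in meta.columns:
        if "hii" not in meta.columns:
            raise UsageError("need either a group label or an hii column")
        meta["group"] = [classify_hii(h) for h in meta["hii"]]
    if "time_slice" not in meta.columns:
        raise UsageError("top-bottom mode needs a time_slice column")
    cm = CountMatrix(cm.counts.copy(), meta)

    subsets = subset_by_group(cm, ("group", "time_slice"))
    classes = sorted({g for g, _ in subsets})
    networks: dict[tuple, CoNetwork] = {}
    summaries: dict[tuple, object] = {}
    kept_classes = []
    for cls in classes:
        sizes = {sl: subsets[(cls, sl)].n_samples
                 for sl in ("top", "bottom") if (cls, sl) in subsets}
        if set(sizes) != {"top", "bottom"} or min(sizes.values()) < cfg.min_group_samples:
            logger.warning("class %r skipped (needs both slices with >= %d samples)",
                           cls, cfg.min_group_samples)
            continue
        kept_classes.append(cls)
        for sl in ("top", "bottom"):
            key = (cls, sl)
            networks[key] = network_from_counts(subsets[key], alpha=alpha,
                                                label=f"{cls}/{sl}")
            summaries[key] = network_summary(networks[key], gamma=cfg.gamma,
                                             metrics=cfg.metrics)

    depth = _resolve_depth(cm, cfg)
    rare = rarefy(cm, depth, seed=np.random.default_rng(s_rarefy))
    div = pd.DataFrame({
        "sample": rare.samples,
        "group": rare.meta["group"].to_numpy(),
        "time_slice": rare.meta["time_slice"].to_numpy(),
        "rarefaction_depth": depth,
        "shannon": [shannon(rare.counts.loc[s]) for s in rare.samples],
    })

    test_blocks = []
    null_children = s_nulls.spawn(max(len(kept_classes), 1))
    for cls, child in zip(kept_classes, null_children):
        obs = {
            sl: (summaries[(cls, sl)].S, summaries[(cls, sl)].connectance)
            for sl in ("top", "bottom")
        }
        sub = div[div["group"] == cls]
        x = sub.loc[sub["time_slice"] == "top", "shannon"].to_numpy()
        y = sub.loc[sub["time_slice"] == "bottom", "shannon"].to_numpy()
        extra = {}
        if len(x) and len(y):
            _, p_mw = mann_whitney(x, y)
            extra["shannon"] = p_mw
        tab = compare_groups(obs, n_reps=cfg.n_reps,
                             seed=int(child.generate_state(1)[0] % (2 ** 31)),
                             gamma=cfg.gamma, metrics=cfg.metrics, extra_p=extra)
        tab.insert(0, "class", cls)
        test_blocks.append(tab)
    tests = pd.concat(test_blocks, ignore_index=True) if test_blocks else pd.DataFrame()

    return RunReport(
        metrics=metrics_table(summaries),
        networks=networks,
        tests=tests,
        diversity=div,
        provenance=_provenance(cfg, {
            "alpha": alpha, "rarefaction_depth": depth,
            "classes": kept_classes,
        }),
    )


def run_fullcore(cm: CountMatrix, cfg: RunConfig | None = None) -> RunReport:
    """Single-core zonal analysis: zonation, per-zone networks, tests."""
    cfg = cfg or RunConfig(mode="fullcore")
    if cfg.mode != "fullcore":
        cfg = RunConfig(**{**asdict(cfg), "mode": "fullcore"})
    alpha = cfg.resolved_alpha()
    root = np.random.SeedSequence(cfg.seed)
    s_rarefy, s_nulls = root.spawn(2)

    if "age_ce" not in cm.meta.columns:
        raise UsageError("full-core mode needs an age_ce column")
    keep = cm.meta["age_ce"].to_numpy(dtype=float) >= cfg.truncation_age
    cm = CountMatrix(cm.counts.loc[keep].copy(), cm.meta.loc[keep].copy())
    if cm.n_samples < 2 * cfg.min_intervals:
        raise UsageError(
            f"record has {cm.n_samples} intervals after truncation; "
            f"cannot form two zones of {cfg.min_intervals}"
        )

    rel = to_relative_abundance(cm)
    hel = hellinger(rel)
    dm = bray_curtis(hel if cfg.zonation_on_hellinger else rel)
    tree = coniss(dm)
    n_sig = broken_stick(tree)
    ages = cm.meta["age_ce"].to_numpy(dtype=float)
    za = assign_zones(tree, n_sig, min_intervals=cfg.min_intervals, ages=ages)
    zones_tab = pd.DataFrame({
        "sample": cm.samples,
        "depth_cm": cm.meta.get("depth_cm", pd.Series(index=cm.counts.index)).to_numpy(),
        "age_ce": ages,
        "zone": za.labels,
    })
    zones_tab.attrs["median_age"] = za.median_age

    meta = cm.meta.copy()
    meta["zone"] = za.labels
    cm = CountMatrix(cm.counts.copy(), meta)

    networks: dict[tuple, CoNetwork] = {}
    summaries: dict[tuple, object] = {}
    for (zone,), sub in subset_by_group(cm, ("zone",)).items():
        networks[(f"zone{zone}",)] = network_from_counts(
            sub, alpha=alpha, label=f"zone{zone}")
        summaries[(f"zone{zone}",)] = network_summary(
            networks[(f"zone{zone}",)], gamma=cfg.gamma, metrics=cfg.metrics)
    mtab = metrics_table(summaries)
    mtab.insert(1, "median_year",
                [za.median_age.get(z, np.nan) for z in range(1, za.n_zones + 1)])

    binned = bin_intervals(cm, cfg.bins) if cfg.bins else cm
    depth = _resolve_depth(binned, cfg)
    rare = rarefy(binned, depth, seed=np.random.default_rng(s_rarefy))
    div = pd.DataFrame({
        "sample": rare.samples,
        "zone": rare.meta["zone"].to_numpy(),
        "rarefaction_depth": depth,
        "shannon": [shannon(rare.counts.loc[s]) for s in rare.samples],
    })

    tests = pd.DataFrame()
    if za.n_zones >= 2:
        obs = {
            f"zone{z}": (summaries[(f"zone{z}",)].S,
                         summaries[(f"zone{z}",)].connectance)
            for z in range(1, za.n_zones + 1)
        }
        first = div.loc[div["zone"] == 1, "shannon"].to_numpy()
        last = div.loc[div["zone"] == za.n_zones, "shannon"].to_numpy()
        extra = {}
        if len(first) and len(last):
            _, p_mw = mann_whitney(first, last)
            extra["shannon"] = p_mw
        tests = compare_groups(
            obs, n_reps=cfg.n_reps,
            seed=int(s_nulls.generate_state(1)[0] % (2 ** 31)),
            gamma=cfg.gamma, metrics=cfg.metrics, extra_p=extra,
        )
    else:
        logger.info("single zone: no between-zone comparison attempted")

    return RunReport(
        metrics=mtab,
        networks=networks,
        tests=tests,
        diversity=div,
        zones=zones_tab,
        provenance=_provenance(cfg, {
            "alpha": alpha, "rarefaction_depth": depth,
            "n_zones": int(za.n_zones),
            "zone_median_year": {str(k): v for k, v in za.median_age.items()},
        }),
    )
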