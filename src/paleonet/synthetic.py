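"""Synthetic assemblage generators with planted association structure.

Counts are produced by a Gaussian-copula-to-multinomial mechanism: a
latent vector z is drawn from a multivariate normal whose correlation
matrix Sigma is block-structured by taxon modules, taxon weights are
``w_i = exp(mu_i + s * z_i)``, the composition is ``w / sum(w)``, and the
observed counts are a multinomial draw at a per-sample total sampled
uniformly from the configured counting-effort range (default 100-600
individuals, the realistic identification effort for a subfossil sample).
Because the downstream association statistic is rank-based, only the
latent rank structure needs controlling; any monotone link would do.

The dominance profile defaults to a geometric series over taxa — a few
dominant taxa and a long tail of rare ones, as in Bosmina-dominated
cladoceran assemblages.  Negative associations are planted by negating a
taxon's latent loading within its module, which preserves positive
semi-definiteness of Sigma.

``generate_zoned_core`` adds a compositional change point: the
log-abundance means are offset for intervals deposited after the change,
and a linear age model spanning ~1750 CE to the present is attached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .assemblage import CountMatrix

#: Per-sample counting-effort range (individuals), matching the realistic
#: identification effort for subfossil samples.
DEFAULT_TOTAL_RANGE = (100, 600)


@dataclass
class SynthConfig:
    """Parameters of the assemblage generator.

    rho_w is the latent within-module correlation; negative_fraction the
    fraction of taxa per module whose loading is negated (planting
    negative pairs); dominance_ratio the geometric decay of mean
    log-abundance across taxa; latent_scale the log-abundance noise
    amplitude.
    """

    n_taxa: int = 45
    n_samples: int = 100
    n_modules: int = 9
    rho_w: float = 0.7
    negative_fraction: float = 0.1
    dominance_ratio: float = 0.95
    latent_scale: float = 0.95
    total_range: tuple[int, int] = DEFAULT_TOTAL_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_w < 1.0:
            raise ConfigError(f"rho_w must be in [0, 1), got {self.rho_w}")
        lo, hi = self.total_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid total-count range {self.total_range}")
        if self.n_modules < 1 or self.n_modules > self.n_taxa:
            raise ConfigError("n_modules must be in [1, n_taxa]")


@dataclass
class PlantedTruth:
    """Ground truth of a generated dataset.

    ``pairs`` lists the planted (i, j, sign) associations — every taxon
    pair whose latent correlation magnitude reaches the planting strength
    (rho_w).  ``change_point`` is the first interval index of the post-
    change regime in a zoned core, or None.
    """

    sigma: np.ndarray
    modules: np.ndarray
    pairs: list[tuple[int, int, int]]
    change_point: int | None = None
    taxa: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "sigma": self.sigma.tolist(),
            "modules": self.modules.tolist(),
            "pairs": [list(p) for p in self.pairs],
            "change_point": self.change_point,
            "taxa": list(self.taxa),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _build_sigma(cfg: SynthConfig, rng: np.random.Generator):
    """Block correlation matrix with planted sign flips."""
    # round-robin membership interleaves modules across the dominance
    # gradient; a module of co-varying dominant taxa would otherwise swing
    # the compositional denominator and induce spurious correlations
    modules = np.arange(cfg.n_taxa) % cfg.n_modules
    sigma = np.eye(cfg.n_taxa)
    for m in range(cfg.n_modules):
        idx = np.flatnonzero(modules == m)
        for a in idx:
            for b in idx:
                if a != b:
                    sigma[a, b] = cfg.rho_w
    # negate loadings of a few taxa per module: D Sigma D stays PSD
    signs = np.ones(cfg.n_taxa)
    for m in range(cfg.n_modules):
        idx = np.flatnonzero(modules == m)
        n_neg = int(round(cfg.negative_fraction * len(idx)))
        if n_neg and len(idx) > 1:
            flip = rng.choice(idx, size=min(n_neg, len(idx) - 1), replace=False)
            signs[flip] = -1.0
    sigma = sigma * np.outer(signs, signs)
    np.fill_diagonal(sigma, 1.0)
    try:
        chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(cfg.n_taxa))
    except np.linalg.LinAlgError:
        raise ConfigError(
            "planted correlation matrix is not positive semi-definite; "
            "lower rho_w or the negative fraction"
        ) from None
    return sigma, modules, chol


def _planted_pairs(sigma: np.ndarray, strength: float) -> list[tuple[int, int, int]]:
    pairs = []
    n = sigma.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if abs(sigma[i, j]) >= strength - 1e-12 and sigma[i, j] != 0.0:
                pairs.append((i, j, 1 if sigma[i, j] > 0 else -1))
    return pairs


def _draw_counts(cfg: SynthConfig, mu: np.ndarray, chol: np.ndarray,
                 rng: np.random.Generator, n_samples: int) -> np.ndarray:
    z = rng.standard_normal((n_samples, cfg.n_taxa)) @ chol.T
    w = np.exp(mu[None, :] + cfg.latent_scale * z)
    p = w / w.sum(axis=1, keepdims=True)
    lo, hi = cfg.total_range
    totals = rng.integers(lo, hi + 1, size=n_samples)
    counts = np.empty((n_samples, cfg.n_taxa), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng.multinomial(totals[i], p[i])
    return counts


def _dominance_mu(cfg: SynthConfig) -> np.ndarray:
    return np.arange(cfg.n_taxa) * np.log(cfg.dominance_ratio)


def generate_assemblage(cfg: SynthConfig) -> tuple[CountMatrix, PlantedTruth]:
    """One site-by-taxon count matrix with planted pairwise associations."""
    rng = np.random.default_rng(cfg.seed)
    sigma, modules, chol = _build_sigma(cfg, rng)
    mu = _dominance_mu(cfg)
    counts = _draw_counts(cfg, mu, chol, rng, cfg.n_samples)
    taxa = [f"taxon{j:02d}" for j in range(cfg.n_taxa)]
    samples = [f"site{i:03d}" for i in range(cfg.n_samples)]
    cm = CountMatrix(pd.DataFrame(counts, index=samples, columns=taxa))
    strength = cfg.rho_w if cfg.rho_w > 0 else 1.1  # rho_w=0 plants nothing
    truth = PlantedTruth(
        sigma=sigma, modules=modules,
        pairs=_planted_pairs(sigma, strength), taxa=taxa,
    )
    return cm, truth


def generate_zoned_core(
    cfg: SynthConfig,
    change_point: int,
    shift,
    age_top: float = 2017.0,
    age_bottom: float = 1750.0,
) -> tuple[CountMatrix, PlantedTruth]:
    """A depth-by-taxon core record with a compositional change point.

    Intervals are ordered stratigraphically from oldest (core bottom) to
    youngest (core top); ages increase linearly toward the top.  The mean
    log-abundance vector is offset by ``shift`` (per-taxon array, or a
    scalar applied with alternating sign to half the taxa) for every
    interval at position >= ``change_point``.  Both sides of the change
    must hold at least 5 intervals, the minimum zone size for a
    correlation network.
    """
    n = cfg.n_samples
    if not 1 < change_point < n:
        raise ConfigError(f"change_point must be inside (1, {n}), got {change_point}")
    if change_point < 5 or n - change_point < 5:
        raise ConfigError(
            "each side of the change point needs at least 5 intervals "
            f"(got {change_point} and {n - change_point})"
        )
    shift = np.asarray(shift, dtype=float)
    if shift.ndim == 0:
        vec = np.zeros(cfg.n_taxa)
        half = cfg.n_taxa // 2
        vec[:half] = float(shift) * np.where(np.arange(half) % 2 == 0, 1.0, -1.0)
        shift = vec
    if shift.shape != (cfg.n_taxa,):
        raise ConfigError(f"shift must have length n_taxa={cfg.n_taxa}")

    rng = np.random.default_rng(cfg.seed)
    sigma, modules, chol = _build_sigma(cfg, rng)
    mu = _dominance_mu(cfg)
    old = _draw_counts(cfg, mu, chol, rng, change_point)
    young = _draw_counts(cfg, mu + shift, chol, rng, n - change_point)
    counts = np.vstack([old, young])

    taxa = [f"taxon{j:02d}" for j in range(cfg.n_taxa)]
    samples = [f"int{i:02d}" for i in range(n)]
    ages = np.linspace(age_bottom, age_top, n)
    depths = 0.5 + np.arange(n)[::-1].astype(float)  # deepest first
    meta = pd.DataFrame(
        {"depth_cm": depths, "age_ce": ages, "time_slice": "none"}, index=samples
    )
    cm = CountMatrix(pd.DataFrame(counts, index=samples, columns=taxa), meta)
    strength = cfg.rho_w if cfg.rho_w > 0 else 1.1
    truth = PlantedTruth(
        sigma=sigma, modules=modules,
        pairs=_planted_pairs(sigma, strength),
        change_point=change_point, taxa=taxa,
    )
    return cm, truth


def generate_topbottom(
    cfg: SynthConfig,
    class_sizes: dict[str, int] | None = None,
    rho_by_group: dict[tuple[str, str], float] | None = None,
    seed: int | None = None,
) -> tuple[CountMatrix, dict[tuple[str, str], PlantedTruth]]:
    """A landscape top-bottom dataset: one modern and one pre-industrial
    sample per lake, lakes grouped by human-impact class.

    ``class_sizes`` defaults to the 43/39/19 low/moderate/high split of a
    ~100-lake survey.  ``rho_by_group`` overrides the within-module latent
    correlation per (class, slice) — e.g. a weakened value for
    ("high", "top") plants a modern-slice decorrelation.  Each
    (class, slice) group is generated independently.
    """
    if class_sizes is None:
        class_sizes = {"low": 43, "moderate": 39, "high": 19}
    rho_by_group = rho_by_group or {}
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    keys = [(c, s) for c in class_sizes for s in ("top", "bottom")]
    children = root.spawn(len(keys))

    blocks, metas, truths = [], [], {}
    hii_rep = {"low": 0.05, "moderate": 0.3, "high": 0.6}
    for (cls, sl), child in zip(keys, children):
        sub = replace(
            cfg,
            n_samples=class_sizes[cls],
            rho_w=rho_by_group.get((cls, sl), cfg.rho_w),
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
        )
        cm, truth = generate_assemblage(sub)
        ids = [f"{cls}_{sl}_{i:03d}" for i in range(sub.n_samples)]
        cm.counts.index = pd.Index(ids)
        blocks.append(cm.counts)
        metas.append(pd.DataFrame(
            {"group": cls, "time_slice": sl, "hii": hii_rep[cls]}, index=ids
        ))
        truths[(cls, sl)] = truth
    counts = pd.concat(blocks)
    meta = pd.concat(metas)
    return CountMatrix(counts, meta), truths
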