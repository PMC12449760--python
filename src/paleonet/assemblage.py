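"""Assemblage count matrices: I/O, compositional transforms, rarefaction,
Shannon diversity and human-impact classification.

The central container is :class:`CountMatrix` — a sample-by-taxon table of
non-negative integer counts (individuals identified per sample) together
with per-sample metadata (impact group, top/bottom time slice, core depth,
calibrated age, human impact index).  Downstream stages consume either the
raw counts (rarefaction, diversity) or a real-valued
:class:`AbundanceMatrix` carrying a transform tag (``relative`` or
``hellinger``).

Column names listed in :data:`RESERVED_META` are recognised as metadata in
input files; every other column is a taxon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import InputError, UsageError

logger = logging.getLogger(__name__)

#: Metadata columns recognised in count CSV/TSV files.  Everything else in
#: the header is treated as a taxon name.
RESERVED_META = ("group", "time_slice", "depth_cm", "age_ce", "hii")

#: Valid time-slice labels for the top-bottom study design.
TIME_SLICES = ("top", "bottom", "none")


@dataclass
class CountMatrix:
    """Sample-by-taxon counts plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, one column per taxon, integer
        counts of individuals.
    meta
        DataFrame indexed identically, columns a subset of
        :data:`RESERVED_META`.  May be empty.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.counts.index)
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise InputError(f"duplicate sample ids: {dup}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise InputError(f"duplicate taxon names: {dup}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise InputError("counts must be numeric")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise InputError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"taxon {self.counts.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise InputError(
                f"non-integral count at sample {self.counts.index[i]!r}, "
                f"taxon {self.counts.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        if not self.meta.index.equals(self.counts.index):
            raise InputError("meta index must match counts index")
        if "depth_cm" in self.meta:
            d = self.meta["depth_cm"].to_numpy(dtype=float)
            if len(d) > 1 and not (np.all(np.diff(d) > 0) or np.all(np.diff(d) < 0)):
                raise InputError("depths must be strictly ordered within a core")

    @property
    def samples(self) -> list:
        return list(self.counts.index)

    @property
    def taxa(self) -> list:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.meta.copy())


@dataclass
class AbundanceMatrix:
    """Real-valued sample-by-taxon matrix tagged with its transform state.

    ``transform`` is ``"relative"`` (rows sum to 1) or ``"hellinger"``
    (rows have unit sum of squares; the square root of relative
    abundances).  All-zero rows are permitted and flagged in
    ``empty_rows``.
    """

    values: pd.DataFrame
    transform: str
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    empty_rows: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.values.index)
        if self.transform not in ("relative", "hellinger"):
            raise UsageError(f"unknown transform tag {self.transform!r}")

    @property
    def taxa(self) -> list:
        return list(self.values.columns)

    @property
    def samples(self) -> list:
        return list(self.values.index)


def read_count_matrix(path, sep: str | None = None) -> CountMatrix:
    """Read a count matrix from CSV/TSV.

    The first column holds sample ids; the header row holds taxon names,
    except columns named in :data:`RESERVED_META` which are moved to the
    metadata table.  The delimiter is inferred unless given.
    """
    try:
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    except FileNotFoundError:
        raise InputError(f"no such file: {path}") from None
    meta_cols = [c for c in df.columns if c in RESERVED_META]
    meta = df[meta_cols].copy()
    body = df.drop(columns=meta_cols)
    for col in body.columns:
        bad = pd.to_numeric(body[col], errors="coerce").isna() & body[col].notna()
        if bad.any():
            row = body.index[bad.to_numpy().nonzero()[0][0]]
            raise InputError(
                f"non-numeric count at sample {row!r}, taxon {col!r}: "
                f"{body.loc[row, col]!r}"
            )
    body = body.apply(pd.to_numeric)
    if "time_slice" in meta:
        bad = ~meta["time_slice"].isin(TIME_SLICES)
        if bad.any():
            raise InputError(
                f"unknown time_slice label {meta['time_slice'][bad].iloc[0]!r}"
            )
    return CountMatrix(body, meta)


def write_count_matrix(cm: CountMatrix, path, sep: str = ",") -> None:
    """Write counts and metadata back to a single delimited file."""
    out = pd.concat([cm.meta, cm.counts], axis=1)
    out.to_csv(path, sep=sep, index_label="sample_id")


def to_relative_abundance(cm: CountMatrix) -> AbundanceMatrix:
    """Divide each row by its total.  All-zero rows stay zero and are flagged."""
    totals = cm.row_totals().to_numpy(dtype=float)
    if not np.any(totals > 0):
        raise UsageError("no sample has a positive total count")
    empty = [s for s, t in zip(cm.samples, totals) if t == 0]
    if empty:
        logger.warning("samples with zero total left as all-zero rows: %s", empty)
    safe = np.where(totals > 0, totals, 1.0)
    vals = cm.counts.to_numpy(dtype=float) / safe[:, None]
    return AbundanceMatrix(
        pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns),
        transform="relative",
        meta=cm.meta.copy(),
        empty_rows=empty,
    )


def hellinger(am: AbundanceMatrix) -> AbundanceMatrix:
    """Square root of relative abundances.

    Rows then have unit sum of squares, so Euclidean-type analyses become
    appropriate for compositional data.
    """
    if am.transform != "relative":
        raise UsageError(
            f"hellinger expects a relative-abundance matrix, got {am.transform!r}"
        )
    return AbundanceMatrix(
        np.sqrt(am.values),
        transform="hellinger",
        meta=am.meta.copy(),
        empty_rows=list(am.empty_rows),
    )


def rarefy(cm: CountMatrix, depth: int, seed: int | np.random.Generator) -> CountMatrix:
    """Rarefy every sample to exactly ``depth`` individuals.

    Each retained sample is a single without-replacement draw of ``depth``
    individuals from its counted individuals (multivariate hypergeometric).
    Samples whose total is below ``depth`` are dropped with a warning.
    """
    if depth < 1:
        raise UsageError("rarefaction depth must be >= 1")
    totals = cm.row_totals()
    keep = totals[totals >= depth].index
    if len(keep) == 0:
        raise UsageError(
            f"rarefaction depth {depth} exceeds every sample total "
            f"(max is {int(totals.max())})"
        )
    dropped = [s for s in cm.samples if s not in set(keep)]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) with total < %d: %s",
            len(dropped), depth, dropped,
        )
    rng = np.random.default_rng(seed)
    sub = cm.counts.loc[keep]
    out = np.empty_like(sub.to_numpy())
    for i, (_, row) in enumerate(sub.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    return CountMatrix(
        pd.DataFrame(out, index=sub.index, columns=sub.columns),
        cm.meta.loc[keep].copy(),
    )


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = −Σ p_i ln p_i of one count (or abundance) vector.

    Natural log by default; pass ``base`` to change units.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise UsageError("negative counts")
    total = x.sum()
    if total <= 0:
        raise UsageError("Shannon diversity undefined for an all-zero sample")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def bin_intervals(cm: CountMatrix, bins: list[list[int]]) -> CountMatrix:
    """Pool contiguous core intervals by summing counts.

    ``bins`` lists groups of positional row indices; each group must be a
    contiguous run, groups must be disjoint.  Intervals not mentioned are
    kept as singleton bins.  A pooled sample takes the midpoint of member
    ages and a depth range label spanning the members.
    """
    seen: set[int] = set()
    for b in bins:
        if sorted(b) != list(range(min(b), max(b) + 1)):
            raise UsageError(f"bin {b} is not contiguous")
        if seen & set(b):
            raise UsageError(f"bin {b} overlaps a previous bin")
        seen |= set(b)
        if max(b) >= cm.n_samples or min(b) < 0:
            raise UsageError(f"bin {b} out of range")
    full = list(bins) + [[i] for i in range(cm.n_samples) if i not in seen]
    full.sort(key=min)

    rows, ids, meta_rows = [], [], []
    for b in full:
        idx = sorted(b)
        rows.append(cm.counts.iloc[idx].sum(axis=0))
        members = [cm.samples[i] for i in idx]
        ids.append(members[0] if len(idx) == 1 else f"{members[0]}..{members[-1]}")
        m = cm.meta.iloc[idx]
        rec = {}
        for col in cm.meta.columns:
            v = m[col]
            if col == "age_ce":
                rec[col] = (float(v.min()) + float(v.max())) / 2.0
            elif col == "depth_cm":
                rec[col] = float(v.min()) if len(idx) == 1 else float(v.mean())
            else:
                rec[col] = v.iloc[0]
        meta_rows.append(rec)
    counts = pd.DataFrame(rows, index=ids)
    meta = pd.DataFrame(meta_rows, index=ids)
    return CountMatrix(counts, meta)


def classify_hii(hii: float) -> str:
    """Map a human impact index in [0, 1] to its class.

    ``low`` for hii <= 0.1, ``high`` for hii >= 0.5, ``moderate`` between.
    """
    if not 0.0 <= hii <= 1.0:
        raise InputError(f"human impact index {hii} outside [0, 1]")
    if hii <= 0.1:
        return "low"
    if hii >= 0.5:
        return "high"
    return "moderate"
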