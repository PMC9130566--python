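"""Standardized allele-frequency-difference (dAF) scan in sliding SNP windows.

For every SNP and every (anadromous, freshwater) pool pair within a lineage the
raw statistic is the absolute allele-frequency difference |f_fresh - f_anad|.
Each pair's values are standardized genome-wide — z = (d - mean_d) / sd_d with
the population (divide-by-n) standard deviation taken over all the lineage's
SNPs — and the per-SNP statistic is the mean of z over all pairs.  Windows of
``window`` consecutive SNPs (default 20), advanced every ``step`` SNPs
(default 10) along each scaffold, average that per-SNP statistic; only full
windows on the ``top_scaffolds`` longest scaffolds are scored.

Per-pair standardization removes pair-specific drift baselines before
averaging; a single pooled standardization over all pairs is available via
``standardize(..., pooled=True)`` but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .snps import SnpTable

__all__ = [
    "DeltaAFTable",
    "WindowStat",
    "WindowSet",
    "ZeroVarianceError",
    "pair_daf",
    "standardize",
    "window_scan",
    "select_top_scaffolds",
]


class ZeroVarianceError(ValueError):
    """A pool pair had zero genome-wide |dAF| variance; z is undefined."""


@dataclass
class DeltaAFTable:
    """Per-SNP raw and standardized |dAF| for one set of pool pairs.

    Rows are aligned with (and sorted like) the source :class:`SnpTable`.
    ``raw`` is (S, K) with K = n_anadromous x n_freshwater pairs; ``z`` and
    ``mean_z`` are filled by :func:`standardize`.
    """

    lineage: str
    scaffold: np.ndarray  # (S,)
    position: np.ndarray  # (S,)
    pairs: list[tuple[str, str]]  # (anadromous, freshwater) pool names
    raw: np.ndarray  # (S, K) in [0, 1]
    z: np.ndarray | None = None
    mean_z: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.position)

    def scaffold_segments(self) -> list[tuple[str, int, int]]:
        segs: list[tuple[str, int, int]] = []
        if self.n_sites == 0:
            return segs
        scafs = self.scaffold
        change = np.flatnonzero(scafs[1:] != scafs[:-1]) + 1
        bounds = np.concatenate(([0], change, [len(scafs)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            segs.append((str(scafs[lo]), int(lo), int(hi)))
        return segs


@dataclass(frozen=True)
class WindowStat:
    """One 20-SNP (by default) window with its genomic span and mean z."""

    scaffold: str
    snp_start_index: int  # 1-based index into the scaffold's SNP list
    n_snps: int
    span: tuple[int, int]  # (first SNP position, last SNP position), inclusive
    stat: float


class WindowSet:
    """A compact, array-backed sequence of :class:`WindowStat`.

    Behaves like an immutable sequence (len / indexing / iteration yield
    :class:`WindowStat` records) while keeping the statistics in flat numpy
    arrays so permutation replicates stay cheap.
    """

    __slots__ = ("scaffold", "snp_start_index", "span_start", "span_end",
                 "window", "stat")

    def __init__(self, scaffold, snp_start_index, span_start, span_end,
                 window: int, stat):
        self.scaffold = np.asarray(scaffold, dtype=object)
        self.snp_start_index = np.asarray(snp_start_index, dtype=np.int64)
        self.span_start = np.asarray(span_start, dtype=np.int64)
        self.span_end = np.asarray(span_end, dtype=np.int64)
        self.window = int(window)
        self.stat = np.asarray(stat, dtype=float)

    def __len__(self) -> int:
        return len(self.stat)

    def __getitem__(self, i):
        if isinstance(i, (int, np.integer)):
            return WindowStat(
                scaffold=str(self.scaffold[i]),
                snp_start_index=int(self.snp_start_index[i]),
                n_snps=self.window,
                span=(int(self.span_start[i]), int(self.span_end[i])),
                stat=float(self.stat[i]),
            )
        return self.subset(np.arange(len(self))[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx)
        return WindowSet(
            self.scaffold[idx],
            self.snp_start_index[idx],
            self.span_start[idx],
            self.span_end[idx],
            self.window,
            self.stat[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": self.scaffold,
                "snp_start_index": self.snp_start_index,
                "span_start": self.span_start,
                "span_end": self.span_end,
                "n_snps": self.window,
                "stat": self.stat,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False,
                                   float_format="%.10g")


def load_windows_tsv(path: str | Path,
                     outlier_percentile: float | None = None) -> WindowSet:
    """Read a window table written by :meth:`WindowSet.to_tsv` (or the scan
    stage's extended table); optionally keep only rows flagged as outliers at
    the given percentile."""
    df = pd.read_csv(path, sep="\t")
    if outlier_percentile is not None:
        flag = f"outlier_{outlier_percentile:g}"
        if flag not in df:
            raise ValueError(f"{path}: no column {flag}")
        df = df[df[flag]]
    window = int(df["n_snps"].iloc[0]) if len(df) else 20
    return WindowSet(df["scaffold"].astype(str).to_numpy(dtype=object),
                     df["snp_start_index"], df["span_start"], df["span_end"],
                     window, df["stat"])


def pair_daf(
    snps: SnpTable,
    anad: Sequence[str] | None = None,
    fresh: Sequence[str] | None = None,
) -> DeltaAFTable:
    """Raw |dAF| for every (anadromous, freshwater) pool pair at every SNP.

    Groups default to the manifest's life-history labels; pass pool-name lists
    to restrict (e.g. a single freshwater population for population-level
    scans).
    """
    name_to_col = {p.name: i for i, p in enumerate(snps.pools)}
    if anad is None:
        anad = [p.name for p in snps.pools if p.life_history == "anadromous"]
    if fresh is None:
        fresh = [p.name for p in snps.pools if p.life_history == "freshwater"]
    if len(anad) == 0 or len(fresh) == 0:
        raise ValueError(
            f"lineage {snps.lineage!r}: need >= 1 pool in each group "
            f"(anadromous={list(anad)}, freshwater={list(fresh)})"
        )
    a_idx = [name_to_col[n] for n in anad]
    f_idx = [name_to_col[n] for n in fresh]

    freqs = snps.freqs
    pairs = [(an, fn) for an in anad for fn in fresh]
    raw = np.abs(
        freqs[:, [name_to_col[fn] for an, fn in pairs]]
        - freqs[:, [name_to_col[an] for an, fn in pairs]]
    )
    return DeltaAFTable(
        lineage=snps.lineage,
        scaffold=snps.scaffold,
        position=snps.position,
        pairs=pairs,
        raw=raw,
    )


def standardize(daf: DeltaAFTable, pooled: bool = False) -> DeltaAFTable:
    """Standardize |dAF| genome-wide and average over pairs.

    Default: each pair is standardized against its own genome-wide mean and
    population standard deviation.  ``pooled=True`` instead standardizes all
    pairs' values against the single pooled mean/sd.
    """
    if daf.n_sites < 2:
        raise ValueError("standardization needs >= 2 SNPs")
    raw = daf.raw
    if pooled:
        mean = raw.mean()
        sd = raw.std()
        if sd == 0:
            raise ZeroVarianceError(
                f"lineage {daf.lineage!r}: pooled |dAF| has zero variance"
            )
        z = (raw - mean) / sd
    else:
        mean = raw.mean(axis=0)
        sd = raw.std(axis=0)  # population (divide-by-n) sd
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            names = ", ".join(f"{daf.pairs[k][0]}x{daf.pairs[k][1]}" for k in bad)
            raise ZeroVarianceError(
                f"lineage {daf.lineage!r}: zero genome-wide |dAF| variance "
                f"for pair(s) {names}"
            )
        z = (raw - mean[None, :]) / sd[None, :]
    return replace(daf, z=z, mean_z=z.mean(axis=1))


def select_top_scaffolds(
    scaffold_lengths: Mapping[str, int] | None,
    present: Sequence[str],
    top_scaffolds: int,
) -> set[str]:
    """Names of the ``top_scaffolds`` longest scaffolds (ties broken by name).

    With no length map every scaffold present in the data is scanned.
    """
    if scaffold_lengths is None:
        return set(map(str, present))
    ranked = sorted(scaffold_lengths.items(), key=lambda kv: (-kv[1], kv[0]))
    return {name for name, _ in ranked[:top_scaffolds]}


def window_scan(
    daf: DeltaAFTable,
    window: int = 20,
    step: int = 10,
    top_scaffolds: int = 1000,
    scaffold_lengths: Mapping[str, int] | None = None,
    offset: int = 1,
) -> WindowSet:
    """Aggregate per-SNP mean z into sliding windows of consecutive SNPs.

    Windows start at SNP indices ``offset, offset+step, ...`` (1-based within
    each scaffold; permutation replicates draw the offset at random).  Only
    full windows are emitted; scaffolds with fewer than ``window`` SNPs
    contribute none.
    """
    if daf.mean_z is None:
        raise ValueError("window_scan needs standardized values; call standardize()")
    if not (1 <= offset <= window):
        raise ValueError(f"offset must be in [1, {window}], got {offset}")
    segments = daf.scaffold_segments()
    keep = select_top_scaffolds(
        scaffold_lengths, [s for s, _, _ in segments], top_scaffolds
    )

    scaffolds: list[np.ndarray] = []
    start_idx: list[np.ndarray] = []
    span_lo: list[np.ndarray] = []
    span_hi: list[np.ndarray] = []
    stats: list[np.ndarray] = []
    for scaffold, lo, hi in segments:
        if scaffold not in keep:
            continue
        n = hi - lo
        if n < window:
            continue
        starts = np.arange(offset - 1, n - window + 1, step)
        if starts.size == 0:
            continue
        seg = daf.mean_z[lo:hi]
        cs = np.concatenate(([0.0], np.cumsum(seg)))
        stats.append((cs[starts + window] - cs[starts]) / window)
        pos = daf.position[lo:hi]
        span_lo.append(pos[starts])
        span_hi.append(pos[starts + window - 1])
        start_idx.append(starts + 1)
        scaffolds.append(np.full(starts.size, scaffold, dtype=object))

    if not stats:
        return WindowSet([], [], [], [], window, [])
    return WindowSet(
        np.concatenate(scaffolds),
        np.concatenate(start_idx),
        np.concatenate(span_lo),
        np.concatenate(span_hi),
        window,
        np.concatenate(stats),
    )
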