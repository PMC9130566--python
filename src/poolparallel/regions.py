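"""Outlier-region merging, gene annotation and parallelism metrics.

Outlier windows separated by at most ``gap`` intervening bases (default
20 kb) on a scaffold are merged transitively into genomic outlier regions;
genes whose span intersects a region extended by ``flank`` bases on both
sides (default 20 kb) are annotated as candidate targets.  Parallelism
between two region sets (or two lineages' polymorphic-site sets) is scored
as 100 x the mean of the two directional shared fractions, and loci shared
across every member of a collection of sets are reported as "complete
parallelism" intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel
from .permutation import PairZCache, build_null, call_outliers
from .scan import WindowSet, WindowStat
from .snps import SnpTable

__all__ = [
    "OutlierRegion",
    "GenomicInterval",
    "ParallelismReport",
    "merge_regions",
    "annotate_genes",
    "population_scan",
    "shared_regions",
    "shared_across",
    "shared_polymorphism",
    "regions_to_dataframe",
]


@dataclass(frozen=True)
class GenomicInterval:
    scaffold: str
    start: int  # 1-based inclusive
    end: int


@dataclass
class OutlierRegion:
    """A merged run of outlier windows; candidate target of selection."""

    scaffold: str
    start: int  # 1-based inclusive union hull over constituent windows
    end: int
    windows: list[WindowStat] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)

    @property
    def peak_stat(self) -> float:
        return max(w.stat for w in self.windows) if self.windows else float("nan")

    def intersects(self, other: "OutlierRegion | GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class ParallelismReport:
    """Symmetric sharing summary for a pair of units (populations/lineages)."""

    unit_pair: tuple[str, str]
    pct_shared_regions: float | None
    pct_shared_polymorphism: float | None
    n_shared: int
    n_a: int
    n_b: int


def merge_regions(outlier_windows: WindowSet | Sequence[WindowStat],
                  gap: int = 20000) -> list[OutlierRegion]:
    """Merge outlier windows within ``gap`` intervening bases of each other.

    Two window spans on one scaffold merge when they overlap or when
    ``next.start - prev.end - 1 <= gap`` (so a separation of exactly ``gap``
    bases still merges); merging is transitive.
    """
    wins = sorted(outlier_windows, key=lambda w: (w.scaffold, w.span[0], w.span[1]))
    regions: list[OutlierRegion] = []
    for w in wins:
        start, end = w.span
        if (
            regions
            and regions[-1].scaffold == w.scaffold
            and start - regions[-1].end - 1 <= gap
        ):
            r = regions[-1]
            r.end = max(r.end, end)
            r.windows.append(w)
        else:
            regions.append(
                OutlierRegion(scaffold=w.scaffold, start=start, end=end, windows=[w])
            )
    return regions


def annotate_genes(regions: Sequence[OutlierRegion],
                   genes: Sequence[GeneModel],
                   flank: int = 20000) -> list[OutlierRegion]:
    """Attach genes intersecting each region's +/- ``flank`` extended span."""
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    out = []
    for r in regions:
        lo = r.start - flank
        hi = r.end + flank
        hits = [
            g for g in by_scaffold.get(r.scaffold, ())
            if g.start <= hi and g.end >= lo
        ]
        out.append(
            OutlierRegion(
                scaffold=r.scaffold, start=r.start, end=r.end,
                windows=list(r.windows),
                genes=sorted(hits, key=lambda g: (g.start, g.end, g.gene_id)),
            )
        )
    return out


def population_scan(
    snps: SnpTable,
    fresh_pool: str,
    seed: int,
    n_perm: int = 1000,
    percentile: float = 99.0,
    window: int = 20,
    step: int = 10,
    top_scaffolds: int = 1000,
    scaffold_lengths: Mapping[str, int] | None = None,
    merge_gap: int = 20000,
) -> list[OutlierRegion]:
    """Outlier regions for a single freshwater population.

    Runs the same dAF -> permutation -> merge pipeline using only the
    lineage's anadromous pools plus the one named freshwater pool.  With a
    lineage that has exactly one freshwater pool this equals the lineage scan.
    """
    anad = [p.name for p in snps.pools if p.life_history == "anadromous"]
    sub = snps.subset_pools(anad + [fresh_pool])
    cache = PairZCache(sub, scaffold_lengths, top_scaffolds)
    observed = cache.scan(
        np.arange(len(anad)), np.array([len(anad)]), window, step, offset=1
    )
    null = build_null(
        sub, n_perm=n_perm, seed=seed, window=window, step=step,
        top_scaffolds=top_scaffolds, scaffold_lengths=scaffold_lengths,
        cache=cache,
    )
    return merge_regions(call_outliers(observed, null, percentile), gap=merge_gap)


def _merged_hulls(regions: Sequence[OutlierRegion]) -> dict[str, np.ndarray]:
    """Per-scaffold sorted, coalesced (start, end) arrays (union of spans)."""
    per: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        per.setdefault(r.scaffold, []).append((r.start, r.end))
    out: dict[str, np.ndarray] = {}
    for s, spans in per.items():
        coalesced: list[list[int]] = []
        for lo, hi in sorted(spans):
            if coalesced and lo <= coalesced[-1][1]:
                coalesced[-1][1] = max(coalesced[-1][1], hi)
            else:
                coalesced.append([lo, hi])
        out[s] = np.array(coalesced)
    return out


def _count_intersecting(a: Sequence[OutlierRegion],
                        b: Sequence[OutlierRegion]) -> int:
    hulls = _merged_hulls(b)
    n = 0
    for r in a:
        iv = hulls.get(r.scaffold)
        if iv is None:
            continue
        # any b-interval with start <= r.end and end >= r.start
        i = np.searchsorted(iv[:, 0], r.end, side="right")
        if i > 0 and (iv[:i, 1] >= r.start).any():
            n += 1
    return n


def shared_regions(a: Sequence[OutlierRegion], b: Sequence[OutlierRegion],
                   unit_pair: tuple[str, str] = ("A", "B")) -> ParallelismReport:
    """Percentage of outlier regions shared by two units.

    A region is shared when it intersects (>= 1 bp) any region of the other
    set; the percentage is 100 x mean(shared_A/|A|, shared_B/|B|), symmetric
    in the two arguments.
    """
    if len(a) == 0 or len(b) == 0:
        warnings.warn(
            f"shared_regions({unit_pair}): one region set is empty; pct = 0",
            stacklevel=2,
        )
        return ParallelismReport(unit_pair, 0.0, None, 0, len(a), len(b))
    shared_a = _count_intersecting(a, b)
    shared_b = _count_intersecting(b, a)
    pct = 100.0 * 0.5 * (shared_a / len(a) + shared_b / len(b))
    return ParallelismReport(unit_pair, pct, None, min(shared_a, shared_b),
                             len(a), len(b))


def _intersect_interval_lists(x: list[tuple[int, int]],
                              y: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(x) and j < len(y):
        lo = max(x[i][0], y[j][0])
        hi = min(x[i][1], y[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if x[i][1] < y[j][1]:
            i += 1
        else:
            j += 1
    return out


def shared_across(sets: Sequence[Sequence[OutlierRegion]]) -> list[GenomicInterval]:
    """Maximal genomic intervals covered by a region in *every* set.

    These are the "complete parallelism" loci; an empty member set yields an
    empty result.
    """
    if len(sets) < 2:
        raise ValueError("shared_across needs >= 2 region sets")
    if any(len(s) == 0 for s in sets):
        return []
    per_set = [_merged_hulls(s) for s in sets]
    scaffolds = set(per_set[0])
    for h in per_set[1:]:
        scaffolds &= set(h)
    out: list[GenomicInterval] = []
    for scaffold in sorted(scaffolds):
        acc = [tuple(v) for v in per_set[0][scaffold]]
        for h in per_set[1:]:
            acc = _intersect_interval_lists(acc, [tuple(v) for v in h[scaffold]])
            if not acc:
                break
        out.extend(GenomicInterval(scaffold, lo, hi) for lo, hi in acc)
    return out


def shared_polymorphism(a: set, b: set,
                        unit_pair: tuple[str, str] = ("A", "B")) -> float:
    """Average percentage of polymorphic sites shared by two lineages.

    pct = 100 x mean(|A n B|/|A|, |A n B|/|B|); site keys are
    (scaffold, position).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"shared_polymorphism({unit_pair}): empty site set")
    inter = len(a & b)
    return 100.0 * 0.5 * (inter / len(a) + inter / len(b))


def regions_to_dataframe(regions: Sequence[OutlierRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "scaffold": r.scaffold,
                "start": r.start,
                "end": r.end,
                "n_windows": len(r.windows),
                "peak_stat": r.peak_stat,
                "genes": ",".join(g.gene_id for g in r.genes),
            }
        )
    return pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "n_windows", "peak_stat", "genes"]
    )
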