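"""Permutation null for the window scan and empirical outlier thresholds.

Each permutation randomly reassigns the lineage's pools to the anadromous /
freshwater labels (preserving the observed group sizes), reruns the full
pair -> standardize -> window pipeline, and draws the window grid's start
offset uniformly from {1..window} so that all possible 20-SNP window phases
are sampled.  The window statistics of all permutations are pooled into one
empirical null per lineage, from which genome-wide 99th / 99.9th nearest-rank
percentile thresholds and add-one empirical p-values are derived.

Because a pool pair's standardized |dAF| column does not depend on which label
each pool carries, the per-pair z columns are computed once and cached; a
permutation then only selects and averages columns.  This is numerically
identical to rerunning the full pipeline per permutation (asserted in tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scan import DeltaAFTable, WindowSet, pair_daf, standardize, window_scan
from .snps import SnpTable

__all__ = [
    "NullDistribution",
    "PairZCache",
    "nearest_rank",
    "permute_once",
    "build_null",
    "window_pvalues",
    "call_outliers",
]

PERCENTILES = (99.0, 99.9)


def nearest_rank(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * N)-th smallest value."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("nearest_rank of an empty distribution")
    # small guard so exact boundaries (e.g. 99.9% of 1000) are not pushed up
    # a rank by floating-point error
    k = math.ceil(percentile / 100.0 * values.size - 1e-9)
    k = min(max(k, 1), values.size)
    return float(np.partition(values, k - 1)[k - 1])


@dataclass
class NullDistribution:
    """Pooled permuted window statistics with percentile thresholds."""

    values: np.ndarray  # all permutations' window stats, permutation order
    n_perm: int
    thresholds: dict[float, float]
    seed: int
    _sorted: np.ndarray | None = None

    def __post_init__(self):
        if self.n_perm >= 1 and self.values.size == 0:
            raise ValueError("null distribution is empty")
        if self._sorted is None:
            self._sorted = np.sort(self.values)

    def threshold(self, percentile: float) -> float:
        return self.thresholds[float(percentile)]

    def to_tsv(self, path: str | Path) -> None:
        rows = [("n_perm", self.n_perm), ("n_values", self.values.size),
                ("seed", self.seed)]
        rows += [(f"threshold_{p:g}", t) for p, t in sorted(self.thresholds.items())]
        pd.DataFrame(rows, columns=["key", "value"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


class PairZCache:
    """Per-pool-pair standardized |dAF| columns plus window-grid geometry.

    The cache is label-free: column (i, j) holds the genome-wide standardized
    |freq_i - freq_j|, which is what the scan computes for the pair regardless
    of which pool is labelled anadromous.  Built once per lineage and reused
    by every permutation.
    """

    def __init__(self, snps: SnpTable,
                 scaffold_lengths: Mapping[str, int] | None = None,
                 top_scaffolds: int = 1000, pooled: bool = False):
        self.snps = snps
        self.scaffold_lengths = scaffold_lengths
        self.top_scaffolds = top_scaffolds
        self.pooled = pooled
        P = snps.n_pools
        names = snps.pool_names
        self._col: dict[tuple[int, int], int] = {}
        z_cols, raw_cols = [], []
        for i in range(P):
            for j in range(i + 1, P):
                # reuse the public pipeline for each single pair so the cache
                # can never drift from pair_daf/standardize semantics
                one = pair_daf(snps, anad=[names[i]], fresh=[names[j]])
                raw_cols.append(one.raw[:, 0])
                if not pooled:
                    one = standardize(one)
                    z_cols.append(one.z[:, 0])
                self._col[(i, j)] = len(raw_cols) - 1
        empty = np.empty((snps.n_sites, 0))
        self.raw = np.column_stack(raw_cols) if raw_cols else empty
        self.z = np.column_stack(z_cols) if z_cols else empty
        self._template = DeltaAFTable(
            lineage=snps.lineage,
            scaffold=snps.scaffold,
            position=snps.position,
            pairs=[],
            raw=empty,
        )

    def daf_for_labels(self, anad_idx: Sequence[int],
                       fresh_idx: Sequence[int]) -> DeltaAFTable:
        """Standardized table for an arbitrary label assignment."""
        names = self.snps.pool_names
        pairs, cols = [], []
        for i in anad_idx:
            for j in fresh_idx:
                pairs.append((names[i], names[j]))
                cols.append(self._col[(min(i, j), max(i, j))])
        t = self._template
        raw = self.raw[:, cols]
        if self.pooled:
            sd = raw.std()
            if sd == 0:
                from .scan import ZeroVarianceError

                raise ZeroVarianceError(
                    f"lineage {t.lineage!r}: pooled |dAF| has zero variance"
                )
            z = (raw - raw.mean()) / sd
        else:
            z = self.z[:, cols]
        return DeltaAFTable(
            lineage=t.lineage, scaffold=t.scaffold, position=t.position,
            pairs=pairs, raw=raw, z=z, mean_z=z.mean(axis=1),
        )

    def scan(self, anad_idx, fresh_idx, window: int, step: int,
             offset: int) -> WindowSet:
        daf = self.daf_for_labels(anad_idx, fresh_idx)
        return window_scan(
            daf, window=window, step=step, top_scaffolds=self.top_scaffolds,
            scaffold_lengths=self.scaffold_lengths, offset=offset,
        )


def permute_once(
    snps: SnpTable,
    rng: np.random.Generator,
    window: int = 20,
    step: int = 10,
    top_scaffolds: int = 1000,
    scaffold_lengths: Mapping[str, int] | None = None,
    cache: PairZCache | None = None,
) -> WindowSet:
    """One label permutation with a random window-start offset.

    Pools are reassigned to the anadromous/freshwater labels uniformly at
    random among assignments preserving the observed group sizes (the identity
    assignment included); the offset is drawn uniformly from {1..window}.
    """
    if snps.n_pools < 2:
        raise ValueError(
            f"lineage {snps.lineage!r}: cannot permute labels with "
            f"{snps.n_pools} pool(s)"
        )
    n_anad = len(snps.pool_indices("anadromous"))
    n_fresh = len(snps.pool_indices("freshwater"))
    if n_anad == 0 or n_fresh == 0:
        raise ValueError(
            f"lineage {snps.lineage!r}: both label groups must be nonempty"
        )
    if cache is None:
        cache = PairZCache(snps, scaffold_lengths, top_scaffolds)
    perm = rng.permutation(snps.n_pools)
    anad_idx = np.sort(perm[:n_anad])
    fresh_idx = np.sort(perm[n_anad:])
    offset = int(rng.integers(1, window + 1))
    return cache.scan(anad_idx, fresh_idx, window, step, offset)


def build_null(
    snps: SnpTable,
    n_perm: int = 1000,
    seed: int = 0,
    window: int = 20,
    step: int = 10,
    top_scaffolds: int = 1000,
    scaffold_lengths: Mapping[str, int] | None = None,
    percentiles: Sequence[float] = PERCENTILES,
    cache: PairZCache | None = None,
) -> NullDistribution:
    """Pool ``n_perm`` permutations into one empirical null distribution.

    The master seed spawns one independent stream per permutation index, so
    the result is invariant to the order permutations are executed in.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if cache is None:
        cache = PairZCache(snps, scaffold_lengths, top_scaffolds)
    children = np.random.SeedSequence(seed).spawn(n_perm)
    chunks = []
    for child in children:
        rng = np.random.default_rng(child)
        ws = permute_once(
            snps, rng, window=window, step=step, top_scaffolds=top_scaffolds,
            scaffold_lengths=scaffold_lengths, cache=cache,
        )
        chunks.append(ws.stat)
    values = np.concatenate(chunks) if chunks else np.empty(0)
    thresholds = {float(p): nearest_rank(values, p) for p in percentiles}
    return NullDistribution(values=values, n_perm=n_perm,
                            thresholds=thresholds, seed=seed)


def window_pvalues(observed: WindowSet, null: NullDistribution) -> np.ndarray:
    """Add-one empirical p-values: p = (1 + #{null >= stat}) / (1 + #null)."""
    srt = null._sorted
    n = srt.size
    if n == 0:
        raise ValueError("null distribution is empty")
    n_ge = n - np.searchsorted(srt, observed.stat, side="left")
    return (1.0 + n_ge) / (1.0 + n)


def call_outliers(
    observed: WindowSet,
    null: NullDistribution,
    percentile: float = 99.0,
) -> WindowSet:
    """Observed windows at or above the null's percentile threshold (>= rule)."""
    thr = null.threshold(percentile)
    return observed.subset(np.flatnonzero(observed.stat >= thr))
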