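"""High-level orchestration: one call per pipeline stage, shared by the CLI,
the analysis drivers and the acceptance checks.

A :class:`ScanParams` bundles every tunable with the defaults used throughout
(minor count 4, coverage bounds [10, 2x mean], 20-SNP/10-step windows over
the 1000 largest scaffolds, 1000 permutations, 99/99.9 percentiles, 20 kb
merging and gene flank, 2-SNP heat-map floor, 95th percentile for the shared
nonsynonymous test); :func:`lineage_scan` runs SNP table -> dAF ->
permutation null -> outlier windows/regions for one lineage and returns
everything downstream stages need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import PoolInfo, SiteCounts
from .permutation import (
    NullDistribution,
    PairZCache,
    build_null,
    call_outliers,
    window_pvalues,
)
from .regions import OutlierRegion, merge_regions
from .scan import DeltaAFTable, WindowSet, pair_daf, standardize, window_scan
from .snps import SnpTable, call_snps, filter_near_indels

__all__ = ["ScanParams", "LineageScanResult", "build_snp_table", "lineage_scan"]


@dataclass(frozen=True)
class ScanParams:
    """All pipeline tunables with their standard defaults."""

    min_minor_count: int = 4
    min_cov: int = 10
    max_cov_factor: float = 2.0
    indel_distance: int = 10
    window: int = 20
    step: int = 10
    top_scaffolds: int = 1000
    n_perm: int = 1000
    percentiles: tuple[float, float] = (99.0, 99.9)
    merge_gap: int = 20000
    gene_flank: int = 20000
    min_snps_per_cell: int = 2
    nonsyn_percentile: float = 95.0
    pooled_standardization: bool = False


@dataclass
class LineageScanResult:
    """Everything the downstream stages need from one lineage's scan."""

    lineage: str
    snps: SnpTable
    daf: DeltaAFTable  # standardized, observed labels
    observed: WindowSet
    null: NullDistribution
    pvalues: np.ndarray
    outliers: dict[float, WindowSet]  # percentile -> outlier windows
    regions: dict[float, list[OutlierRegion]]  # percentile -> merged regions

    def outlier_windows(self, percentile: float = 99.0) -> WindowSet:
        return self.outliers[float(percentile)]

    def outlier_regions(self, percentile: float = 99.0) -> list[OutlierRegion]:
        return self.regions[float(percentile)]


def build_snp_table(
    sites: Sequence[SiteCounts],
    pools: Sequence[PoolInfo],
    params: ScanParams = ScanParams(),
    indels: Sequence[tuple[str, int]] = (),
) -> SnpTable:
    """Count-level SNP calling plus the near-indel filter for one lineage."""
    snps = call_snps(
        sites, pools,
        min_minor_count=params.min_minor_count,
        min_cov=params.min_cov,
        max_cov_factor=params.max_cov_factor,
    )
    if indels:
        snps = filter_near_indels(snps, indels, distance=params.indel_distance)
    return snps


def lineage_scan(
    snps: SnpTable,
    seed: int,
    params: ScanParams = ScanParams(),
    scaffold_lengths: Mapping[str, int] | None = None,
) -> LineageScanResult:
    """Observed scan, permutation null, p-values, outliers and regions."""
    cache = PairZCache(snps, scaffold_lengths, params.top_scaffolds,
                       pooled=params.pooled_standardization)
    daf = standardize(pair_daf(snps), pooled=params.pooled_standardization)
    observed = window_scan(
        daf, window=params.window, step=params.step,
        top_scaffolds=params.top_scaffolds,
        scaffold_lengths=scaffold_lengths, offset=1,
    )
    null = build_null(
        snps, n_perm=params.n_perm, seed=seed, window=params.window,
        step=params.step, top_scaffolds=params.top_scaffolds,
        scaffold_lengths=scaffold_lengths, percentiles=params.percentiles,
        cache=cache,
    )
    pvals = window_pvalues(observed, null)
    outliers = {
        float(p): call_outliers(observed, null, p) for p in params.percentiles
    }
    regions = {
        p: merge_regions(ws, gap=params.merge_gap) for p, ws in outliers.items()
    }
    return LineageScanResult(
        lineage=snps.lineage, snps=snps, daf=daf, observed=observed,
        null=null, pvalues=pvals, outliers=outliers, regions=regions,
    )
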