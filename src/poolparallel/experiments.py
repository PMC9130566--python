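"""Whole-pipeline experiments on synthetic data with known truth.

Two standard designs are bundled because the package's own validation and the
analysis drivers both run them:

* :func:`null_calibration` — pure-drift datasets; measures the fraction of
  observed windows called outliers at the 99th / 99.9th percentile
  thresholds (should match the nominal 1% / 0.1% rates).
* :func:`planted_recovery` — datasets with freshwater-selected regions
  planted at a known |dAF| shift; measures how many planted regions are
  recovered at the 99.9th percentile and how many called regions are false
  positives.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .pipeline import ScanParams, build_snp_table, lineage_scan
from .regions import OutlierRegion
from .simulate import SimConfig, evenly_planted_regions, null_dataset, simulate

__all__ = ["derive_seed", "CalibrationResult", "RecoveryResult",
           "null_calibration", "planted_recovery"]


def derive_seed(master: int, label: str) -> int:
    """Stable 31-bit per-stage seed from a master seed and a stage label."""
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class CalibrationResult:
    n_windows: int
    n_exceed_99: int
    n_exceed_999: int

    @property
    def frac_99(self) -> float:
        return self.n_exceed_99 / self.n_windows

    @property
    def frac_999(self) -> float:
        return self.n_exceed_999 / self.n_windows

    def binomial_se(self, nominal: float) -> float:
        return float(np.sqrt(nominal * (1 - nominal) / self.n_windows))


def null_calibration(
    seeds: Sequence[int],
    n_snps: int = 50_000,
    n_lineages: int = 2,
    pools: tuple[int, int] = (2, 2),
    coverage_mean: float = 32.0,
    n_perm: int = 200,
    n_scaffolds: int = 10,
    scaffold_length: int = 1_000_000,
) -> CalibrationResult:
    """Outlier-call rates on pure-drift data, pooled over seeds and lineages."""
    params = ScanParams(n_perm=n_perm)
    n_windows = exceed99 = exceed999 = 0
    for seed in seeds:
        cfg = SimConfig(
            n_lineages=n_lineages,
            pools_per_lineage=tuple([pools] * n_lineages),
            n_scaffolds=n_scaffolds,
            scaffold_length=scaffold_length,
            n_snps=n_snps,
            coverage_mean=coverage_mean,
            seed=derive_seed(seed, "null-data"),
        )
        ds = null_dataset(cfg)
        for lname, lin in ds.lineages.items():
            snps = build_snp_table(lin.site_counts(), lin.pools, params)
            res = lineage_scan(snps, derive_seed(seed, f"null-scan:{lname}"),
                               params, ds.scaffold_lengths)
            n_windows += len(res.observed)
            exceed99 += int(np.sum(res.observed.stat
                                   >= res.null.threshold(99)))
            exceed999 += int(np.sum(res.observed.stat
                                    >= res.null.threshold(99.9)))
    return CalibrationResult(n_windows, exceed99, exceed999)


@dataclass(frozen=True)
class RecoveryResult:
    n_regions_planted: int
    recovered_per_seed: tuple[int, ...]
    false_positives_per_seed: tuple[int, ...]

    @property
    def mean_recovered(self) -> float:
        return float(np.mean(self.recovered_per_seed))

    @property
    def mean_false_positives(self) -> float:
        return float(np.mean(self.false_positives_per_seed))


def planted_recovery(
    seeds: Sequence[int],
    n_snps: int = 100_000,
    n_regions: int = 10,
    delta: float = 0.7,
    min_snps_per_region: int = 40,
    region_length: int = 20_000,
    pools: tuple[int, int] = (2, 3),
    n_perm: int = 200,
    percentile: float = 99.9,
    n_scaffolds: int = 10,
    scaffold_length: int = 1_000_000,
) -> RecoveryResult:
    """Planted-region recovery and false-positive regions at a percentile.

    One lineage per dataset; a planted region counts as recovered when it
    intersects any called outlier region, and a called region not touching
    any planted region is a false positive.
    """
    params = ScanParams(n_perm=n_perm)
    recovered, false_pos = [], []
    for seed in seeds:
        base = SimConfig(
            n_lineages=1,
            pools_per_lineage=(pools,),
            n_scaffolds=n_scaffolds,
            scaffold_length=scaffold_length,
            n_snps=n_snps,
            min_snps_per_region=min_snps_per_region,
            seed=derive_seed(seed, "planted-data"),
        )
        regions = evenly_planted_regions(base, n_regions, delta,
                                         length=region_length)
        ds = simulate(replace(base, planted_regions=regions))
        lin = ds.lineages["L1"]
        snps = build_snp_table(lin.site_counts(), lin.pools, params)
        res = lineage_scan(snps, derive_seed(seed, "planted-scan"),
                           params, ds.scaffold_lengths)
        called = res.outlier_regions(percentile)
        truth = [OutlierRegion(s, a, b)
                 for s, a, b, _d in ds.truth.regions["L1"]]
        recovered.append(
            sum(any(c.intersects(t) for c in called) for t in truth))
        false_pos.append(
            sum(not any(c.intersects(t) for t in truth) for c in called))
    return RecoveryResult(n_regions, tuple(recovered), tuple(false_pos))
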