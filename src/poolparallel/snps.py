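"""Count-level SNP filtering and per-pool allele frequencies.

SNPs are called per lineage from pooled read counts.  A site is retained iff

* exactly two of A/T/C/G have nonzero counts summed over the lineage's pools
  (biallelic),
* the lineage-wide minor-allele count is at least ``min_minor_count``
  (default 4),
* every pool's coverage lies in ``[min_cov, max_cov_factor x that pool's
  genome-wide mean coverage]`` (defaults 10 and 2.0); the genome-wide mean is
  computed from the full, unfiltered input.

The per-pool allele frequency of a retained SNP is the frequency of the
lineage-wide minor allele among that pool's major+minor reads (N/del reads
count toward coverage but never toward allele frequencies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PoolInfo, SiteCounts

__all__ = ["SnpTable", "call_snps", "filter_near_indels", "polymorphic_sites"]

_ACGT = np.array(["A", "T", "C", "G"])  # sync order


@dataclass
class SnpTable:
    """Lineage-level biallelic SNPs with per-pool minor-allele frequencies.

    Column order of the 2-D arrays follows ``pools``.  Sites are sorted by
    (scaffold, position).  ``minor_count``/``major_count`` are per-pool read
    counts of the lineage-wide minor/major allele, so every frequency is
    recomputable as minor/(minor+major).
    """

    lineage: str
    pools: list[PoolInfo]
    scaffold: np.ndarray  # (S,) str
    position: np.ndarray  # (S,) int64, 1-based
    major: np.ndarray  # (S,) str
    minor: np.ndarray  # (S,) str
    minor_count: np.ndarray  # (S, P) int64
    major_count: np.ndarray  # (S, P) int64

    @property
    def n_sites(self) -> int:
        return len(self.position)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def pool_names(self) -> list[str]:
        return [p.name for p in self.pools]

    @property
    def freqs(self) -> np.ndarray:
        """(S, P) frequency of the lineage-wide minor allele in each pool."""
        denom = self.minor_count + self.major_count
        return self.minor_count / denom

    @property
    def coverage(self) -> np.ndarray:
        """(S, P) allele coverage (major + minor reads) used for frequencies."""
        return self.minor_count + self.major_count

    def pool_indices(self, life_history: str | None = None) -> np.ndarray:
        if life_history is None:
            return np.arange(self.n_pools)
        return np.array(
            [i for i, p in enumerate(self.pools) if p.life_history == life_history],
            dtype=int,
        )

    def subset_sites(self, mask: np.ndarray) -> "SnpTable":
        return replace(
            self,
            scaffold=self.scaffold[mask],
            position=self.position[mask],
            major=self.major[mask],
            minor=self.minor[mask],
            minor_count=self.minor_count[mask],
            major_count=self.major_count[mask],
        )

    def subset_pools(self, names: Sequence[str]) -> "SnpTable":
        """Restrict to the named pools; the SNP set itself is left as called."""
        index = {p.name: i for i, p in enumerate(self.pools)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"pools not in table: {missing}")
        cols = np.array([index[n] for n in names], dtype=int)
        return replace(
            self,
            pools=[self.pools[i] for i in cols],
            minor_count=self.minor_count[:, cols],
            major_count=self.major_count[:, cols],
        )

    def site_keys(self) -> set[tuple[str, int]]:
        return set(zip(self.scaffold.tolist(), self.position.tolist()))

    def scaffold_segments(self) -> list[tuple[str, int, int]]:
        """Contiguous (scaffold, lo, hi) row slices; sites are sorted."""
        segs: list[tuple[str, int, int]] = []
        if self.n_sites == 0:
            return segs
        scafs = self.scaffold
        change = np.flatnonzero(scafs[1:] != scafs[:-1]) + 1
        bounds = np.concatenate(([0], change, [len(scafs)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            segs.append((str(scafs[lo]), int(lo), int(hi)))
        return segs

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "scaffold": self.scaffold,
                "position": self.position,
                "major": self.major,
                "minor": self.minor,
            }
        )
        freqs = self.freqs
        cov = self.coverage
        for j, p in enumerate(self.pools):
            df[f"freq_{p.name}"] = freqs[:, j]
            df[f"cov_{p.name}"] = cov[:, j]
        return df

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        mc = self.minor_count
        for j, p in enumerate(self.pools):
            df[f"minor_count_{p.name}"] = mc[:, j]
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, pools: Sequence[PoolInfo]) -> "SnpTable":
        """Load a table written by :meth:`to_tsv` (pools give column order)."""
        df = pd.read_csv(path, sep="\t")
        lineages = {p.lineage for p in pools}
        if len(lineages) != 1:
            raise ValueError("pools must belong to a single lineage")
        minor_count = np.column_stack(
            [df[f"minor_count_{p.name}"].to_numpy(np.int64) for p in pools]
        )
        cov = np.column_stack(
            [df[f"cov_{p.name}"].to_numpy(np.int64) for p in pools]
        )
        return cls(
            lineage=next(iter(lineages)),
            pools=list(pools),
            scaffold=df["scaffold"].astype(str).to_numpy(dtype=object),
            position=df["position"].to_numpy(np.int64),
            major=df["major"].astype(str).to_numpy(dtype=object),
            minor=df["minor"].astype(str).to_numpy(dtype=object),
            minor_count=minor_count,
            major_count=cov - minor_count,
        )


def _stack_counts(sites: Sequence[SiteCounts], n_pools: int) -> np.ndarray:
    arr = np.asarray([s.counts for s in sites], dtype=np.int64)
    if arr.ndim != 3 or arr.shape[1] != n_pools or arr.shape[2] != 6:
        raise ValueError(
            f"count block has shape {arr.shape}, expected (S, {n_pools}, 6)"
        )
    return arr


def call_snps(
    sites: Sequence[SiteCounts],
    lineage_pools: Sequence[PoolInfo],
    min_minor_count: int = 4,
    min_cov: int = 10,
    max_cov_factor: float = 2.0,
) -> SnpTable:
    """Apply the count-level SNP filters for one lineage.

    ``lineage_pools`` must all belong to one lineage and match the sync column
    order of ``sites``.  Biallelic status and the minor allele are decided from
    counts summed over the lineage's pools.
    """
    if not lineage_pools:
        raise ValueError("lineage has zero pools")
    lineages = {p.lineage for p in lineage_pools}
    if len(lineages) != 1:
        raise ValueError(f"pools span multiple lineages: {sorted(lineages)}")
    lineage = lineage_pools[0].lineage
    n_pools = len(lineage_pools)

    if len(sites) == 0:
        empty = np.empty((0, n_pools), dtype=np.int64)
        return SnpTable(
            lineage=lineage,
            pools=list(lineage_pools),
            scaffold=np.empty(0, dtype=object),
            position=np.empty(0, dtype=np.int64),
            major=np.empty(0, dtype=object),
            minor=np.empty(0, dtype=object),
            minor_count=empty,
            major_count=empty.copy(),
        )

    arr = _stack_counts(sites, n_pools)  # (S, P, 6)
    cov = arr.sum(axis=2)  # full coverage incl. N/del
    # genome-wide mean coverage per pool, from ALL input sites before filtering
    mean_cov = cov.mean(axis=0)

    acgt = arr[:, :, :4]
    pooled = acgt.sum(axis=1)  # (S, 4) lineage-wide counts
    biallelic = (pooled > 0).sum(axis=1) == 2

    order = np.argsort(pooled, axis=1, kind="stable")
    major_idx = order[:, -1]
    minor_idx = order[:, -2]
    rows = np.arange(len(sites))
    minor_total = pooled[rows, minor_idx]

    cov_ok = (cov >= min_cov).all(axis=1) & (
        cov <= max_cov_factor * mean_cov[None, :]
    ).all(axis=1)
    keep = biallelic & (minor_total >= min_minor_count) & cov_ok

    minor_counts = acgt[rows[:, None], np.arange(n_pools)[None, :], minor_idx[:, None]]
    major_counts = acgt[rows[:, None], np.arange(n_pools)[None, :], major_idx[:, None]]

    # frequency denominator is major+minor reads; a pool with zero such reads
    # at a site leaves the frequency undefined, so the site is dropped
    denom_ok = ((minor_counts + major_counts) > 0).all(axis=1)
    n_undef = int((keep & ~denom_ok).sum())
    if n_undef:
        warnings.warn(
            f"{lineage}: dropped {n_undef} site(s) where a pool had no "
            "major/minor-allele reads (frequency undefined)",
            stacklevel=2,
        )
    keep &= denom_ok

    scaffold = np.asarray([s.scaffold for s in sites], dtype=object)[keep]
    position = np.asarray([s.position for s in sites], dtype=np.int64)[keep]
    major = _ACGT[major_idx[keep]].astype(object)
    minor = _ACGT[minor_idx[keep]].astype(object)
    minor_counts = minor_counts[keep]
    major_counts = major_counts[keep]

    order = np.lexsort((position, scaffold.astype(str)))
    return SnpTable(
        lineage=lineage,
        pools=list(lineage_pools),
        scaffold=scaffold[order],
        position=position[order],
        major=major[order],
        minor=minor[order],
        minor_count=minor_counts[order],
        major_count=major_counts[order],
    )


def filter_near_indels(
    snps: SnpTable,
    indels: Iterable[tuple[str, int]],
    distance: int = 10,
) -> SnpTable:
    """Drop SNPs within ``distance`` bp of an indel on the same scaffold."""
    by_scaffold: dict[str, list[int]] = {}
    for scaffold, pos in indels:
        by_scaffold.setdefault(scaffold, []).append(pos)
    if not by_scaffold:
        return snps
    keep = np.ones(snps.n_sites, dtype=bool)
    for scaffold, lo, hi in snps.scaffold_segments():
        ipos = by_scaffold.get(scaffold)
        if not ipos:
            continue
        ipos = np.sort(np.asarray(ipos, dtype=np.int64))
        pos = snps.position[lo:hi]
        j = np.searchsorted(ipos, pos)
        near = np.zeros(len(pos), dtype=bool)
        left = j - 1
        ok = left >= 0
        near[ok] |= (pos[ok] - ipos[left[ok]]) <= distance
        ok = j < len(ipos)
        near[ok] |= (ipos[j[ok]] - pos[ok]) <= distance
        keep[lo:hi] = ~near
    return snps.subset_sites(keep)


def polymorphic_sites(
    snps: SnpTable,
    ref_alleles: Mapping[tuple[str, int], str],
) -> set[tuple[str, int]]:
    """Sites variable, or fixed for a non-reference allele, in >= 1 pool.

    A pool is polymorphic at a site if 0 < freq < 1; a pool fixed at freq 1 is
    fixed for the minor allele and at freq 0 for the major allele — the site
    qualifies if that fixed base differs from the reference base.
    """
    freqs = snps.freqs
    variable = ((freqs > 0) & (freqs < 1)).any(axis=1)

    result: set[tuple[str, int]] = set()
    for i in range(snps.n_sites):
        key = (str(snps.scaffold[i]), int(snps.position[i]))
        if variable[i]:
            result.add(key)
            continue
        ref = ref_alleles.get(key)
        if ref is None:
            continue
        fixed_bases = np.where(freqs[i] == 1.0, snps.minor[i], snps.major[i])
        if (fixed_bases != ref).any():
            result.add(key)
    return result
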