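"""Pool-seq nucleotide diversity, Watterson's theta, Tajima's D and D_XY.

Statistics are computed over the same 20-SNP windows as the dAF scan so that
outlier / non-outlier contrasts align one-to-one with scan windows, and they
are per-variant-site averages (monomorphic sites between SNPs are not
included), not per-bp.

Estimators
----------
site pi        (C/(C-1)) * (1 - sum_i p_i^2) with p_i the read frequency of
               allele i and C the allele coverage; unbiased for the pool's
               heterozygosity under binomial read sampling.
site D_XY      p1*(1-p2) + p2*(1-p1) for the same allele's frequencies in the
               two pools, averaged over all anadromous x freshwater pairs.
Tajima's D     standard constants with n = the window's effective sample
               size: per site n_eff = min(coverage, haploid pool size) (reads
               cannot sample more chromosomes than the pool holds), per
               window n = floor(mean per-site n_eff).  theta_pi is the sum of
               site pi over the window, S counts sites segregating in the
               pool, theta_W = S / a1(n).

Undefined values (coverage < 2 for pi; S = 0 or n < 4 for D) are reported as
NaN, never silently zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .regions import OutlierRegion
from .scan import WindowSet
from .snps import SnpTable

__all__ = [
    "PopGenTrack",
    "ContrastSummary",
    "site_pi",
    "site_dxy",
    "tajima_constants",
    "tajima_d",
    "window_tajima_d",
    "pool_track",
    "dxy_track",
    "contrast_outliers",
]


def site_pi(counts: Sequence[int] | np.ndarray) -> float:
    """Per-site nucleotide diversity from per-allele read counts.

    pi_hat = (C/(C-1)) * (1 - sum p_i^2); NaN when coverage C < 2.
    """
    counts = np.asarray(counts, dtype=float)
    c = counts.sum()
    if c < 2:
        return float("nan")
    p = counts / c
    return float(c / (c - 1.0) * (1.0 - np.sum(p * p)))


def site_dxy(p1: float, p2: float) -> float:
    """Pairwise divergence between two pools at one site: p1(1-p2)+p2(1-p1)."""
    return p1 * (1.0 - p2) + p2 * (1.0 - p1)


def tajima_constants(n: int) -> dict[str, float]:
    """The standard a1/a2/b1/b2/c1/c2/e1/e2 constants for sample size n."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(theta_pi: float, n_segregating: int, n: int) -> float:
    """Tajima's D from window totals; NaN when S = 0 or n < 4."""
    if n_segregating < 1 or n < 4:
        return float("nan")
    k = tajima_constants(n)
    theta_w = n_segregating / k["a1"]
    var = k["e1"] * n_segregating + k["e2"] * n_segregating * (n_segregating - 1)
    if var <= 0:
        return float("nan")
    return float((theta_pi - theta_w) / np.sqrt(var))


def window_tajima_d(minor_counts: np.ndarray, major_counts: np.ndarray,
                    n_eff: int) -> float:
    """Tajima's D for one pool over one window of SNP sites.

    ``minor_counts``/``major_counts`` are that pool's read counts at the
    window's sites; ``n_eff`` is the window's effective sample size.
    """
    minor = np.asarray(minor_counts, dtype=float)
    major = np.asarray(major_counts, dtype=float)
    seg = (minor > 0) & (major > 0)
    s = int(seg.sum())
    cov = minor + major
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(cov > 0, minor / np.where(cov > 0, cov, 1), np.nan)
        pi_sites = np.where(
            cov >= 2, cov / (cov - 1.0) * (2.0 * p * (1.0 - p)), np.nan
        )
    theta_pi = float(np.nansum(pi_sites))
    return tajima_d(theta_pi, s, n_eff)


@dataclass
class PopGenTrack:
    """Per-window statistics for one pool (pi/theta_w/D) or lineage (D_XY).

    Windows are the scan's windows; undefined entries are NaN.  Values are
    per-variant-site averages except ``theta_w`` and the D components, which
    are window totals entering Tajima's D.
    """

    unit: str
    windows: WindowSet
    pi: np.ndarray | None = None  # (W,) mean site pi
    theta_w: np.ndarray | None = None  # (W,) S / a1(n)
    tajima: np.ndarray | None = None  # (W,)
    dxy: np.ndarray | None = None  # (W,) mean over sites and pool pairs
    n_eff: np.ndarray | None = None  # (W,) mean per-site effective sample size

    def to_dataframe(self) -> pd.DataFrame:
        df = self.windows.to_dataframe()[["scaffold", "span_start", "span_end"]]
        df.insert(0, "unit", self.unit)
        for name in ("pi", "theta_w", "tajima", "dxy", "n_eff"):
            v = getattr(self, name)
            if v is not None:
                df[name] = v
        return df

    def to_tsv(self, path: str | Path) -> None:
        # header comment records the per-variant-site (not per-bp) convention
        with open(path, "w") as fh:
            fh.write("# pi and dxy are averages over the window's variant "
                     "sites, not per-bp\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False,
                                       float_format="%.10g")


def _window_site_slices(snps: SnpTable, windows: WindowSet) -> list[np.ndarray]:
    """Row indices of ``snps`` inside each window's genomic span."""
    seg = {s: (lo, hi) for s, lo, hi in snps.scaffold_segments()}
    out = []
    for i in range(len(windows)):
        scaffold = str(windows.scaffold[i])
        if scaffold not in seg:
            out.append(np.empty(0, dtype=int))
            continue
        lo, hi = seg[scaffold]
        pos = snps.position[lo:hi]
        a = np.searchsorted(pos, windows.span_start[i], side="left")
        b = np.searchsorted(pos, windows.span_end[i], side="right")
        out.append(np.arange(lo + a, lo + b))
    return out


def pool_track(snps: SnpTable, windows: WindowSet, pool: str) -> PopGenTrack:
    """pi, Watterson's theta and Tajima's D per window for one pool."""
    j = snps.pool_names.index(pool)
    minor = snps.minor_count[:, j].astype(float)
    major = snps.major_count[:, j].astype(float)
    cov = minor + major
    hap = snps.pools[j].haploid_pool_size
    neff_site = np.minimum(cov, hap)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(cov > 0, minor / np.where(cov > 0, cov, 1), np.nan)
        pi_site = np.where(cov >= 2, cov / (cov - 1.0) * 2.0 * p * (1.0 - p),
                           np.nan)
    seg_site = (minor > 0) & (major > 0)

    slices = _window_site_slices(snps, windows)
    W = len(windows)
    pi = np.full(W, np.nan)
    theta_w = np.full(W, np.nan)
    taj = np.full(W, np.nan)
    neff = np.full(W, np.nan)
    for w, idx in enumerate(slices):
        if idx.size == 0:
            continue
        pi[w] = np.nanmean(pi_site[idx])
        neff[w] = float(neff_site[idx].mean())
        n = int(np.floor(neff[w]))
        s = int(seg_site[idx].sum())
        if n >= 2 and s >= 1:
            theta_w[w] = s / tajima_constants(n)["a1"]
        taj[w] = tajima_d(float(np.nansum(pi_site[idx])), s, n)
    return PopGenTrack(unit=pool, windows=windows, pi=pi, theta_w=theta_w,
                       tajima=taj, n_eff=neff)


def dxy_track(snps: SnpTable, windows: WindowSet,
              anad: Sequence[str] | None = None,
              fresh: Sequence[str] | None = None) -> PopGenTrack:
    """Window D_XY averaged over all anadromous x freshwater pool pairs."""
    if anad is None:
        anad = [p.name for p in snps.pools if p.life_history == "anadromous"]
    if fresh is None:
        fresh = [p.name for p in snps.pools if p.life_history == "freshwater"]
    cols = {p.name: k for k, p in enumerate(snps.pools)}
    freqs = snps.freqs
    pair_dxy = []
    for an in anad:
        for fn in fresh:
            p1 = freqs[:, cols[an]]
            p2 = freqs[:, cols[fn]]
            pair_dxy.append(p1 * (1 - p2) + p2 * (1 - p1))
    site_mean = np.mean(pair_dxy, axis=0)

    slices = _window_site_slices(snps, windows)
    dxy = np.full(len(windows), np.nan)
    for w, idx in enumerate(slices):
        if idx.size:
            dxy[w] = float(site_mean[idx].mean())
    return PopGenTrack(unit=f"{snps.lineage}:anad-fresh", windows=windows,
                       dxy=dxy)


@dataclass(frozen=True)
class ContrastSummary:
    """Outlier vs non-outlier window contrast for one statistic."""

    statistic: str
    n_outlier: int
    n_background: int
    mean_outlier: float
    mean_background: float
    u_statistic: float
    p_value: float  # NaN when a partition is empty


def contrast_outliers(track: PopGenTrack,
                      regions: Sequence[OutlierRegion]) -> list[ContrastSummary]:
    """Compare each defined statistic between outlier and background windows.

    A window is an outlier window when its span intersects any outlier region;
    significance is a two-sided Mann-Whitney U test.
    """
    w = track.windows
    in_outlier = np.zeros(len(w), dtype=bool)
    per: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        per.setdefault(r.scaffold, []).append((r.start, r.end))
    for i in range(len(w)):
        for lo, hi in per.get(str(w.scaffold[i]), ()):
            if w.span_start[i] <= hi and lo <= w.span_end[i]:
                in_outlier[i] = True
                break

    out: list[ContrastSummary] = []
    for name in ("pi", "theta_w", "tajima", "dxy"):
        values = getattr(track, name)
        if values is None:
            continue
        ok = ~np.isnan(values)
        x = values[ok & in_outlier]
        y = values[ok & ~in_outlier]
        if len(x) == 0 or len(y) == 0:
            warnings.warn(
                f"contrast_outliers({track.unit}/{name}): a partition is "
                "empty; p undefined",
                stacklevel=2,
            )
            out.append(ContrastSummary(name, len(x), len(y),
                                       float(np.mean(x)) if len(x) else float("nan"),
                                       float(np.mean(y)) if len(y) else float("nan"),
                                       float("nan"), float("nan")))
            continue
        u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        out.append(ContrastSummary(name, len(x), len(y), float(np.mean(x)),
                                   float(np.mean(y)), float(u), float(p)))
    return out
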