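"""Cross-lineage convergence: dAF heat maps and the shared-nonsynonymous test.

The heat map takes one lineage's 99.9th-percentile outlier windows and, for
each window's genomic span, averages the standardized per-SNP dAF (mean z) of
every lineage's SNPs falling in that span.  A cell whose span holds fewer
than two SNPs in that lineage is excluded (marked NA), since a one-SNP mean
is not a window statistic.

The shared-nonsynonymous test asks, for sites that are nonsynonymous in both
of two lineages (matched by scaffold and position; effect tables carry no
allele phase, so matching is positional), whether the site's per-site mean z
reaches the 95th nearest-rank percentile of mean z over *all* nonsynonymous
sites within each lineage — and counts the sites extreme in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import EffectRecord
from .permutation import nearest_rank
from .scan import DeltaAFTable, WindowSet

__all__ = [
    "ConvergenceMatrix",
    "SharedNonsynReport",
    "heatmap_matrix",
    "shared_nonsyn_test",
]

EXCLUDED_MARKER = "NA:lt2snps"


@dataclass
class ConvergenceMatrix:
    """Mean standardized dAF of each lineage inside one lineage's outlier spans.

    ``values[w, l]`` is lineage ``lineages[l]``'s mean z over SNPs in window
    ``w``'s span; ``excluded[w, l]`` marks cells backed by < ``min_snps``
    SNPs (their value is NaN).
    """

    target_lineage: str
    windows: WindowSet  # the target's 99.9th-percentile outlier windows
    lineages: list[str]
    values: np.ndarray  # (W, L)
    excluded: np.ndarray  # (W, L) bool
    min_snps: int = 2

    def to_dataframe(self) -> pd.DataFrame:
        df = self.windows.to_dataframe()[["scaffold", "span_start", "span_end"]]
        for l, name in enumerate(self.lineages):
            col = [
                EXCLUDED_MARKER if self.excluded[w, l] else f"{self.values[w, l]:.10g}"
                for w in range(len(self.windows))
            ]
            df[name] = col
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def plot(self, path: str | Path) -> None:
        """Optional heat-map image (excluded cells hatched grey)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(2 + 0.8 * len(self.lineages),
                     1 + 0.12 * max(len(self.windows), 8))
        )
        masked = np.ma.masked_array(self.values, mask=self.excluded)
        im = ax.imshow(masked, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(self.lineages)), self.lineages, rotation=45)
        ax.set_ylabel(f"{self.target_lineage} outlier windows (99.9th pct)")
        fig.colorbar(im, ax=ax, label="mean standardized dAF")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _window_means(daf: DeltaAFTable, windows: WindowSet,
                  min_snps: int) -> tuple[np.ndarray, np.ndarray]:
    seg = {s: (lo, hi) for s, lo, hi in daf.scaffold_segments()}
    W = len(windows)
    vals = np.full(W, np.nan)
    excl = np.ones(W, dtype=bool)
    for i in range(W):
        scaffold = str(windows.scaffold[i])
        if scaffold not in seg:
            continue
        lo, hi = seg[scaffold]
        pos = daf.position[lo:hi]
        a = np.searchsorted(pos, windows.span_start[i], side="left")
        b = np.searchsorted(pos, windows.span_end[i], side="right")
        if b - a >= min_snps:
            vals[i] = float(daf.mean_z[lo + a:lo + b].mean())
            excl[i] = False
    return vals, excl


def heatmap_matrix(
    target_lineage: str,
    target_outliers: WindowSet,
    lineage_daf: Mapping[str, DeltaAFTable],
    min_snps: int = 2,
) -> ConvergenceMatrix:
    """Build the cross-lineage matrix for one target lineage's outlier windows.

    ``lineage_daf`` maps every lineage (the target included) to its
    standardized per-SNP table; the target column reproduces the scan's
    window statistics because the same SNPs fall in the same spans.
    """
    if target_lineage not in lineage_daf:
        raise KeyError(f"target lineage {target_lineage!r} missing from lineage_daf")
    lineages = list(lineage_daf)
    W = len(target_outliers)
    if W == 0:
        warnings.warn(
            f"{target_lineage}: no 99.9th-percentile outlier windows; "
            "empty convergence matrix",
            stacklevel=2,
        )
    values = np.full((W, len(lineages)), np.nan)
    excluded = np.ones((W, len(lineages)), dtype=bool)
    for l, name in enumerate(lineages):
        daf = lineage_daf[name]
        if daf.mean_z is None:
            raise ValueError(f"lineage {name!r}: table is not standardized")
        values[:, l], excluded[:, l] = _window_means(daf, target_outliers, min_snps)
    return ConvergenceMatrix(
        target_lineage=target_lineage,
        windows=target_outliers,
        lineages=lineages,
        values=values,
        excluded=excluded,
        min_snps=min_snps,
    )


@dataclass
class SharedNonsynReport:
    """Shared nonsynonymous sites and which are extreme in both lineages."""

    lineage_pair: tuple[str, str]
    percentile: float
    thresholds: tuple[float, float]  # per-lineage nearest-rank cutoffs
    sites: pd.DataFrame  # scaffold, position, z_a, z_b, top_a, top_b, top_both
    n_shared: int
    n_top_both: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# shared nonsynonymous sites matched by position only "
                "(effect tables carry no allele phase)\n"
            )
            self.sites.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _nonsyn_z(daf: DeltaAFTable, effects: Sequence[EffectRecord]) -> dict:
    nonsyn = {
        (e.scaffold, e.position) for e in effects if e.effect == "nonsynonymous"
    }
    out = {}
    for i in range(daf.n_sites):
        key = (str(daf.scaffold[i]), int(daf.position[i]))
        if key in nonsyn:
            out[key] = float(daf.mean_z[i])
    return out


def shared_nonsyn_test(
    daf_a: DeltaAFTable,
    effects_a: Sequence[EffectRecord],
    daf_b: DeltaAFTable,
    effects_b: Sequence[EffectRecord],
    percentile: float = 95.0,
) -> SharedNonsynReport:
    """Count shared nonsynonymous sites extreme in both lineages.

    The reference distribution for each lineage's percentile cutoff is the
    per-site mean z over all that lineage's nonsynonymous SNPs; a shared site
    passes when its z is >= the cutoff in *both* lineages.  Symmetric in
    lineage order.
    """
    if len(effects_a) == 0 or len(effects_b) == 0:
        raise ValueError("shared_nonsyn_test: empty effect table")
    if daf_a.mean_z is None or daf_b.mean_z is None:
        raise ValueError("shared_nonsyn_test needs standardized tables")
    za = _nonsyn_z(daf_a, effects_a)
    zb = _nonsyn_z(daf_b, effects_b)
    if len(za) == 0 or len(zb) == 0:
        raise ValueError(
            "shared_nonsyn_test: a lineage has no nonsynonymous SNPs"
        )
    thr_a = nearest_rank(np.array(list(za.values())), percentile)
    thr_b = nearest_rank(np.array(list(zb.values())), percentile)

    shared = sorted(set(za) & set(zb))
    rows = []
    for key in shared:
        top_a = za[key] >= thr_a
        top_b = zb[key] >= thr_b
        rows.append(
            {
                "scaffold": key[0],
                "position": key[1],
                "z_a": za[key],
                "z_b": zb[key],
                "top_a": top_a,
                "top_b": top_b,
                "top_both": top_a and top_b,
            }
        )
    sites = pd.DataFrame(
        rows,
        columns=["scaffold", "position", "z_a", "z_b", "top_a", "top_b",
                 "top_both"],
    )
    return SharedNonsynReport(
        lineage_pair=(daf_a.lineage, daf_b.lineage),
        percentile=percentile,
        thresholds=(thr_a, thr_b),
        sites=sites,
        n_shared=len(shared),
        n_top_both=int(sites["top_both"].sum()) if len(sites) else 0,
    )
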