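#!/usr/bin/env python
"""Cross-lineage convergence: dAF heat maps over each lineage's strongest
outlier windows, and the shared-nonsynonymous percentile test.

For every 99.9th-percentile outlier window of a target lineage, the mean
standardized dAF of the other lineage's SNPs in the same genomic span is
tabulated (cells with fewer than two SNPs are excluded).  Shared
nonsynonymous sites whose per-site dAF reaches the 95th percentile of all
nonsynonymous sites in *both* lineages are the convergence candidates.
"""

from pathlib import Path

from poolparallel.convergence import heatmap_matrix, shared_nonsyn_test
from poolparallel.io import read_effects, read_manifest
from poolparallel.pipeline import ScanParams
from poolparallel.scan import load_windows_tsv, pair_daf, standardize
from poolparallel.snps import SnpTable

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = RESULTS / "data"
    manifest = read_manifest(data / "manifest.tsv")
    effects = read_effects(data / "effects.tsv")
    params = ScanParams()
    lineages = sorted({p.lineage for p in manifest})
    daf = {}
    for lineage in lineages:
        snps = SnpTable.from_tsv(RESULTS / f"snps_{lineage}.tsv",
                                 [p for p in manifest if p.lineage == lineage])
        daf[lineage] = standardize(pair_daf(snps))

    for target in lineages:
        outliers = load_windows_tsv(RESULTS / f"windows_{target}.tsv",
                                    outlier_percentile=99.9)
        m = heatmap_matrix(target, outliers, daf,
                           min_snps=params.min_snps_per_cell)
        m.to_tsv(RESULTS / f"heatmap_{target}.tsv")
        m.plot(RESULTS / f"heatmap_{target}.png")
        n_excl = int(m.excluded[:, [i for i, l in enumerate(m.lineages)
                                    if l != target]].sum())
        print(f"{target}: heat map over {len(outliers)} outlier windows "
              f"({n_excl} cross-lineage cells excluded with <2 SNPs)")

    a, b = lineages[0], lineages[1]
    report = shared_nonsyn_test(daf[a], effects, daf[b], effects,
                                percentile=params.nonsyn_percentile)
    report.to_tsv(RESULTS / f"shared_nonsyn_{a}_{b}.tsv")
    print(f"{a} vs {b}: {report.n_shared} shared nonsynonymous sites, "
          f"{report.n_top_both} in the top 5% of dAF in both lineages")


if __name__ == "__main__":
    main()
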