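#!/usr/bin/env python
"""Parallelism within and across lineages.

Within each lineage, every freshwater population gets its own outlier scan
(anadromous pools vs that single population, 99th percentile) and pairs of
populations are scored by the percentage of outlier regions they share;
region sets common to all of a lineage's freshwater populations are the
"complete parallelism" loci.  Across lineages, sharing of polymorphic sites
(position-matched) and of lineage-level outlier regions is reported.
"""

from pathlib import Path

import pandas as pd

from poolparallel.experiments import derive_seed
from poolparallel.io import read_manifest, read_regions_bed, read_scaffold_lengths
from poolparallel.regions import (
    OutlierRegion,
    population_scan,
    shared_across,
    shared_polymorphism,
    shared_regions,
)
from poolparallel.snps import SnpTable, polymorphic_sites

MASTER_SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = RESULTS / "data"
    manifest = read_manifest(data / "manifest.tsv")
    lengths = read_scaffold_lengths(data / "scaffold_lengths.tsv")
    lineages = sorted({p.lineage for p in manifest})
    tables = {
        l: SnpTable.from_tsv(RESULTS / f"snps_{l}.tsv",
                             [p for p in manifest if p.lineage == l])
        for l in lineages
    }

    rows = []
    for lineage, snps in tables.items():
        fresh = [p.name for p in snps.pools if p.life_history == "freshwater"]
        if len(fresh) < 2:
            continue
        pop_regions = {
            fp: population_scan(snps, fp,
                                derive_seed(MASTER_SEED, f"popscan:{fp}"),
                                n_perm=200, percentile=99,
                                scaffold_lengths=lengths)
            for fp in fresh
        }
        for i, a in enumerate(fresh):
            for b in fresh[i + 1:]:
                rep = shared_regions(pop_regions[a], pop_regions[b], (a, b))
                rows.append({"unit_a": a, "unit_b": b, "kind": "regions",
                             "pct": rep.pct_shared_regions,
                             "n_a": rep.n_a, "n_b": rep.n_b})
                print(f"{a} vs {b}: {rep.pct_shared_regions:.1f}% of outlier "
                      f"regions shared ({rep.n_a}/{rep.n_b} regions)")
        loci = shared_across(list(pop_regions.values()))
        print(f"{lineage}: {len(loci)} loci outliers in all "
              f"{len(fresh)} freshwater populations (complete parallelism)")

    # cross-lineage sharing: polymorphism and lineage-level outlier regions
    ref_bases = {}
    for lineage in lineages:
        sync_sites = pd.read_csv(data / f"{lineage}.sync", sep="\t",
                                 header=None, usecols=[0, 1, 2],
                                 names=["scaffold", "position", "ref"])
        ref_bases[lineage] = {
            (str(s), int(p)): str(r)
            for s, p, r in sync_sites.itertuples(index=False)
        }
    poly = {l: polymorphic_sites(tables[l], ref_bases[l]) for l in lineages}
    for i, a in enumerate(lineages):
        for b in lineages[i + 1:]:
            pct_poly = shared_polymorphism(poly[a], poly[b], (a, b))
            regions = {
                l: [OutlierRegion(s, st, e) for s, st, e, _n, _sc in
                    read_regions_bed(RESULTS / f"regions_{l}_99.bed")]
                for l in (a, b)
            }
            rep = shared_regions(regions[a], regions[b], (a, b))
            rows.append({"unit_a": a, "unit_b": b, "kind": "polymorphism",
                         "pct": pct_poly, "n_a": len(poly[a]),
                         "n_b": len(poly[b])})
            rows.append({"unit_a": a, "unit_b": b, "kind": "regions",
                         "pct": rep.pct_shared_regions,
                         "n_a": rep.n_a, "n_b": rep.n_b})
            print(f"{a} vs {b}: {pct_poly:.1f}% shared polymorphism, "
                  f"{rep.pct_shared_regions:.1f}% shared outlier regions")

    pd.DataFrame(rows).to_csv(RESULTS / "parallelism.tsv", sep="\t",
                              index=False, float_format="%.10g")


if __name__ == "__main__":
    main()
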