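#!/usr/bin/env python
"""Call and filter SNPs per lineage from the simulated sync files.

Applies the count-level filters (biallelic within the lineage, pooled minor
count >= 4, every pool's coverage in [10, 2x its genome-wide mean]) and
writes one SNP table per lineage under results/.
"""

from pathlib import Path

from poolparallel.io import read_manifest, read_sync
from poolparallel.pipeline import ScanParams, build_snp_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = RESULTS / "data"
    manifest = read_manifest(data / "manifest.tsv")
    params = ScanParams()
    for lineage in sorted({p.lineage for p in manifest}):
        pools = [p for p in manifest if p.lineage == lineage]
        sites = read_sync(data / f"{lineage}.sync", pools)
        snps = build_snp_table(sites, pools, params)
        snps.to_tsv(RESULTS / f"snps_{lineage}.tsv")
        kept = 100 * snps.n_sites / len(sites)
        print(f"{lineage}: {snps.n_sites}/{len(sites)} sites retained "
              f"({kept:.1f}%) across {len(pools)} pools")


if __name__ == "__main__":
    main()
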