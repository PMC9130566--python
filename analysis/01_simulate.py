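#!/usr/bin/env python
"""Generate the study dataset: two lineages of pooled anadromous/freshwater
populations with six freshwater-selected regions planted at |dAF| = 0.6.

Design: 2 lineages x (2 anadromous + 3 freshwater) pools of 25 diploids,
40,000 SNPs on 10 scaffolds of 1 Mb, ~32x coverage, half the SNP positions
shared between lineages.  The six planted regions are shared by both
lineages (complete parallelism) and their SNPs are labelled nonsynonymous so
the convergence test has a positive control.  Everything downstream reads
the files this writes under results/data/.
"""

from dataclasses import replace
from pathlib import Path

from poolparallel.experiments import derive_seed
from poolparallel.simulate import SimConfig, evenly_planted_regions, simulate

MASTER_SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config(master_seed: int = MASTER_SEED) -> SimConfig:
    base = SimConfig(
        n_lineages=2,
        pools_per_lineage=((2, 3), (2, 3)),
        n_scaffolds=10,
        scaffold_length=1_000_000,
        n_snps=40_000,
        shared_fraction=0.5,
        min_snps_per_region=40,
        force_nonsyn_in_regions=True,
        seed=derive_seed(master_seed, "study-data"),
    )
    return replace(base,
                   planted_regions=evenly_planted_regions(base, 6, 0.6,
                                                          length=20_000))


def main() -> None:
    cfg = study_config()
    ds = simulate(cfg)
    out = RESULTS / "data"
    ds.write(out)
    n_sites = {l: len(d.position) for l, d in ds.lineages.items()}
    print(f"wrote {out}")
    print(f"simulated SNPs per lineage: {n_sites}")
    print(f"planted regions per lineage: "
          f"{ {l: len(r) for l, r in ds.truth.regions.items()} }")
    print("pools:", ", ".join(p.name for p in ds.manifest))


if __name__ == "__main__":
    main()
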