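import numpy as np
import pytest

from poolparallel.io import PoolInfo, SiteCounts
from poolparallel.pipeline import ScanParams, build_snp_table
from poolparallel.simulate import SimConfig, simulate
from poolparallel.snps import SnpTable, call_snps


@pytest.fixture(scope="session")
def pools_2x2():
    """One lineage, two anadromous and two freshwater pools of 25 diploids."""
    return [
        PoolInfo("an1", "lin", "anadromous", 25),
        PoolInfo("an2", "lin", "anadromous", 25),
        PoolInfo("fw1", "lin", "freshwater", 25),
        PoolInfo("fw2", "lin", "freshwater", 25),
    ]


def make_sites(rng, pools, n_sites=500, n_scaffolds=3, scaffold_length=100_000,
               coverage=30):
    """Random biallelic count data that mostly passes the SNP filters."""
    sites = []
    positions = {}
    for s in range(n_scaffolds):
        pos = np.sort(rng.choice(scaffold_length, size=n_sites // n_scaffolds,
                                 replace=False)) + 1
        positions[f"scaf{s + 1}"] = pos
    for scaffold, pos_arr in positions.items():
        for pos in pos_arr:
            freq = rng.beta(0.8, 0.8)
            row = []
            for _p in pools:
                cov = rng.poisson(coverage)
                alt = rng.binomial(cov, freq)
                row.append((cov - alt, alt, 0, 0, 0, 0))  # A=major, T=alt
            sites.append(SiteCounts(scaffold, int(pos), "A", tuple(row)))
    return sites


@pytest.fixture(scope="session")
def small_snps(pools_2x2):
    """A few hundred filtered SNPs on 3 scaffolds, deterministic."""
    rng = np.random.default_rng(7)
    sites = make_sites(rng, pools_2x2)
    snps = call_snps(sites, pools_2x2)
    assert snps.n_sites > 200
    return snps


@pytest.fixture(scope="session")
def sim_dataset():
    """Small 2-lineage simulated dataset shared by integration tests."""
    cfg = SimConfig(
        n_lineages=2,
        pools_per_lineage=((2, 2), (2, 2)),
        n_scaffolds=4,
        scaffold_length=500_000,
        n_snps=6000,
        shared_fraction=0.5,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def sim_snp_tables(sim_dataset):
    params = ScanParams()
    return {
        name: build_snp_table(lin.site_counts(), lin.pools, params)
        for name, lin in sim_dataset.lineages.items()
    }
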