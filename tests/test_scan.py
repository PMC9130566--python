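import numpy as np
import pytest

from poolparallel.io import PoolInfo
from poolparallel.scan import (
    DeltaAFTable,
    ZeroVarianceError,
    pair_daf,
    standardize,
    window_scan,
)
from poolparallel.snps import SnpTable

from .oracles import brute_force_window_stats


def make_table(freqs, pools, positions=None, scaffold="scaf1"):
    freqs = np.asarray(freqs, dtype=float)
    S = freqs.shape[0]
    positions = np.arange(1, S + 1) * 100 if positions is None else positions
    cov = np.full_like(freqs, 100)
    minor = np.rint(freqs * 100).astype(np.int64)
    return SnpTable(
        lineage="lin", pools=list(pools),
        scaffold=np.array([scaffold] * S, dtype=object),
        position=np.asarray(positions, dtype=np.int64),
        major=np.array(["A"] * S, dtype=object),
        minor=np.array(["T"] * S, dtype=object),
        minor_count=minor,
        major_count=100 - minor,
    )


@pytest.fixture
def pools_1x1():
    return [PoolInfo("an1", "lin", "anadromous", 25),
            PoolInfo("fw1", "lin", "freshwater", 25)]


class TestPairDaf:
    def test_absolute_difference(self, pools_1x1):
        snps = make_table([[0.1, 0.9], [0.5, 0.5], [0.9, 0.1]], pools_1x1)
        daf = pair_daf(snps)
        np.testing.assert_allclose(daf.raw[:, 0], [0.8, 0.0, 0.8])

    def test_pair_count_is_cross_product(self, pools_2x2):
        snps = make_table(np.full((5, 4), 0.5), pools_2x2)
        extra = [PoolInfo("fw3", "lin", "freshwater", 25)]
        snps5 = make_table(np.full((5, 5), 0.5), pools_2x2 + extra)
        assert pair_daf(snps).raw.shape[1] == 4  # 2 x 2
        assert pair_daf(snps5).raw.shape[1] == 6  # 2 x 3

    def test_empty_group_is_fatal(self, pools_1x1):
        snps = make_table([[0.1, 0.9]], pools_1x1)
        with pytest.raises(ValueError, match="each group"):
            pair_daf(snps, anad=[], fresh=["fw1"])

    def test_invariant_to_minor_label_swap(self, pools_1x1):
        snps = make_table([[0.1, 0.9], [0.3, 0.4], [0.8, 0.2]], pools_1x1)
        swapped = make_table(1 - np.column_stack([snps.freqs[:, 0],
                                                  snps.freqs[:, 1]]),
                             pools_1x1)
        np.testing.assert_allclose(pair_daf(snps).raw, pair_daf(swapped).raw)


class TestStandardize:
    def test_hand_computed_z(self, pools_1x1):
        # pair values {0.0, 0.2, 0.4}: mean 0.2, population sd 0.16330
        snps = make_table([[0.5, 0.5], [0.4, 0.6], [0.3, 0.7]], pools_1x1)
        daf = standardize(pair_daf(snps))
        np.testing.assert_allclose(daf.z[:, 0], [-1.224745, 0.0, 1.224745],
                                   atol=1e-6)

    def test_mean_zero_sd_one_by_construction(self, small_snps):
        daf = standardize(pair_daf(small_snps))
        np.testing.assert_allclose(daf.z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(daf.z.std(axis=0), 1.0, atol=1e-12)

    def test_value_at_mean_maps_to_zero(self, pools_1x1):
        snps = make_table([[0.5, 0.5], [0.4, 0.6], [0.3, 0.7]], pools_1x1)
        daf = standardize(pair_daf(snps))
        assert daf.z[1, 0] == 0.0

    def test_zero_variance_names_the_pair(self, pools_1x1):
        # both differences are exactly 0.25 (binary-exact frequencies)
        snps = make_table([[0.25, 0.5], [0.5, 0.75]], pools_1x1)
        with pytest.raises(ZeroVarianceError, match="an1xfw1"):
            standardize(pair_daf(snps))


class TestWindowScan:
    def scan(self, n_snps, pools, window=20, step=10, offset=1, **kw):
        rng = np.random.default_rng(5)
        snps = make_table(rng.uniform(0, 1, size=(n_snps, len(pools))), pools)
        daf = standardize(pair_daf(snps))
        return window_scan(daf, window=window, step=step, offset=offset, **kw)

    def test_35_snps_gives_2_windows(self, pools_2x2):
        ws = self.scan(35, pools_2x2)
        assert len(ws) == 2
        assert list(ws.snp_start_index) == [1, 11]

    def test_19_snps_gives_no_windows(self, pools_2x2):
        assert len(self.scan(19, pools_2x2)) == 0

    def test_constant_signal_gives_constant_windows(self, pools_2x2):
        snps = make_table(np.full((40, 4), 0.5), pools_2x2)
        daf = pair_daf(snps)
        daf.z = np.tile(np.linspace(-1, 1, 40)[:, None], (1, 4))
        daf.mean_z = np.full(40, 0.75)
        ws = window_scan(daf)
        np.testing.assert_allclose(ws.stat, 0.75)

    def test_top_scaffold_restriction(self, pools_2x2):
        rng = np.random.default_rng(5)
        freqs = rng.uniform(0, 1, size=(60, 4))
        snps_a = make_table(freqs[:30], pools_2x2, scaffold="big")
        snps_b = make_table(freqs[30:], pools_2x2, scaffold="small")
        merged = SnpTable(
            lineage="lin", pools=list(pools_2x2),
            scaffold=np.concatenate([snps_a.scaffold, snps_b.scaffold]),
            position=np.concatenate([snps_a.position, snps_b.position]),
            major=np.concatenate([snps_a.major, snps_b.major]),
            minor=np.concatenate([snps_a.minor, snps_b.minor]),
            minor_count=np.vstack([snps_a.minor_count, snps_b.minor_count]),
            major_count=np.vstack([snps_a.major_count, snps_b.major_count]),
        )
        daf = standardize(pair_daf(merged))
        ws = window_scan(daf, top_scaffolds=1,
                         scaffold_lengths={"big": 10_000, "small": 500})
        assert set(ws.scaffold) == {"big"}

    def test_matches_brute_force_oracle(self, small_snps):
        daf = standardize(pair_daf(small_snps))
        ws = window_scan(daf)
        expected = brute_force_window_stats(small_snps)
        got = {}
        for w in ws:
            got.setdefault(w.scaffold, []).append(
                (w.snp_start_index, w.span, w.stat))
        assert set(got) == {s for s, rows in expected.items() if rows}
        for scaffold, rows in got.items():
            exp = expected[scaffold]
            assert len(rows) == len(exp)
            for (gi, gs, gstat), (ei, es, estat) in zip(rows, exp):
                assert gi == ei and gs == es
                assert gstat == pytest.approx(estat, abs=1e-12)

    def test_pool_order_within_group_is_irrelevant(self, small_snps):
        daf1 = standardize(pair_daf(small_snps))
        reordered = small_snps.subset_pools(["an2", "an1", "fw2", "fw1"])
        daf2 = standardize(pair_daf(reordered))
        ws1, ws2 = window_scan(daf1), window_scan(daf2)
        np.testing.assert_allclose(ws1.stat, ws2.stat, atol=1e-14)

    def test_offset_shifts_window_grid(self, pools_2x2):
        ws = self.scan(45, pools_2x2, offset=6)
        assert list(ws.snp_start_index) == [6, 16, 26]
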