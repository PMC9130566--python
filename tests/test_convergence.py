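import numpy as np
import pytest

from poolparallel.convergence import (
    EXCLUDED_MARKER,
    heatmap_matrix,
    shared_nonsyn_test,
)
from poolparallel.io import EffectRecord
from poolparallel.scan import DeltaAFTable, WindowSet

from .oracles import brute_force_shared_nonsyn_count


def make_daf(lineage, positions, mean_z, scaffold="s"):
    positions = np.asarray(positions, dtype=np.int64)
    mean_z = np.asarray(mean_z, dtype=float)
    return DeltaAFTable(
        lineage=lineage,
        scaffold=np.array([scaffold] * len(positions), dtype=object),
        position=positions,
        pairs=[("a", "f")],
        raw=np.abs(mean_z)[:, None],
        z=mean_z[:, None],
        mean_z=mean_z,
    )


def make_windows(spans, stats=None):
    stats = stats if stats is not None else np.ones(len(spans))
    return WindowSet(["s"] * len(spans), np.arange(1, len(spans) + 1),
                     [a for a, _ in spans], [b for _, b in spans], 20, stats)


class TestHeatmapMatrix:
    def test_cell_is_mean_of_other_lineages_snps(self):
        target = make_daf("T", [100, 200, 300], [2.0, 2.0, 2.0])
        other = make_daf("O", [150, 250], [1.0, 3.0])
        windows = make_windows([(100, 300)], np.array([2.0]))
        m = heatmap_matrix("T", windows, {"T": target, "O": other})
        j = m.lineages.index("O")
        assert not m.excluded[0, j]
        assert m.values[0, j] == pytest.approx(2.0)

    def test_fewer_than_two_snps_excluded(self):
        target = make_daf("T", [100, 200, 300], [2.0, 2.0, 2.0])
        other = make_daf("O", [150, 999_000], [1.0, 3.0])  # 1 SNP in span
        windows = make_windows([(100, 300)])
        m = heatmap_matrix("T", windows, {"T": target, "O": other})
        j = m.lineages.index("O")
        assert m.excluded[0, j]
        assert np.isnan(m.values[0, j])
        assert EXCLUDED_MARKER in m.to_dataframe()["O"].iloc[0]

    def test_target_column_reproduces_window_stats(self, small_snps):
        from poolparallel.scan import pair_daf, standardize, window_scan

        daf = standardize(pair_daf(small_snps))
        windows = window_scan(daf)
        m = heatmap_matrix("lin", windows, {"lin": daf})
        j = m.lineages.index("lin")
        np.testing.assert_allclose(m.values[:, j], windows.stat, atol=1e-12)

    def test_invariant_to_snp_order_within_span(self):
        windows = make_windows([(100, 300)])
        target = make_daf("T", [100, 200, 300], [2.0, 2.0, 2.0])
        a = make_daf("O", [150, 250], [1.0, 3.0])
        m1 = heatmap_matrix("T", windows, {"T": target, "O": a})
        # same sites, supplied in a different underlying order -> same cell
        b = make_daf("O", [250, 150], [3.0, 1.0])
        order = np.argsort(b.position)
        b = make_daf("O", b.position[order], b.mean_z[order])
        m2 = heatmap_matrix("T", windows, {"T": target, "O": b})
        np.testing.assert_allclose(m1.values, m2.values)

    def test_no_outlier_windows_warns(self):
        target = make_daf("T", [100], [1.0])
        with pytest.warns(UserWarning, match="no 99.9"):
            m = heatmap_matrix("T", make_windows([]), {"T": target})
        assert m.values.shape[0] == 0


class TestSharedNonsynTest:
    def build(self, za, zb, rng=None, n_other=30):
        """Two lineages sharing 40 nonsynonymous sites plus private ones."""
        rng = rng or np.random.default_rng(0)
        shared_pos = np.arange(1000, 1000 + 40 * 10, 10)
        priv_a = np.arange(50_000, 50_000 + n_other * 7, 7)
        priv_b = np.arange(90_000, 90_000 + n_other * 7, 7)
        pos_a = np.concatenate([shared_pos, priv_a])
        pos_b = np.concatenate([shared_pos, priv_b])
        z_priv_a = rng.normal(size=n_other)
        z_priv_b = rng.normal(size=n_other)
        daf_a = make_daf("A", pos_a, np.concatenate([za, z_priv_a]))
        daf_b = make_daf("B", pos_b, np.concatenate([zb, z_priv_b]))
        eff_a = [EffectRecord("s", int(p), "nonsynonymous") for p in pos_a]
        eff_b = [EffectRecord("s", int(p), "nonsynonymous") for p in pos_b]
        return daf_a, eff_a, daf_b, eff_b

    def test_counts_match_exhaustive_brute_force(self):
        rng = np.random.default_rng(42)
        za = rng.normal(size=40)
        zb = rng.normal(size=40)
        daf_a, eff_a, daf_b, eff_b = self.build(za, zb, rng)
        report = shared_nonsyn_test(daf_a, eff_a, daf_b, eff_b, percentile=95)
        sites_a = {(str(daf_a.scaffold[i]), int(daf_a.position[i])):
                   float(daf_a.mean_z[i]) for i in range(daf_a.n_sites)}
        sites_b = {(str(daf_b.scaffold[i]), int(daf_b.position[i])):
                   float(daf_b.mean_z[i]) for i in range(daf_b.n_sites)}
        expected = brute_force_shared_nonsyn_count(sites_a, sites_b, 95)
        assert report.n_shared == 40
        assert report.n_top_both == expected

    def test_site_extreme_in_one_lineage_only_not_counted(self):
        za = np.zeros(40)
        zb = np.zeros(40)
        za[0] = 100.0  # top of A only; B's top site is elsewhere
        zb[1] = 100.0
        daf_a, eff_a, daf_b, eff_b = self.build(za, zb)
        report = shared_nonsyn_test(daf_a, eff_a, daf_b, eff_b, percentile=95)
        df = report.sites
        row0 = df[df.position == 1000].iloc[0]
        assert row0.top_a and not row0.top_b and not row0.top_both

    def test_site_extreme_in_both_is_counted(self):
        za = np.zeros(40)
        zb = np.zeros(40)
        za[0] = zb[0] = 100.0
        daf_a, eff_a, daf_b, eff_b = self.build(za, zb)
        report = shared_nonsyn_test(daf_a, eff_a, daf_b, eff_b, percentile=95)
        assert report.n_top_both >= 1
        assert bool(report.sites[report.sites.position == 1000].top_both.iloc[0])

    def test_symmetric_in_lineage_order(self):
        rng = np.random.default_rng(9)
        daf_a, eff_a, daf_b, eff_b = self.build(rng.normal(size=40),
                                                rng.normal(size=40), rng)
        r1 = shared_nonsyn_test(daf_a, eff_a, daf_b, eff_b)
        r2 = shared_nonsyn_test(daf_b, eff_b, daf_a, eff_a)
        assert r1.n_top_both == r2.n_top_both
        assert r1.n_shared == r2.n_shared

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(10)
        daf_a, eff_a, daf_b, eff_b = self.build(rng.normal(size=40),
                                                rng.normal(size=40), rng)
        counts = [
            shared_nonsyn_test(daf_a, eff_a, daf_b, eff_b, percentile=p).n_top_both
            for p in (50, 75, 90, 95, 99)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_effect_table_is_fatal(self):
        daf_a, eff_a, daf_b, eff_b = self.build(np.zeros(40), np.zeros(40))
        with pytest.raises(ValueError, match="empty effect table"):
            shared_nonsyn_test(daf_a, [], daf_b, eff_b)
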