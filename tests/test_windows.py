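"""Sliding-window smoothing, top-fraction thresholding and region calls."""

import math

import numpy as np
import pytest

from csscan.model import SnpMap
from csscan.windows import (
    WindowSpec,
    call_clusters,
    count_concordance,
    significant_snps,
    smooth,
)


def make_map(positions, chroms=None):
    positions = list(positions)
    chroms = chroms or ["1"] * len(positions)
    return SnpMap.from_arrays(
        [f"s{i}" for i in range(len(positions))], chroms, positions
    )


def brute_smooth(values, snp_map, spec):
    """O(n^2) oracle: closed +/-half-width window mean per SNP."""
    out = np.full(len(values), np.nan)
    counts = np.zeros(len(values), dtype=int)
    for j in range(len(values)):
        members = [
            i
            for i in range(len(values))
            if snp_map.chrom[i] == snp_map.chrom[j]
            and abs(int(snp_map.pos_bp[i]) - int(snp_map.pos_bp[j])) <= spec.half_width_bp
            and np.isfinite(values[i])
        ]
        counts[j] = len(members)
        if len(members) >= spec.min_snps:
            out[j] = np.mean([values[i] for i in members])
    return out, counts


class TestSmooth:
    def test_constant_input(self):
        snp_map = make_map(np.arange(1, 12) * 100_000)
        sm, n = smooth(np.full(11, 3.25), snp_map)
        assert np.nanmax(sm) == np.nanmin(sm) == 3.25

    def test_sparse_window_pruned(self):
        # only 4 SNPs within half a window of each other: all pruned
        snp_map = make_map([1, 100_001, 200_001, 300_001])
        sm, n = smooth(np.ones(4), snp_map)
        assert np.isnan(sm).all()
        assert (n == 4).all()

    def test_matches_brute_force(self, rng):
        spec = WindowSpec()
        positions = np.sort(rng.choice(np.arange(1, 40_000_000), 1000, replace=False))
        snp_map = make_map(positions)
        values = rng.normal(size=1000)
        values[rng.choice(1000, 20, replace=False)] = np.nan
        sm, n = smooth(values, snp_map, spec)
        want, want_n = brute_smooth(values, snp_map, spec)
        np.testing.assert_allclose(sm, want, atol=1e-10)
        np.testing.assert_array_equal(n, want_n)

    def test_mean_preserved_on_dense_uniform_chromosome(self, rng):
        positions = np.arange(1, 2001) * 20_000  # 50 SNPs per window
        snp_map = make_map(positions)
        values = rng.normal(size=2000)
        sm, _ = smooth(values, snp_map)
        assert np.nanmean(sm) == pytest.approx(values.mean(), abs=0.05)

    def test_chromosomes_do_not_leak(self):
        snp_map = make_map([1000] * 0 + [1000, 2000, 3000, 1000, 2000, 3000],
                           ["1"] * 3 + ["2"] * 3)
        values = np.array([1.0, 1.0, 1.0, 5.0, 5.0, 5.0])
        sm, _ = smooth(values, snp_map, WindowSpec(min_snps=2))
        np.testing.assert_allclose(sm, [1, 1, 1, 5, 5, 5])


class TestSignificantSnps:
    def test_top_fraction_count(self, rng):
        x = rng.normal(size=39_000)
        sig = significant_snps(x)
        assert len(sig) == 39 == math.ceil(0.001 * 39_000)

    def test_matches_full_sort(self, rng):
        x = rng.normal(size=10_000)
        sig = significant_snps(x)
        want = np.sort(np.argsort(x)[-10:])
        np.testing.assert_array_equal(sig, want)

    def test_ties_broken_by_genome_order(self):
        x = np.full(5000, 1.0)
        sig = significant_snps(x)
        np.testing.assert_array_equal(sig, np.arange(5))

    def test_pruned_excluded_from_basis(self, rng):
        x = rng.normal(size=2000)
        x[1000:] = np.nan
        sig = significant_snps(x)
        assert len(sig) == 1  # ceil(0.001 * 1000)
        assert sig[0] == np.nanargmax(x)

    def test_small_input_keeps_at_least_one(self):
        assert len(significant_snps(np.array([1.0, 3.0, 2.0]))) == 1


MB = 1_000_000


class TestCallClusters:
    def run(self, positions, values, sig_idx, chroms=None, spec=None):
        snp_map = make_map(positions, chroms)
        return call_clusters(np.asarray(sig_idx), np.asarray(values, dtype=float),
                             snp_map, spec or WindowSpec())

    def test_single_cluster_with_padding(self):
        # 3 significant SNPs at 10.0 / 10.2 / 10.4 Mb -> one cluster,
        # region adds 0.5 Mb on each side
        pos = [int(10.0 * MB), int(10.2 * MB), int(10.4 * MB)]
        regions = self.run(pos, [5.0, 9.0, 6.0], [0, 1, 2])
        assert len(regions) == 1
        r = regions[0]
        assert (r.cluster_start_bp, r.cluster_end_bp) == (pos[0], pos[2])
        assert (r.region_start_bp, r.region_end_bp) == (int(9.5 * MB), int(10.9 * MB))
        assert r.core_snp_id == "s1" and r.n_members == 3

    def test_nearby_clusters_merged(self):
        # clusters ending at 5.0 Mb and starting at 5.8 Mb: gap 0.8 Mb < 1 Mb
        pos = [int(4.6 * MB), int(4.8 * MB), int(5.0 * MB),
               int(5.8 * MB), int(6.0 * MB), int(6.2 * MB)]
        regions = self.run(pos, [7, 8, 7, 6, 9, 6], list(range(6)))
        assert len(regions) == 1
        assert regions[0].n_members == 6
        assert regions[0].core_snp_id == "s4"  # more extreme of the two cores

    def test_isolated_pairs_dropped(self):
        pos = [1 * MB, int(1.1 * MB), 11 * MB]
        regions = self.run(pos, [5, 5, 9], [0, 1, 2])
        assert regions == []

    def test_region_floor_at_one(self):
        pos = [100_000, 200_000, 300_000]
        regions = self.run(pos, [1, 2, 3], [0, 1, 2])
        assert regions[0].region_start_bp == 1

    def test_merged_clusters_respect_gap(self, rng):
        positions = np.sort(rng.choice(np.arange(1, 80 * MB), 4000, replace=False))
        values = rng.normal(size=4000)
        sig = significant_snps(np.where(np.isfinite(values), values, np.nan),
                               WindowSpec(top_fraction=0.01))
        regions = self.run(positions, values, sig,
                           spec=WindowSpec(min_cluster_snps=1))
        for a, b in zip(regions, regions[1:]):
            if a.chrom == b.chrom:
                assert b.cluster_start_bp - a.cluster_end_bp >= MB

    def test_larger_top_fraction_keeps_cores(self, rng):
        positions = np.sort(rng.choice(np.arange(1, 50 * MB), 3000, replace=False))
        snp_map = make_map(positions)
        values = rng.normal(size=3000)
        spec_small = WindowSpec(top_fraction=0.005, min_cluster_snps=1)
        spec_big = WindowSpec(top_fraction=0.02, min_cluster_snps=1)
        cores_small = {
            r.core_snp_id
            for r in call_clusters(significant_snps(values, spec_small), values,
                                   snp_map, spec_small)
        }
        cores_big_members = {
            sid
            for r in call_clusters(significant_snps(values, spec_big), values,
                                   snp_map, spec_big)
            for sid in r.member_snp_ids
        }
        assert cores_small <= cores_big_members


class TestConcordance:
    def test_counts_match_interval_scan(self, rng):
        positions = np.sort(rng.choice(np.arange(1, 30 * MB), 800, replace=False))
        snp_map = make_map(positions)
        values = rng.normal(size=800)
        sig = significant_snps(values, WindowSpec(top_fraction=0.02))
        regions = call_clusters(sig, values, snp_map, WindowSpec(min_cluster_snps=1))
        per_test = {
            "FST": rng.choice(800, 40, replace=False),
            "XPEHH": np.array([], dtype=int),
        }
        count_concordance(regions, per_test, snp_map)
        for r in regions:
            for test, idx in per_test.items():
                want = sum(
                    1
                    for i in idx
                    if snp_map.chrom[i] == r.chrom
                    and r.region_start_bp <= snp_map.pos_bp[i] <= r.region_end_bp
                )
                assert r.n_sig[test] == want
            assert r.n_sig["XPEHH"] == 0
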