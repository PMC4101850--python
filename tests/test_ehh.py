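"""EHH decay and XP-EHH: examples, invariants and oracle equivalence."""

import itertools

import numpy as np
import pytest

from csscan.ehh import ehh_at, integrated_ehh, xpehh_per_snp, xpehh_scan
from csscan.model import GroupAssignment, HaplotypePanel, REFERENCE, SELECTED, SnpMap


def brute_ehh(haps, core, boundary):
    """Direct pair enumeration: identical-over-interval pairs / all pairs."""
    lo, hi = sorted((core, boundary))
    pairs = list(itertools.combinations(range(haps.shape[0]), 2))
    same = sum(1 for i, j in pairs if np.array_equal(haps[i, lo:hi + 1], haps[j, lo:hi + 1]))
    return same / len(pairs)


def brute_integrated(haps, core, positions, truncation=0.05, max_ext=1_000_000):
    """Independent trapezoid oracle with the same stopping semantics:
    stop a side at the chromosome end, past the maximum extension, or
    after including the first below-truncation SNP."""
    if haps.shape[0] < 2:
        return 0.0
    total = 0.0
    e0 = brute_ehh(haps, core, core)
    for step in (-1, 1):
        prev_x, prev_y = 0.0, e0
        k = core + step
        while 0 <= k < len(positions) and abs(positions[k] - positions[core]) <= max_ext:
            x = abs(positions[k] - positions[core])
            y = brute_ehh(haps, core, k)
            total += 0.5 * (prev_y + y) * (x - prev_x)
            prev_x, prev_y = x, y
            if y < truncation:
                break
            k += step
    return total


def single_chrom_map(positions):
    return SnpMap.from_arrays(
        [f"s{i}" for i in range(len(positions))],
        ["1"] * len(positions),
        positions,
    )


class TestEhhAt:
    def test_single_class_is_one(self):
        haps = np.tile(np.array([1, 0, 1], dtype=np.uint8), (4, 1))
        assert ehh_at(haps, 1, 1) == 1.0
        assert ehh_at(haps, 0, 2) == 1.0

    def test_partial_sharing(self):
        # classes of sizes {2, 1}: one homozygous pair of C(3,2)=3
        haps = np.array([[0, 1], [0, 1], [1, 1]], dtype=np.uint8)
        assert ehh_at(haps, 0, 1) == pytest.approx(1 / 3)

    def test_all_distinct_is_zero(self):
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        assert ehh_at(haps, 0, 1) == 0.0

    def test_fewer_than_two_haplotypes_undefined(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            ehh_at(np.zeros((1, 3), dtype=np.uint8), 0, 0)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(60):
            k = rng.integers(2, 11)
            n = rng.integers(1, 21)
            haps = rng.integers(0, 2, size=(k, n)).astype(np.uint8)
            core = int(rng.integers(0, n))
            boundary = int(rng.integers(0, n))
            assert ehh_at(haps, core, boundary) == pytest.approx(
                brute_ehh(haps, core, boundary), abs=1e-12
            )

    def test_invariant_to_row_order_and_allele_relabel(self, rng):
        haps = rng.integers(0, 2, size=(8, 12)).astype(np.uint8)
        val = ehh_at(haps, 3, 9)
        assert ehh_at(haps[rng.permutation(8)], 3, 9) == pytest.approx(val)
        assert ehh_at(1 - haps, 3, 9) == pytest.approx(val)

    def test_decay_non_increasing(self, rng):
        haps = rng.integers(0, 2, size=(10, 15)).astype(np.uint8)
        core = 7
        for direction in (-1, 1):
            prev = 1.0
            for step in range(1, 8):
                cur = ehh_at(haps, core, core + direction * step)
                assert cur <= prev + 1e-12
                prev = cur


class TestIntegratedEhh:
    def test_identical_haplotypes_integrate_to_span(self):
        # EHH == 1 everywhere: integral equals the full spanned distance
        positions = [1_000, 51_000, 101_000, 151_000, 201_000]
        haps = np.tile(np.array([0, 1, 0, 1, 1], dtype=np.uint8), (4, 1))
        got = integrated_ehh(haps, 2, single_chrom_map(positions))
        assert got == pytest.approx(200_000.0)

    def test_hand_trapezoid_single_side(self):
        # core + one right SNP at 1000 bp where EHH drops to 0.5 (classes
        # {3,1} of 4): area = (1 + 0.5)/2 * 1000 = 750, no left side
        haps = np.array([[0, 0], [0, 0], [0, 0], [0, 1]], dtype=np.uint8)
        got = integrated_ehh(haps, 0, single_chrom_map([500, 1500]), truncation=0.4)
        assert got == pytest.approx(750.0)

    def test_zero_for_singleton(self):
        haps = np.ones((1, 4), dtype=np.uint8)
        assert integrated_ehh(haps, 1, single_chrom_map([1, 2, 3, 4])) == 0.0

    def test_matches_independent_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 25))
            positions = np.sort(rng.choice(np.arange(1, 2_000_000, 1000), n, replace=False))
            haps = rng.integers(0, 2, size=(8, n)).astype(np.uint8)
            core = int(rng.integers(0, n))
            got = integrated_ehh(haps, core, single_chrom_map(positions))
            want = brute_integrated(haps, core, positions)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-9)


def tiny_panel(rng, n_samples=8, n_snps=30):
    alleles = rng.integers(0, 2, size=(2 * n_samples, n_snps)).astype(np.uint8)
    samples = [f"x{i}" for i in range(n_samples)]
    panel = HaplotypePanel(alleles, tuple(samples))
    groups = GroupAssignment(
        {s: (SELECTED if i < n_samples // 2 else REFERENCE) for i, s in enumerate(samples)}
    )
    positions = np.sort(rng.choice(np.arange(1, 3_000_000, 1000), n_snps, replace=False))
    return single_chrom_map(positions), panel, groups


class TestXpehh:
    def test_identical_group_panels_score_zero(self):
        block = np.array([[0, 1, 0], [1, 1, 0], [0, 0, 1], [1, 0, 1]], dtype=np.uint8)
        panel = HaplotypePanel(np.vstack([block, block]), ("a", "b", "c", "d"))
        groups = GroupAssignment(
            {"a": SELECTED, "b": SELECTED, "c": REFERENCE, "d": REFERENCE}
        )
        snp_map = single_chrom_map([1000, 2000, 3000])
        assert xpehh_per_snp(panel, groups, snp_map, 1) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_group_swap(self, rng):
        snp_map, panel, groups = tiny_panel(rng)
        for core in (5, 15, 25):
            a = xpehh_per_snp(panel, groups, snp_map, core)
            b = xpehh_per_snp(panel, groups.swapped(), snp_map, core)
            assert a == pytest.approx(-b, abs=1e-10)

    def test_scan_equals_per_snp_reference(self, rng):
        snp_map, panel, groups = tiny_panel(rng, n_samples=10, n_snps=40)
        fast = xpehh_scan(panel, groups, snp_map)
        for core in rng.choice(40, size=12, replace=False):
            want = xpehh_per_snp(panel, groups, snp_map, int(core))
            if np.isnan(want):
                assert np.isnan(fast[core])
            else:
                assert fast[core] == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_sweep_elevates_scores_near_locus(self, sweep_scan):
        result, truth = sweep_scan
        t = result.scores
        near = (t["chrom"] == truth.sweep_chrom) & (
            (t["pos_bp"] - truth.sweep_pos_bp).abs() <= 100_000
        )
        assert near.sum() >= 3
        assert t.loc[near, "xpehh"].mean() > t["xpehh"].mean()
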