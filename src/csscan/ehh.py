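"""Extended haplotype homozygosity (EHH) and cross-population XP-EHH.

EHH at a boundary SNP is the probability that two haplotypes drawn at
random from a population are identical over the whole interval from the
core SNP to that boundary. Integrating EHH against physical distance on
both sides of the core gives a length-weighted measure of haplotype
homozygosity; XP-EHH is the log-ratio of that integral between a
SELECTED and a REFERENCE population, computed over identical integration
boundaries so the two integrals are comparable. Long positive scores mark
sweeps that are (near) complete in the SELECTED population.

Two implementations live here. ``ehh_at``/``integrated_ehh``/
``xpehh_per_snp`` are direct, readable single-core routines; they define
the semantics. ``xpehh_scan`` computes the whole genome with prefix-summed
random 64-bit hashes (an interval's haplotype partition in O(1) per
haplotype) and must agree with the reference routines — tests enforce
this equivalence.

EHH here is unconditional: a population's decay is computed from all of
its haplotypes at the core site rather than conditioning on carrying a
particular core allele, matching the cross-population construction where
each population is summarized by one decay curve per SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import GroupAssignment, HaplotypePanel, SnpMap

log = logging.getLogger(__name__)

DEFAULT_TRUNCATION = 0.05
DEFAULT_MAX_EXTENSION_BP = 1_000_000

# Fixed internal seed for the interval-hash weights; not a tuning knob —
# any value gives identical results up to 2^-64 collision probability.
_HASH_SEED = 0xC55C0DE


def ehh_at(haps: np.ndarray, core_index: int, boundary_index: int) -> float:
    """EHH of the interval between core and boundary SNP (inclusive).

    ``haps`` is a (K >= 2, n_snps) 0/1 matrix of one population's
    haplotypes. Partitions haplotypes by their full allele string over
    the interval; with class sizes k_c, returns
    ``sum_c C(k_c, 2) / C(K, 2)``.
    """
    K = haps.shape[0]
    if K < 2:
        raise ValueError("EHH undefined for fewer than 2 haplotypes")
    lo, hi = sorted((core_index, boundary_index))
    _, counts = np.unique(haps[:, lo : hi + 1], axis=0, return_counts=True)
    return float((counts * (counts - 1)).sum() / (K * (K - 1)))


def _chrom_slice(snp_map: SnpMap, core_index: int) -> tuple[np.ndarray, int]:
    """Column indices of the core's chromosome and the core's local index."""
    cols = np.flatnonzero(snp_map.chrom == snp_map.chrom[core_index])
    return cols, int(np.searchsorted(cols, core_index))


def _side_steps(
    positions: np.ndarray, j: int, direction: int, max_extension_bp: float
) -> np.ndarray:
    """Boundary indices walking out from core j (exclusive) on one side,
    limited to the maximum physical extension."""
    n = len(positions)
    steps = []
    k = j + direction
    while 0 <= k < n and abs(int(positions[k]) - int(positions[j])) <= max_extension_bp:
        steps.append(k)
        k += direction
    return np.asarray(steps, dtype=np.intp)


def _integrate_sides(
    haps: np.ndarray,
    stop_haps: np.ndarray,
    positions: np.ndarray,
    j: int,
    truncation: float,
    max_extension_bp: float,
) -> float:
    """Trapezoid integral of EHH (bp x probability) over both sides.

    Stopping on each side is driven by ``stop_haps`` (the same matrix for
    plain integrated EHH, the pooled two-population matrix for XP-EHH):
    extension stops at the chromosome end, beyond ``max_extension_bp``, or
    at the first SNP where the stopping EHH drops below ``truncation``
    (that SNP's trapezoid is still included; EHH is clamped to zero
    beyond it).
    """
    if haps.shape[0] < 2:
        return 0.0
    total = 0.0
    ehh0 = ehh_at(haps, j, j)
    for direction in (-1, +1):
        steps = _side_steps(positions, j, direction, max_extension_bp)
        prev_x, prev_y = 0.0, ehh0
        for k in steps:
            x = abs(float(positions[k]) - float(positions[j]))
            y = ehh_at(haps, j, k)
            total += 0.5 * (prev_y + y) * (x - prev_x)
            prev_x, prev_y = x, y
            if ehh_at(stop_haps, j, k) < truncation:
                break
    return total


def integrated_ehh(
    haps: np.ndarray,
    core_index: int,
    snp_map: SnpMap,
    truncation: float = DEFAULT_TRUNCATION,
    max_extension_bp: float = DEFAULT_MAX_EXTENSION_BP,
    stop_haps: np.ndarray | None = None,
) -> float:
    """Integral of the EHH decay around one core SNP for one population.

    ``haps`` holds the population's haplotypes over *all* SNPs in
    ``snp_map`` order; only the core's chromosome is used. Returns 0 when
    fewer than 2 haplotypes are supplied. ``stop_haps`` optionally drives
    the stopping rule (used by XP-EHH to share boundaries between
    populations); by default the population stops on its own decay.
    """
    if haps.shape[0] < 2:
        return 0.0
    cols, j = _chrom_slice(snp_map, core_index)
    sub = haps[:, cols]
    stop = sub if stop_haps is None else stop_haps[:, cols]
    return _integrate_sides(
        sub, stop, snp_map.pos_bp[cols], j, truncation, max_extension_bp
    )


def xpehh_per_snp(
    panel: HaplotypePanel,
    groups: GroupAssignment,
    snp_map: SnpMap,
    core_index: int,
    truncation: float = DEFAULT_TRUNCATION,
    max_extension_bp: float = DEFAULT_MAX_EXTENSION_BP,
) -> float:
    """Raw XP-EHH log-ratio ln(I_sel / I_ref) at one core SNP.

    Both integrals use the boundaries determined on the pooled panel, so
    the score is antisymmetric under a group swap. Returns NaN when either
    integral is zero (undefined score; downstream assigns the median rank).
    """
    sel = panel.alleles[panel.rows_of_samples(groups.selected)]
    ref = panel.alleles[panel.rows_of_samples(groups.reference)]
    pooled = np.concatenate([sel, ref], axis=0)
    i_sel = integrated_ehh(
        sel, core_index, snp_map, truncation, max_extension_bp, stop_haps=pooled
    )
    i_ref = integrated_ehh(
        ref, core_index, snp_map, truncation, max_extension_bp, stop_haps=pooled
    )
    if i_sel <= 0.0 or i_ref <= 0.0:
        return float("nan")
    return float(np.log(i_sel / i_ref))


# ---------------------------------------------------------------------------
# fast whole-genome scan
# ---------------------------------------------------------------------------


def _homozygous_pairs(M: np.ndarray) -> np.ndarray:
    """Per-column count of identical (unordered) row pairs of M (K x S)."""
    K, S = M.shape
    if K < 2 or S == 0:
        return np.zeros(S, dtype=np.int64)
    Ms = np.sort(M, axis=0)
    eq = Ms[1:] == Ms[:-1]
    c = np.cumsum(eq, axis=0, dtype=np.int64)
    idx = np.arange(eq.shape[0])[:, None]
    # index of the last non-equal row at or before i (-1 if none)
    last0 = np.maximum.accumulate(np.where(~eq, idx, -1), axis=0)
    czero = np.vstack([np.zeros((1, S), dtype=np.int64), c])
    base = np.take_along_axis(czero, last0 + 1, axis=0)
    # run position of each equal pair; summing gives sum_c C(k_c, 2)
    return (c - base).sum(axis=0)


def _hash_prefix(alleles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(K, n+1) prefix sums of per-(SNP, allele) random 64-bit weights.

    The hash of the allele string over columns [lo, hi] of haplotype k is
    ``prefix[k, hi+1] - prefix[k, lo]`` (wrapping uint64 arithmetic), so
    two haplotypes share an interval hash iff they share the allele
    string, up to a ~2^-64 collision probability.
    """
    n = alleles.shape[1]
    w = rng.integers(0, 2**64, size=(2, n), dtype=np.uint64)
    vals = np.where(alleles == 1, w[1], w[0])
    prefix = np.zeros((alleles.shape[0], n + 1), dtype=np.uint64)
    np.cumsum(vals, axis=1, out=prefix[:, 1:])
    return prefix


def _ehh_profile(prefix: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """EHH of intervals [lo_s, hi_s] for the population whose prefix is given."""
    K = prefix.shape[0]
    pairs = _homozygous_pairs(prefix[:, hi + 1] - prefix[:, lo])
    return pairs / (K * (K - 1) / 2.0)


def xpehh_scan(
    panel: HaplotypePanel,
    groups: GroupAssignment,
    snp_map: SnpMap,
    truncation: float = DEFAULT_TRUNCATION,
    max_extension_bp: float = DEFAULT_MAX_EXTENSION_BP,
    _chunk: int = 16,
) -> np.ndarray:
    """Raw XP-EHH log-ratio at every SNP (NaN where undefined).

    Semantically identical to calling :func:`xpehh_per_snp` at each SNP;
    implemented with prefix hashes and chunked extension so genome scans
    stay fast.
    """
    sel_rows_panel = panel.rows_of_samples(groups.selected)
    ref_rows_panel = panel.rows_of_samples(groups.reference)
    rng = np.random.default_rng(_HASH_SEED)
    out = np.full(panel.n_snps, np.nan)

    n_sel = len(sel_rows_panel)
    for chrom in dict.fromkeys(snp_map.chrom.tolist()):  # preserves order
        cols = np.flatnonzero(snp_map.chrom == chrom)
        alleles = panel.alleles[np.concatenate([sel_rows_panel, ref_rows_panel])][:, cols]
        pos = snp_map.pos_bp[cols].astype(np.int64)
        prefix = _hash_prefix(alleles, rng)
        # sel/ref rows are contiguous by construction: cheap views
        p_pool, p_sel, p_ref = prefix, prefix[:n_sel], prefix[n_sel:]
        n = len(cols)
        all_j = np.arange(n)
        ehh0_all = {
            "sel": _ehh_profile(p_sel, all_j, all_j),
            "ref": _ehh_profile(p_ref, all_j, all_j),
        }

        # physical extension limits per core
        lo_lim = np.searchsorted(pos, pos - int(max_extension_bp), side="left")
        hi_lim = np.searchsorted(pos, pos + int(max_extension_bp), side="right") - 1

        for j in range(n):
            used_sides = []
            for steps in (
                np.arange(j - 1, lo_lim[j] - 1, -1),  # leftward boundaries
                np.arange(j + 1, hi_lim[j] + 1),      # rightward boundaries
            ):
                # chunked pooled-EHH extension to find the stopping step
                n_used = 0
                stopped = False
                while n_used < len(steps) and not stopped:
                    part = steps[n_used : n_used + _chunk]
                    lo = np.minimum(part, j)
                    hi = np.maximum(part, j)
                    e_pool = _ehh_profile(p_pool, lo, hi)
                    below = np.flatnonzero(e_pool < truncation)
                    if len(below):
                        n_used += int(below[0]) + 1  # include the crossing SNP
                        stopped = True
                    else:
                        n_used += len(part)
                used_sides.append(steps[:n_used])

            both = np.concatenate(used_sides)
            lo = np.minimum(both, j)
            hi = np.maximum(both, j)
            x = np.abs(pos[both] - pos[j]).astype(float)
            n_left = len(used_sides[0])
            sides: dict[str, float] = {}
            for name, pref in (("sel", p_sel), ("ref", p_ref)):
                y = _ehh_profile(pref, lo, hi)
                total = 0.0
                for sl in (slice(0, n_left), slice(n_left, None)):
                    xs = np.concatenate([[0.0], x[sl]])
                    ys = np.concatenate([[ehh0_all[name][j]], y[sl]])
                    total += float(np.trapezoid(ys, xs))
                sides[name] = total
            if sides["sel"] > 0.0 and sides["ref"] > 0.0:
                out[cols[j]] = np.log(sides["sel"] / sides["ref"])

    n_undef = int(np.isnan(out).sum())
    if n_undef:
        log.info("XP-EHH undefined (zero integral) at %d SNPs", n_undef)
    return out
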