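"""Sliding-window smoothing, top-fraction significance and region calls.

Per-SNP scores are noisy; selection leaves clusters of elevated scores,
so each SNP's score is replaced by the mean over a 1 Mb window centred on
it (all SNPs within +/-0.5 Mb, closed interval). Windows holding fewer
than ``min_snps`` SNPs are pruned. The top ``top_fraction`` (0.1% by
default) of retained smoothed values are significant; significant SNPs
are grouped into clusters around local peaks, nearby clusters merged,
small ones dropped, and each surviving cluster padded by 0.5 Mb per side
into a candidate region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .model import RegionCall, SnpMap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Window/threshold constants for the genome scan."""

    half_width_bp: int = 500_000
    min_snps: int = 5
    top_fraction: float = 0.001
    cluster_merge_gap_bp: int = 1_000_000
    region_pad_bp: int = 500_000
    min_cluster_snps: int = 3

    def __post_init__(self) -> None:
        if min(
            self.half_width_bp, self.min_snps, self.top_fraction,
            self.cluster_merge_gap_bp, self.region_pad_bp, self.min_cluster_snps,
        ) <= 0:
            raise ValueError("all window parameters must be positive")


def smooth(
    values: np.ndarray, snp_map: SnpMap, spec: WindowSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Window-mean of ``values`` at every SNP plus the window SNP count.

    For SNP j at position x, the window is every same-chromosome SNP with
    |pos - x| <= half_width_bp (including j itself). NaN input values are
    excluded from both numerator and count (they carry no information).
    Windows with fewer than ``min_snps`` contributing SNPs yield NaN
    ("pruned"); the returned count is the number of contributing SNPs.
    """
    spec = spec or WindowSpec()
    x = np.asarray(values, dtype=float)
    if len(x) != len(snp_map):
        raise ValueError("values not aligned to map")
    smoothed = np.full(len(x), np.nan)
    n_in_window = np.zeros(len(x), dtype=np.int64)
    for chrom in dict.fromkeys(snp_map.chrom.tolist()):
        cols = np.flatnonzero(snp_map.chrom == chrom)
        pos = snp_map.pos_bp[cols]
        v = x[cols]
        ok = np.isfinite(v)
        cs = np.concatenate([[0.0], np.cumsum(np.where(ok, v, 0.0))])
        cn = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
        left = np.searchsorted(pos, pos - spec.half_width_bp, side="left")
        right = np.searchsorted(pos, pos + spec.half_width_bp, side="right")
        counts = cn[right] - cn[left]
        sums = cs[right] - cs[left]
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        means[counts < spec.min_snps] = np.nan
        smoothed[cols] = means
        n_in_window[cols] = counts
    return smoothed, n_in_window


def significant_snps(
    smoothed: np.ndarray, spec: WindowSpec | None = None
) -> np.ndarray:
    """Indices of the top ``ceil(top_fraction * n_retained)`` smoothed SNPs.

    Pruned (NaN) entries count neither toward the threshold basis nor the
    candidates. Ties at the cutoff are broken by genome order (the array
    order), keeping the significant count exact. Small score vectors
    always yield at least one significant SNP (with a logged warning).
    """
    spec = spec or WindowSpec()
    x = np.asarray(smoothed, dtype=float)
    retained = np.flatnonzero(np.isfinite(x))
    n_retained = len(retained)
    if n_retained == 0:
        return np.empty(0, dtype=np.intp)
    if n_retained < 1000:
        log.warning(
            "only %d retained SNPs; top-%g%% threshold keeps at least 1",
            n_retained, 100 * spec.top_fraction,
        )
    k = max(1, math.ceil(spec.top_fraction * n_retained))
    # primary key: descending value; secondary: genome order (stable)
    order = retained[np.lexsort((retained, -x[retained]))]
    return np.sort(order[:k])


def call_clusters(
    sig: np.ndarray,
    smoothed: np.ndarray,
    snp_map: SnpMap,
    spec: WindowSpec | None = None,
) -> list[RegionCall]:
    """Group significant SNPs into clusters and pad them into regions.

    Greedy seeding: the unassigned significant SNP with the most extreme
    smoothed score becomes a core; every unassigned significant SNP on the
    same chromosome within +/- half_width_bp of the core joins its
    cluster; repeat until all are assigned. Same-chromosome clusters whose
    boundary gap is smaller than ``cluster_merge_gap_bp`` are then merged
    (the merged core is the more extreme of the two), and clusters with
    fewer than ``min_cluster_snps`` members are dropped. Cluster bounds
    are the first/last member positions; region bounds add
    ``region_pad_bp`` per side, floored at 1 bp.
    """
    spec = spec or WindowSpec()
    sig = np.asarray(sig, dtype=np.intp)
    if sig.size == 0:
        return []
    x = np.asarray(smoothed, dtype=float)

    # --- greedy seeding by descending smoothed score
    order = sig[np.lexsort((sig, -x[sig]))]
    assigned = {}
    clusters: list[dict] = []
    for core in order:
        if core in assigned:
            continue
        members = [
            i
            for i in sig
            if i not in assigned
            and snp_map.chrom[i] == snp_map.chrom[core]
            and abs(int(snp_map.pos_bp[i]) - int(snp_map.pos_bp[core])) <= spec.half_width_bp
        ]
        for i in members:
            assigned[i] = len(clusters)
        clusters.append({"core": int(core), "members": sorted(int(i) for i in members)})

    # --- merge same-chromosome clusters closer than the merge gap
    def bounds(c: dict) -> tuple[int, int]:
        pos = snp_map.pos_bp[c["members"]]
        return int(pos.min()), int(pos.max())

    merged = True
    while merged:
        merged = False
        clusters.sort(key=lambda c: (str(snp_map.chrom[c["core"]]), bounds(c)[0]))
        for a, b in zip(clusters, clusters[1:]):
            if snp_map.chrom[a["core"]] != snp_map.chrom[b["core"]]:
                continue
            gap = bounds(b)[0] - bounds(a)[1]
            if gap < spec.cluster_merge_gap_bp:
                a["members"] = sorted(set(a["members"]) | set(b["members"]))
                a["core"] = a["core"] if x[a["core"]] >= x[b["core"]] else b["core"]
                clusters.remove(b)
                merged = True
                break

    # --- minimum-member filter and region construction
    out: list[RegionCall] = []
    for c in clusters:
        if len(c["members"]) < spec.min_cluster_snps:
            continue
        lo, hi = bounds(c)
        out.append(
            RegionCall(
                chrom=str(snp_map.chrom[c["core"]]),
                cluster_start_bp=lo,
                cluster_end_bp=hi,
                region_start_bp=max(1, lo - spec.region_pad_bp),
                region_end_bp=hi + spec.region_pad_bp,
                core_snp_id=str(snp_map.snp_id[c["core"]]),
                peak_smoothed=float(x[c["core"]]),
                member_snp_ids=[str(snp_map.snp_id[i]) for i in c["members"]],
            )
        )
    out.sort(key=lambda r: (r.chrom, r.region_start_bp))
    return out


def count_concordance(
    regions: list[RegionCall],
    per_test_sig: dict[str, np.ndarray],
    snp_map: SnpMap,
) -> list[RegionCall]:
    """Fill each region's per-test significant-SNP counts (in place).

    ``per_test_sig`` maps a test name to the indices of its significant
    SNPs (from smoothing + top-fraction thresholding of that test's own
    statistic); a SNP counts when its position falls inside the padded
    region boundaries.
    """
    for region in regions:
        for test, sig in per_test_sig.items():
            sig = np.asarray(sig, dtype=np.intp)
            inside = [
                int(i)
                for i in sig
                if region.contains(str(snp_map.chrom[i]), int(snp_map.pos_bp[i]))
            ]
            region.n_sig[test] = len(inside)
    return regions
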