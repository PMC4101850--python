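"""Empirical p-value recalibration and tail-area FDR (q-values).

Composite p-values are empirical rank products, not exact test p-values,
so before attaching FDR estimates they are recalibrated toward an ideal
empirical p-value distribution: a monotone map g with g(0)=0, g(1)=1,
estimated from a linear null model fitted to the empirical CDF on its
null-dominated upper range, is applied to every p-value. The map is
order-preserving by construction (calibrated ranks always equal raw
ranks), and reduces to the identity when the input is already ideally
uniform. This is a deliberately simplified form of constrained-regression
recalibration: the contract downstream q-values need is order
preservation plus approximate uniformity of the null component, not a
particular basis expansion.

q-values are then tail-area FDRs: q(p) = min over p' >= p of
eta0 * n * p' / #{p_k <= p'}, with the null proportion eta0 estimated
from the upper-tail density of the calibrated p-values (the data above
their 75th percentile, the region where true signals are rare). With
eta0 = 1 this is exactly the Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import RegionCall, SnpMap

log = logging.getLogger(__name__)

#: Below this many p-values, calibration is skipped and eta0 pinned at 1.
MIN_CALIBRATION_N = 100

#: Quantile above which the p distribution is treated as null-dominated.
NULL_QUANTILE = 0.75


@dataclass(frozen=True)
class FdrResult:
    """Calibrated p-values, q-values and the estimated null proportion."""

    calibrated_p: np.ndarray
    q_value: np.ndarray
    eta0: float


#: Power-basis exponents for the concave CDF fit. Each p**a (0 < a <= 1)
#: is monotone and concave through (0,0) and (1,1); a non-negative
#: combination summing to 1 inherits all three constraints.
_EXPONENTS = np.array([0.02, 0.05, 0.1, 0.2, 0.35, 0.5, 0.7, 0.85, 1.0])


def _fit_concave_cdf(uniq: np.ndarray, ecdf: np.ndarray) -> np.ndarray:
    """Non-negative weights c (summing to 1) of F(p) = sum_k c_k p**a_k.

    Weighted NNLS with relative (1/ecdf) weights, so the sparse extreme
    tail influences the fit as strongly as the bulk; a heavy soft
    constraint row pins F(1) = 1, renormalized exactly afterwards.
    """
    from scipy.optimize import nnls

    X = uniq[:, None] ** _EXPONENTS[None, :]
    w = 1.0 / ecdf
    lam = 100.0 * float(np.sqrt((w**2).sum()))
    A = np.vstack([X * w[:, None], lam * np.ones((1, len(_EXPONENTS)))])
    y = np.concatenate([ecdf * w, [lam]])
    c, _ = nnls(A, y)
    total = c.sum()
    if total <= 0:  # pathological; identity map
        c = np.zeros(len(_EXPONENTS))
        c[-1] = 1.0
        return c
    return c / total


def calibrate_p(p: np.ndarray) -> np.ndarray:
    """Recalibrate empirical p-values toward an ideal uniform null.

    Fits a concave, monotone CDF model F(p) = sum_k c_k p**a_k
    (c_k >= 0, sum c_k = 1, exponents fixed) to the empirical CDF of the
    p-values and returns F^{-1}(ecdf(p)): the sample is remapped so its
    distribution matches the fitted ideal curve. Where the data already
    behave like well-calibrated p-values (null bulk), F ~ identity there
    and values pass through nearly unchanged; genuine signal mass near
    zero steepens F near the origin, and inverting through the steep
    segment restores the extreme tail's magnitudes instead of flattening
    them to ranks.

    The empirical CDF uses Weibull plotting positions rank/(n+1), so an
    exactly uniform input p_j = j/(n+1) is a fixed point. Ties share a
    calibrated value and the output rank order always equals the input
    rank order. Inputs shorter than :data:`MIN_CALIBRATION_N` are
    returned unchanged (with a warning): the fit would be noise.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p-values must lie strictly inside (0, 1)")
    if n < MIN_CALIBRATION_N:
        log.warning("calibration skipped: only %d p-values (< %d)", n, MIN_CALIBRATION_N)
        return p.copy()

    uniq, inverse, counts = np.unique(p, return_inverse=True, return_counts=True)
    ecdf = np.cumsum(counts) / (n + 1.0)
    c = _fit_concave_cdf(uniq, ecdf)

    # invert F through a dense grid covering well below the smallest p
    lo = np.log10(uniq[0]) - 4.0
    grid = np.unique(np.concatenate([np.logspace(lo, 0.0, 1024), uniq]))
    f_grid = (grid[:, None] ** _EXPONENTS[None, :]) @ c
    calibrated = np.interp(ecdf, f_grid, grid)
    calibrated = np.clip(calibrated, np.finfo(float).tiny, 1.0)
    return calibrated[inverse]


def estimate_eta0(p: np.ndarray) -> float:
    """Null-proportion estimate from the upper-tail density of p.

    Under the two-groups model the density of p above its 75th percentile
    is approximately the null proportion eta0 (true signals concentrate
    near zero), so eta0 = (mass above q75) / (uniform mass above q75) =
    0.25 / (1 - q75), clipped to (0, 1]. Small samples return 1.
    """
    p = np.asarray(p, dtype=float)
    if len(p) < MIN_CALIBRATION_N:
        return 1.0
    q75 = float(np.quantile(p, NULL_QUANTILE))
    if q75 >= 1.0 - 1e-12:
        return 1.0
    return float(min(1.0, (1.0 - NULL_QUANTILE) / (1.0 - q75)))


def q_values(calibrated_p: np.ndarray, eta0: float | None = None) -> FdrResult:
    """Tail-area FDR q-values from (calibrated) p-values.

    ``eta0=None`` estimates the null proportion with
    :func:`estimate_eta0`; passing ``eta0=1.0`` reproduces plain
    Benjamini-Hochberg step-up values exactly. Output is permutation
    equivariant and monotone in p.
    """
    p = np.asarray(calibrated_p, dtype=float)
    n = len(p)
    if n == 0:
        return FdrResult(p.copy(), p.copy(), 1.0)
    if eta0 is None:
        eta0 = estimate_eta0(p)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, n + 1)
    q_sorted = eta0 * n * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]  # step-up
    q_sorted = np.clip(q_sorted, np.finfo(float).tiny, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return FdrResult(p.copy(), q, float(eta0))


def region_fdr_summary(
    result: FdrResult,
    regions: list[RegionCall],
    snp_map: SnpMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region counts and percentages of SNPs with q <= alpha.

    One row per region plus a final genome-wide row for all SNPs outside
    every region ("region" = "outside_regions"). Percentages are 100 *
    (SNPs with q <= alpha) / (SNPs in the region).
    """
    q = np.asarray(result.q_value, dtype=float)
    if len(q) != len(snp_map):
        raise ValueError("q-values not aligned to map")
    inside_any = np.zeros(len(snp_map), dtype=bool)
    rows = []
    for k, region in enumerate(regions, start=1):
        inside = (snp_map.chrom == region.chrom) & (
            (snp_map.pos_bp >= region.region_start_bp)
            & (snp_map.pos_bp <= region.region_end_bp)
        )
        inside_any |= inside
        n_in = int(inside.sum())
        n_sig = int((q[inside] <= alpha).sum())
        rows.append(
            {
                "region": f"R{k}",
                "chrom": region.chrom,
                "region_start_bp": region.region_start_bp,
                "region_end_bp": region.region_end_bp,
                "n_snps": n_in,
                "n_q_le_alpha": n_sig,
                "pct_q_le_alpha": 100.0 * n_sig / n_in if n_in else float("nan"),
            }
        )
    outside = ~inside_any
    n_out = int(outside.sum())
    n_sig_out = int((q[outside] <= alpha).sum())
    rows.append(
        {
            "region": "outside_regions",
            "chrom": "*",
            "region_start_bp": pd.NA,
            "region_end_bp": pd.NA,
            "n_snps": n_out,
            "n_q_le_alpha": n_sig_out,
            "pct_q_le_alpha": 100.0 * n_sig_out / n_out if n_out else float("nan"),
        }
    )
    return pd.DataFrame(rows)
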