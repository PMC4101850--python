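"""Composite selection signal: rank-combine constituent statistics.

Each constituent statistic T_ij (test i, SNP j) is reduced to its
fractional rank R'_ij = R_ij / (n + 1) across the genome, mapped to a
standard-normal score Z_ij = Phi^-1(R'_ij), and averaged over the m tests
at each SNP. Under the null of no shared signal the mean Zbar_j is
N(0, 1/m), so p_j = 1 - Phi(sqrt(m) * Zbar_j) is an upper-tail p-value
and CSS_j = -log10 p_j is the composite score. Because only ranks enter,
the composite is invariant to any strictly monotone transform of any
constituent statistic.

Polarity convention: every constituent is oriented so that LARGE values
mean selection in the SELECTED group (FST is unsigned — large means
differentiation either way; dDAF/dSAF and XP-EHH are signed). Signed
statistics are ranked as-is, not by absolute value, matching the
one-tailed upper-tail p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical constituent-test names, in score-table column order.
TESTS = ("FST", "DAFDIFF", "XPEHH")


@dataclass(frozen=True)
class CompositeConfig:
    """Which constituent tests enter the composite (m = number of tests)."""

    tests_included: tuple[str, ...] = TESTS

    def __post_init__(self) -> None:
        bad = set(self.tests_included) - set(TESTS)
        if bad:
            raise ValueError(f"unknown tests: {sorted(bad)}")
        if len(self.tests_included) < 1:
            raise ValueError("at least one test must be included")

    @property
    def m(self) -> int:
        return len(self.tests_included)


def fractional_ranks(values: np.ndarray) -> np.ndarray:
    """Ascending fractional ranks R/(n+1) in (0, 1), ties sharing the
    average rank.

    NaN entries (undefined constituent scores, e.g. a zero-integral
    XP-EHH) receive the median fractional rank 0.5 so every test keeps
    the same SNP count; finite entries are ranked among themselves.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to rank")
    finite = np.isfinite(x)
    out = np.full(x.shape, 0.5)
    n_def = int(finite.sum())
    if n_def:
        out[finite] = stats.rankdata(x[finite], method="average") / (n_def + 1)
    return out


def z_scores(fracs: np.ndarray) -> np.ndarray:
    """Standard-normal quantiles of fractional ranks (all strictly in (0,1))."""
    r = np.asarray(fracs, dtype=float)
    if np.any((r <= 0.0) | (r >= 1.0)):
        raise ValueError("fractional ranks must lie strictly inside (0, 1)")
    return stats.norm.ppf(r)


def composite_p(z_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-Z, upper-tail p and CSS from an (m, n) matrix of Z-scores.

    p_j = 1 - Phi(sqrt(m) * Zbar_j), computed with the survival function
    so extreme scores keep full precision; CSS_j = -log10 p_j.
    """
    z = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    m = z.shape[0]
    zbar = z.mean(axis=0)
    p = stats.norm.sf(np.sqrt(m) * zbar)
    css = -np.log10(p)
    return zbar, p, css


def compose(table: pd.DataFrame, cfg: CompositeConfig | None = None) -> pd.DataFrame:
    """Fill rank/Z/Zbar/p/css columns from constituent statistic columns.

    Expects columns ``fst``, ``dafdiff``, ``xpehh`` (those named in the
    config); adds ``z_fst``/``z_dafdiff``/``z_xpehh`` (the rank-based
    Z_ij), ``zbar``, ``p`` and ``css``. Deterministic for fixed input and
    equivariant under SNP reordering.
    """
    cfg = cfg or CompositeConfig()
    out = table.copy()
    zs = []
    for test in cfg.tests_included:
        col = test.lower()
        if col not in out.columns:
            raise ValueError(f"missing constituent column {col!r}")
        z = z_scores(fractional_ranks(out[col].to_numpy(dtype=float)))
        out[f"z_{col}"] = z
        zs.append(z)
    zbar, p, css = composite_p(np.vstack(zs))
    out["zbar"] = zbar
    out["p"] = p
    out["css"] = css
    return out
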