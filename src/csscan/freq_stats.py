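"""Allele-frequency constituent statistics: FST, dDAF and dSAF.

All three contrast a putatively SELECTED group against a REFERENCE group
at each SNP. FST measures frequency differentiation against within-group
heterozygosity; dDAF is the difference in derived-allele frequency
(requires an ancestral-allele annotation); dSAF is its annotation-free
surrogate, the between-group difference in frequency of the SELECTED
group's major allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ANCESTRAL_ALT,
    ANCESTRAL_REF,
    ANCESTRAL_UNKNOWN,
    GroupAssignment,
    HaplotypePanel,
    SnpMap,
)


@dataclass(frozen=True)
class FreqPair:
    """ALT-allele frequencies and haplotype counts for the two groups."""

    f_sel: np.ndarray
    f_ref: np.ndarray
    n_hap_sel: int
    n_hap_ref: int


def group_frequencies(panel: HaplotypePanel, groups: GroupAssignment) -> FreqPair:
    """ALT-allele frequency per SNP within each group."""
    sel_rows = panel.rows_of_samples(groups.selected)
    ref_rows = panel.rows_of_samples(groups.reference)
    if len(sel_rows) < 2 or len(ref_rows) < 2:
        raise ValueError("each group needs at least 2 haplotypes")
    return FreqPair(
        f_sel=panel.alleles[sel_rows].mean(axis=0),
        f_ref=panel.alleles[ref_rows].mean(axis=0),
        n_hap_sel=len(sel_rows),
        n_hap_ref=len(ref_rows),
    )


def fst_per_snp(freqs: FreqPair, estimator: str = "wright") -> np.ndarray:
    """Two-population fixation index per SNP.

    The default ("wright") is the unweighted Wright/Nei form: with
    p_bar = (f_sel + f_ref)/2, H_T = 2 p_bar (1 - p_bar) and H_S the mean
    within-group expected heterozygosity, FST = (H_T - H_S) / H_T, defined
    as 0 where H_T = 0. It lies in [0, 1] and treats the two groups
    symmetrically regardless of their sample sizes — a pure frequency
    contrast, appropriate when group sizes are very unbalanced.

    ``estimator="weir-cockerham"`` gives the haploid ANOVA (method-of-
    moments) estimator instead, which weights by haplotype counts and can
    go slightly negative for undifferentiated SNPs.
    """
    f1 = np.asarray(freqs.f_sel, dtype=float)
    f2 = np.asarray(freqs.f_ref, dtype=float)
    if estimator == "wright":
        p_bar = 0.5 * (f1 + f2)
        h_t = 2.0 * p_bar * (1.0 - p_bar)
        h_s = f1 * (1.0 - f1) + f2 * (1.0 - f2)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(h_t > 0.0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), 0.0)
        return fst
    if estimator == "weir-cockerham":
        n1, n2 = float(freqs.n_hap_sel), float(freqs.n_hap_ref)
        n_tot = n1 + n2
        p_w = (n1 * f1 + n2 * f2) / n_tot
        msp = n1 * (f1 - p_w) ** 2 + n2 * (f2 - p_w) ** 2  # k - 1 = 1
        msg = (n1 * f1 * (1 - f1) + n2 * f2 * (1 - f2)) / (n_tot - 2.0)
        n_c = n_tot - (n1 ** 2 + n2 ** 2) / n_tot
        denom = msp + (n_c - 1.0) * msg
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(denom > 0.0, (msp - msg) / np.where(denom > 0, denom, 1.0), 0.0)
        return fst
    raise ValueError(f"unknown FST estimator {estimator!r}")


def derived_frequencies(freqs: FreqPair, ancestral: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Derived-allele frequency (D_S, D_NS) per SNP given ancestral flags.

    Raises when any SNP's ancestral allele is unknown; callers fall back
    to :func:`delta_saf` in that case.
    """
    ancestral = np.asarray(ancestral, dtype=object)
    if np.any(ancestral == ANCESTRAL_UNKNOWN):
        raise ValueError("ancestral unknown for some SNPs; use delta_saf instead")
    flip = ancestral == ANCESTRAL_ALT  # derived allele is REF
    d_s = np.where(flip, 1.0 - freqs.f_sel, freqs.f_sel)
    d_ns = np.where(flip, 1.0 - freqs.f_ref, freqs.f_ref)
    return d_s, d_ns


def delta_daf(freqs: FreqPair, ancestral: np.ndarray) -> np.ndarray:
    """dDAF = D_S - D_NS: derived-frequency gain in the SELECTED group."""
    d_s, d_ns = derived_frequencies(freqs, ancestral)
    return d_s - d_ns


def delta_saf(freqs: FreqPair) -> np.ndarray:
    """dSAF: between-group frequency difference of the SELECTED group's
    major allele.

    Allele A is whichever allele has frequency >= 0.5 in the SELECTED
    group (tie broken toward ALT, a fixed deterministic rule); the same
    allele's frequency is then contrasted between the groups, so the
    statistic is signed with positive values meaning A is commoner in the
    SELECTED group.
    """
    a_is_alt = freqs.f_sel >= 0.5
    f_a_sel = np.where(a_is_alt, freqs.f_sel, 1.0 - freqs.f_sel)
    f_a_ref = np.where(a_is_alt, freqs.f_ref, 1.0 - freqs.f_ref)
    return f_a_sel - f_a_ref


def dafdiff(
    freqs: FreqPair, snp_map: SnpMap, mode: str = "auto"
) -> tuple[np.ndarray, str]:
    """The DAFDIFF constituent: dDAF when ancestral alleles allow, else dSAF.

    ``mode`` is "auto" (dDAF iff every SNP is annotated), "daf" or "saf".
    Returns the statistic and the name actually used.
    """
    if mode == "auto":
        mode = "daf" if snp_map.has_full_ancestral else "saf"
    if mode == "daf":
        return delta_daf(freqs, snp_map.ancestral), "daf"
    if mode == "saf":
        return delta_saf(freqs), "saf"
    raise ValueError(f"unknown dafdiff mode {mode!r}")


def standardize(scores: np.ndarray) -> np.ndarray:
    """Center and scale to zero mean / unit (population) variance.

    NaN entries are ignored for the moments and propagated unchanged.
    Raises on fewer than 2 finite values or zero variance. Applied
    genome-wide (all chromosomes pooled), per the scan's convention.
    """
    x = np.asarray(scores, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("standardize needs at least 2 finite values")
    mu = x[finite].mean()
    sd = x[finite].std()  # ddof=0
    if sd == 0.0:
        raise ValueError("zero variance input")
    out = np.where(finite, (x - mu) / sd, np.nan)
    return out
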