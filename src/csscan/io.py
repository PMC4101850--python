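"""Readers and writers for haplotype panels, maps, groups and results.

Supported inputs: phased VCF (via :mod:`cyvcf2`) and a transposed
haplotype text dialect ("THAP": one SNP per row, two 0/1 columns per
sample) with a companion map file. Outputs: a per-SNP score TSV and a
BED-like region TSV.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    ANCESTRAL_ALT,
    ANCESTRAL_REF,
    ANCESTRAL_UNKNOWN,
    DataModelError,
    GroupAssignment,
    HaplotypePanel,
    RegionCall,
    SnpMap,
)

log = logging.getLogger(__name__)

#: Column order of the score table TSV.
SCORE_COLUMNS = [
    "snp_id", "chrom", "pos_bp",
    "fst", "dafdiff", "xpehh",
    "z_fst", "z_dafdiff", "z_xpehh",
    "zbar", "p", "css", "css_smoothed", "n_snps_window", "q_value",
]


def read_group_file(path: str | Path) -> GroupAssignment:
    """Read a two-column "sample_id group" file; '#' lines are comments."""
    group_of: dict[str, str] = {}
    breed_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise DataModelError(f"{path}:{lineno}: expected 'sample_id group'")
            sample, grp = parts[0], parts[1]
            if sample in group_of:
                raise DataModelError(f"{path}:{lineno}: duplicate sample {sample!r}")
            group_of[sample] = grp
            if len(parts) > 2:
                breed_of[sample] = parts[2]
    return GroupAssignment(group_of, breed_of)


def read_phased_vcf(
    path: str | Path, groups: GroupAssignment, strict: bool = True
) -> tuple[SnpMap, HaplotypePanel]:
    """Load phased biallelic SNPs for the assigned samples from a VCF.

    The INFO/AA key (a base) is matched against REF/ALT to set the
    ancestral-allele flag; anything else is recorded as unknown. In strict
    mode (default) an unphased or missing genotype raises; in lenient mode
    the offending SNP is skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    wanted = list(groups.samples)
    missing = [s for s in wanted if s not in vcf_samples]
    if missing:
        raise DataModelError(f"samples absent from VCF: {missing}")
    cols = np.asarray([vcf_samples.index(s) for s in wanted], dtype=np.intp)

    ids, chroms, poss, ancs = [], [], [], []
    hap_cols: list[np.ndarray] = []
    n_skipped = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise DataModelError(
                f"multiallelic or non-SNP record at {rec.CHROM}:{rec.POS}"
            )
        # genotypes: (n_samples, 3) = allele0, allele1, phased flag
        gt = np.asarray(rec.genotypes, dtype=np.int64)[cols]
        ok = bool(np.all(gt[:, 2] == 1) and np.all(gt[:, :2] >= 0))
        if not ok:
            if strict:
                raise DataModelError(
                    f"unphased genotype (or missing call) at {rec.CHROM}:{rec.POS}"
                )
            n_skipped += 1
            continue
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM))
        poss.append(int(rec.POS))
        aa = rec.INFO.get("AA")
        if aa is not None:
            aa = str(aa).upper()
        if aa == rec.REF:
            ancs.append(ANCESTRAL_REF)
        elif aa == rec.ALT[0]:
            ancs.append(ANCESTRAL_ALT)
        else:
            ancs.append(ANCESTRAL_UNKNOWN)
        hap_cols.append(gt[:, :2].reshape(-1).astype(np.uint8))
    if n_skipped:
        log.warning("skipped %d SNPs with unphased/missing genotypes", n_skipped)

    snp_map = SnpMap.from_arrays(ids, chroms, poss, ancs)
    alleles = (
        np.stack(hap_cols, axis=1)
        if hap_cols
        else np.empty((2 * len(wanted), 0), dtype=np.uint8)
    )
    panel = HaplotypePanel(alleles, tuple(wanted))
    return snp_map, panel


def read_thap(
    path_hap: str | Path, path_map: str | Path, groups: GroupAssignment,
    sample_ids: Sequence[str] | None = None,
) -> tuple[SnpMap, HaplotypePanel]:
    """Read the transposed-haplotype dialect plus its companion map.

    THAP: whitespace-separated, one SNP per row, ``2 * n_samples`` columns
    of {0,1}, haplotype pairs in sample order. The map supplies
    "snp_id chrom pos_bp [ancestral]" per SNP. Column order follows
    ``sample_ids`` when given, else the group file's sample order.
    """
    samples = list(sample_ids) if sample_ids is not None else list(groups.samples)
    n_cols = 2 * len(samples)

    rows: list[np.ndarray] = []
    with open(path_hap) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) != n_cols:
                raise DataModelError(
                    f"{path_hap}:{lineno}: row length {len(toks)} does not match "
                    f"2 x {len(samples)} samples"
                )
            if any(t not in ("0", "1") for t in toks):
                raise DataModelError(f"{path_hap}:{lineno}: invalid allele code")
            rows.append(np.asarray(toks, dtype=np.uint8))

    ids, chroms, poss, ancs = [], [], [], []
    with open(path_map) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 3:
                raise DataModelError(f"{path_map}:{lineno}: expected 'snp_id chrom pos_bp'")
            ids.append(toks[0])
            chroms.append(toks[1])
            poss.append(int(toks[2]))
            anc = toks[3].upper() if len(toks) > 3 else ANCESTRAL_UNKNOWN
            if anc not in (ANCESTRAL_REF, ANCESTRAL_ALT, ANCESTRAL_UNKNOWN):
                raise DataModelError(f"{path_map}:{lineno}: invalid ancestral flag {anc!r}")
            ancs.append(anc)
    if len(ids) != len(rows):
        raise DataModelError(
            f"map has {len(ids)} SNPs but haplotype file has {len(rows)} rows"
        )

    snp_map = SnpMap.from_arrays(ids, chroms, poss, ancs)
    alleles = (
        np.stack(rows, axis=1) if rows else np.empty((n_cols, 0), dtype=np.uint8)
    )
    panel = HaplotypePanel(alleles, tuple(samples))
    # keep only assigned samples, in group-file order
    assigned = [s for s in samples if s in groups.group_of]
    if len(assigned) != len(samples):
        panel = HaplotypePanel(
            np.ascontiguousarray(panel.alleles[panel.rows_of_samples(assigned)]),
            tuple(assigned),
        )
    return snp_map, panel


def pooled_maf(panel: HaplotypePanel) -> np.ndarray:
    """Minor-allele frequency per SNP over all haplotypes (groups pooled)."""
    f_alt = panel.alleles.mean(axis=0)
    return np.minimum(f_alt, 1.0 - f_alt)


def apply_maf_filter(
    panel: HaplotypePanel, snp_map: SnpMap, min_maf: float = 0.01
) -> tuple[SnpMap, HaplotypePanel]:
    """Drop SNPs whose pooled MAF is <= ``min_maf``, preserving order.

    The filter pools haplotypes across groups deliberately: a SNP
    monomorphic in one group but segregating in the other is exactly the
    differentiation signal the scan looks for.
    """
    if not (0.0 <= min_maf < 0.5):
        raise DataModelError("min_maf must be in [0, 0.5)")
    keep = pooled_maf(panel) > min_maf
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("MAF filter removed %d of %d SNPs", n_drop, len(snp_map))
    return snp_map.subset(keep), panel.subset_snps(keep)


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.6g}"


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-SNP score table as TSV; NaN rendered as ``NA``.

    Columns are fixed (:data:`SCORE_COLUMNS`); SNPs in pruned smoothing
    windows carry NA in the ``css_smoothed`` column.
    """
    out = table.reindex(columns=SCORE_COLUMNS)
    with open(path, "w") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            vals = []
            for col, v in zip(SCORE_COLUMNS, row):
                if col in ("snp_id", "chrom"):
                    vals.append(str(v))
                elif col in ("pos_bp", "n_snps_window"):
                    vals.append("NA" if pd.isna(v) else str(int(v)))
                else:
                    vals.append(_fmt(v))
            fh.write("\t".join(vals) + "\n")


def read_scores(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_scores` output."""
    return pd.read_csv(
        path, sep="\t", na_values=["NA"], dtype={"snp_id": str, "chrom": str}
    )


def write_regions(regions: Sequence[RegionCall], path: str | Path) -> None:
    """Write region calls as BED-like TSV (0-based start, 1-based end)."""
    tests = sorted({t for r in regions for t in r.n_sig})
    header = [
        "chrom", "region_start", "region_end", "core_snp_id",
        "peak_css_smoothed", "n_members",
    ] + [f"n_sig_{t.lower()}" for t in tests]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in regions:
            row = [
                r.chrom, str(r.region_start_bp - 1), str(r.region_end_bp),
                r.core_snp_id, f"{r.peak_smoothed:.6g}", str(r.n_members),
            ] + [str(r.n_sig.get(t, 0)) for t in tests]
            fh.write("\t".join(row) + "\n")
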