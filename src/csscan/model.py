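"""Shared data model for two-population haplotype scans.

The scan operates on three aligned objects: a :class:`SnpMap` (genomic
coordinates of every SNP, optionally annotated with which allele is
ancestral), a :class:`HaplotypePanel` (phased 0/1 alleles, two rows per
diploid sample) and a :class:`GroupAssignment` splitting samples into a
putatively SELECTED group and a REFERENCE group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SELECTED = "SELECTED"
REFERENCE = "REFERENCE"

#: Ancestral-allele states. Stored as a REF/ALT flag, never a base, so
#: derived-allele frequencies need no sequence context.
ANCESTRAL_REF = "REF"
ANCESTRAL_ALT = "ALT"
ANCESTRAL_UNKNOWN = "NA"


class DataModelError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass(frozen=True)
class SnpMap:
    """Per-SNP chromosome, 1-based physical position and identifier.

    Within each chromosome records must be sorted strictly ascending by
    position; SNP ids must be unique genome-wide.
    """

    snp_id: np.ndarray      # object dtype, unique
    chrom: np.ndarray       # object dtype
    pos_bp: np.ndarray      # int64, 1-based
    ancestral: np.ndarray   # object dtype, values in {REF, ALT, NA}

    def __post_init__(self) -> None:
        n = len(self.snp_id)
        if not (len(self.chrom) == len(self.pos_bp) == len(self.ancestral) == n):
            raise DataModelError("SnpMap arrays must have equal length")
        if n and self.pos_bp.min() < 1:
            raise DataModelError("positions are 1-based; found pos_bp < 1")
        if len(set(self.snp_id.tolist())) != n:
            raise DataModelError("snp_id values must be unique")
        # strict ascending positions within each chromosome run
        for c in pd.unique(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise DataModelError(
                    f"map not sorted: positions on chromosome {c!r} must be "
                    "strictly increasing"
                )
        bad = set(pd.unique(self.ancestral)) - {ANCESTRAL_REF, ANCESTRAL_ALT, ANCESTRAL_UNKNOWN}
        if bad:
            raise DataModelError(f"invalid ancestral states: {sorted(bad)}")

    @classmethod
    def from_arrays(
        cls,
        snp_id: Iterable[str],
        chrom: Iterable[str],
        pos_bp: Iterable[int],
        ancestral: Iterable[str] | None = None,
    ) -> "SnpMap":
        snp_id = np.asarray(list(snp_id), dtype=object)
        chrom = np.asarray([str(c) for c in chrom], dtype=object)
        pos_bp = np.asarray(list(pos_bp), dtype=np.int64)
        if ancestral is None:
            anc = np.full(len(snp_id), ANCESTRAL_UNKNOWN, dtype=object)
        else:
            anc = np.asarray(list(ancestral), dtype=object)
        return cls(snp_id, chrom, pos_bp, anc)

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def has_full_ancestral(self) -> bool:
        """True when every SNP carries a known ancestral allele."""
        return len(self) > 0 and bool(np.all(self.ancestral != ANCESTRAL_UNKNOWN))

    def subset(self, keep: np.ndarray) -> "SnpMap":
        """Return the map restricted to a boolean mask or index array."""
        return SnpMap(
            self.snp_id[keep], self.chrom[keep], self.pos_bp[keep], self.ancestral[keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "ancestral": self.ancestral,
            }
        )


@dataclass(frozen=True)
class HaplotypePanel:
    """Phased biallelic alleles: one row per haplotype, one column per SNP.

    Coding is 0 = REF, 1 = ALT with no missing values (phasing and
    imputation are upstream of this package). Sample ``i`` owns rows
    ``2*i`` and ``2*i + 1``.
    """

    alleles: np.ndarray          # uint8, (n_haplotypes, n_snps)
    sample_ids: tuple[str, ...]  # length n_haplotypes // 2

    def __post_init__(self) -> None:
        a = self.alleles
        if a.ndim != 2:
            raise DataModelError("allele matrix must be 2-D")
        if a.shape[0] != 2 * len(self.sample_ids):
            raise DataModelError("every sample must own exactly two haplotype rows")
        if a.size and not np.isin(a, (0, 1)).all():
            raise DataModelError("invalid allele code: alleles must be 0 or 1")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataModelError("sample_ids must be unique")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def rows_of_samples(self, samples: Sequence[str]) -> np.ndarray:
        """Haplotype row indices owned by the given samples, in panel order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = []
        for s in samples:
            if s not in index:
                raise DataModelError(f"sample {s!r} absent from panel")
            rows.extend((2 * index[s], 2 * index[s] + 1))
        return np.asarray(rows, dtype=np.intp)

    def subset_snps(self, keep: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(np.ascontiguousarray(self.alleles[:, keep]), self.sample_ids)


@dataclass(frozen=True)
class GroupAssignment:
    """Maps each sample to SELECTED or REFERENCE (both non-empty)."""

    group_of: Mapping[str, str]
    breed_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g for g in self.group_of.values()} - {SELECTED, REFERENCE}
        if bad:
            raise DataModelError(f"invalid group labels: {sorted(bad)}")
        if not self.selected or not self.reference:
            raise DataModelError("both SELECTED and REFERENCE groups must be non-empty")

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(s for s, g in self.group_of.items() if g == SELECTED)

    @property
    def reference(self) -> tuple[str, ...]:
        return tuple(s for s, g in self.group_of.items() if g == REFERENCE)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.group_of)

    def swapped(self) -> "GroupAssignment":
        """Return a copy with SELECTED and REFERENCE labels exchanged."""
        flip = {SELECTED: REFERENCE, REFERENCE: SELECTED}
        return GroupAssignment(
            {s: flip[g] for s, g in self.group_of.items()}, dict(self.breed_of)
        )


@dataclass
class RegionCall:
    """A significant cluster of top-scoring smoothed SNPs plus flanks.

    Cluster boundaries are the first/last member SNP positions; the region
    adds ``region_pad_bp`` (0.5 Mb by default) on each side, floored at 1.
    """

    chrom: str
    cluster_start_bp: int
    cluster_end_bp: int
    region_start_bp: int
    region_end_bp: int
    core_snp_id: str
    peak_smoothed: float
    member_snp_ids: list[str]
    n_sig: dict[str, int] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.member_snp_ids)

    def contains(self, chrom: str, pos_bp: int) -> bool:
        return chrom == self.chrom and self.region_start_bp <= pos_bp <= self.region_end_bp
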