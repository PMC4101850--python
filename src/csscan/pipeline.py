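"""End-to-end genome scan: inputs -> constituent tests -> composite ->
windows/regions -> FDR.

:func:`scan` is the in-memory pipeline; :func:`run_scan` wraps it with
file input/output for the command line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composite, fdr, freq_stats, io, windows
from .composite import CompositeConfig, TESTS
from .ehh import DEFAULT_MAX_EXTENSION_BP, DEFAULT_TRUNCATION, xpehh_scan
from .model import GroupAssignment, HaplotypePanel, RegionCall, SnpMap
from .windows import WindowSpec

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    """All tunable parameters of a scan, with the standard defaults
    (MAF 0.01; 1 Mb windows, min 5 SNPs; top 0.1%; 1 Mb merge gap;
    0.5 Mb region pad; EHH truncation 0.05 with 1 Mb max extension)."""

    min_maf: float = 0.01
    window: WindowSpec = field(default_factory=WindowSpec)
    tests_included: tuple[str, ...] = TESTS
    dafdiff_mode: str = "auto"          # auto | daf | saf
    fst_estimator: str = "wright"       # wright | weir-cockerham
    ehh_truncation: float = DEFAULT_TRUNCATION
    ehh_max_extension_bp: float = DEFAULT_MAX_EXTENSION_BP
    fdr_alpha: float = 0.05


@dataclass
class ScanResult:
    """Everything a scan produces, aligned to the MAF-filtered map."""

    snp_map: SnpMap
    scores: pd.DataFrame
    regions: list[RegionCall]
    fdr_summary: pd.DataFrame
    per_test_significant: dict[str, np.ndarray]
    significant: np.ndarray
    eta0: float
    dafdiff_kind: str


def scan(
    snp_map: SnpMap,
    panel: HaplotypePanel,
    groups: GroupAssignment,
    cfg: ScanConfig | None = None,
) -> ScanResult:
    """Run the full composite scan on an in-memory panel."""
    cfg = cfg or ScanConfig()
    n_in = len(snp_map)
    snp_map, panel = io.apply_maf_filter(panel, snp_map, cfg.min_maf)
    log.info("SNPs: %d input, %d after MAF > %g filter", n_in, len(snp_map), cfg.min_maf)
    if len(snp_map) < 2:
        raise ValueError("fewer than 2 SNPs survive the MAF filter")

    # --- constituent statistics
    freqs = freq_stats.group_frequencies(panel, groups)
    table = snp_map.to_frame().drop(columns="ancestral")
    stats_by_test: dict[str, np.ndarray] = {}
    dafdiff_kind = "none"
    if "FST" in cfg.tests_included:
        stats_by_test["FST"] = freq_stats.fst_per_snp(freqs, cfg.fst_estimator)
    if "DAFDIFF" in cfg.tests_included:
        raw, dafdiff_kind = freq_stats.dafdiff(freqs, snp_map, cfg.dafdiff_mode)
        stats_by_test["DAFDIFF"] = freq_stats.standardize(raw)
        log.info("DAFDIFF statistic: delta-%s", dafdiff_kind.upper())
    if "XPEHH" in cfg.tests_included:
        raw = xpehh_scan(
            panel, groups, snp_map, cfg.ehh_truncation, cfg.ehh_max_extension_bp
        )
        stats_by_test["XPEHH"] = freq_stats.standardize(raw)
    for test in cfg.tests_included:
        table[test.lower()] = stats_by_test[test]

    # --- composite score
    table = composite.compose(table, CompositeConfig(cfg.tests_included))

    # --- smoothing and significance (composite and each constituent)
    table["css_smoothed"], table["n_snps_window"] = windows.smooth(
        table["css"].to_numpy(), snp_map, cfg.window
    )
    significant = windows.significant_snps(table["css_smoothed"].to_numpy(), cfg.window)
    per_test_sig: dict[str, np.ndarray] = {"CSS": significant}
    for test in cfg.tests_included:
        sm, _ = windows.smooth(table[test.lower()].to_numpy(), snp_map, cfg.window)
        per_test_sig[test] = windows.significant_snps(sm, cfg.window)

    regions = windows.call_clusters(
        significant, table["css_smoothed"].to_numpy(), snp_map, cfg.window
    )
    windows.count_concordance(regions, per_test_sig, snp_map)
    log.info(
        "significant SNPs: %d; regions called: %d", len(significant), len(regions)
    )

    # --- FDR on the raw (non-smoothed) composite p-values
    calibrated = fdr.calibrate_p(table["p"].to_numpy())
    fdr_result = fdr.q_values(calibrated)
    table["q_value"] = fdr_result.q_value
    summary = fdr.region_fdr_summary(fdr_result, regions, snp_map, cfg.fdr_alpha)

    return ScanResult(
        snp_map=snp_map,
        scores=table,
        regions=regions,
        fdr_summary=summary,
        per_test_significant=per_test_sig,
        significant=significant,
        eta0=fdr_result.eta0,
        dafdiff_kind=dafdiff_kind,
    )


def run_scan(
    out_dir: str | Path,
    groups_path: str | Path,
    vcf_path: str | Path | None = None,
    hap_path: str | Path | None = None,
    map_path: str | Path | None = None,
    cfg: ScanConfig | None = None,
    strict: bool = True,
) -> ScanResult:
    """File-level scan: read inputs, run :func:`scan`, write outputs.

    Writes ``scores.tsv``, ``regions.tsv`` and ``fdr_summary.tsv`` into
    ``out_dir``.
    """
    groups = io.read_group_file(groups_path)
    if vcf_path is not None:
        snp_map, panel = io.read_phased_vcf(vcf_path, groups, strict=strict)
    elif hap_path is not None and map_path is not None:
        snp_map, panel = io.read_thap(hap_path, map_path, groups)
    else:
        raise ValueError("provide either vcf_path or hap_path + map_path")

    result = scan(snp_map, panel, groups, cfg)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_scores(result.scores, out / "scores.tsv")
    io.write_regions(result.regions, out / "regions.tsv")
    result.fdr_summary.to_csv(out / "fdr_summary.tsv", sep="\t", index=False, na_rep="NA")
    return result
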