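"""Synthetic two-population haplotype panels with a plantable hard sweep.

The generator emulates the contrast a selection scan exploits: two
populations sharing neutral allele-frequency structure (a common base
frequency per SNP plus independent between-population jitter), with the
SELECTED population optionally carrying a partial or complete hard sweep
at a known locus. The sweep is encoded structurally rather than by
forward simulation: a single fixed haplotype string spanning the sweep
interval, carrying the derived allele at the focal SNP, is assigned to
each SELECTED haplotype with the target carrier frequency. This creates
exactly the two signals the composite scan's constituents detect — local
frequency differentiation and one long, high-frequency haplotype — while
the background stays at linkage equilibrium, keeping null behaviour
analytically predictable.

A truth table records where the sweep was planted so end-to-end recovery
can be scored without any external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import (
    ANCESTRAL_REF,
    GroupAssignment,
    HaplotypePanel,
    REFERENCE,
    SELECTED,
    SnpMap,
)


@dataclass(frozen=True)
class SweepScenario:
    """Study conditions for one simulated two-population panel.

    Defaults are the package's reference conditions: 20,000 SNPs on five
    100 Mb chromosomes (a dense-chip SNP density of ~35 retained SNPs per
    1 Mb window), 100 + 100 diploid samples, U-shaped Beta(0.5, 0.5) base
    allele frequencies, N(0, 0.05) between-population frequency jitter,
    and a 90%-frequency sweep haplotype spanning +/-300 kb around the
    middle of chromosome 1.
    """

    n_snps: int = 20_000
    n_chrom: int = 5
    chrom_length_bp: int = 100_000_000
    n_samples_sel: int = 100
    n_samples_ref: int = 100
    base_freq_a: float = 0.5
    base_freq_b: float = 0.5
    divergence_noise_sd: float = 0.05
    sweep_chrom: str = "1"
    sweep_pos_bp: int = 50_000_000
    sweep_final_freq: float = 0.9
    sweep_core_halfwidth_bp: int = 300_000
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.sweep_final_freq <= 1.0):
            raise ValueError("sweep_final_freq must be in [0, 1]")
        if not (1 <= self.sweep_pos_bp <= self.chrom_length_bp):
            raise ValueError("sweep_pos_bp outside chromosome")
        if self.sweep_chrom not in {str(c + 1) for c in range(self.n_chrom)}:
            raise ValueError("sweep_chrom not among simulated chromosomes")
        if self.n_snps < self.n_chrom:
            raise ValueError("need at least one SNP per chromosome")


@dataclass(frozen=True)
class SweepTruth:
    """Where the sweep was planted and what frequency it reached."""

    sweep_chrom: str
    sweep_pos_bp: int
    sweep_start_bp: int
    sweep_end_bp: int
    freq_selected: float
    freq_reference: float
    is_null: bool

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def null_scenario(scenario: SweepScenario) -> SweepScenario:
    """Copy of a scenario with the sweep switched off (frequency 0)."""
    return dataclasses.replace(scenario, sweep_final_freq=0.0)


def _chrom_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct sorted 1-based positions, uniform over the chromosome."""
    pos: set[int] = set()
    while len(pos) < n:
        draw = rng.integers(1, length + 1, size=n - len(pos))
        pos.update(int(x) for x in draw)
    return np.sort(np.fromiter(pos, dtype=np.int64, count=n))


def simulate(
    scenario: SweepScenario,
) -> tuple[SnpMap, HaplotypePanel, GroupAssignment, SweepTruth]:
    """Generate (map, panel, groups, truth) for a scenario.

    Fixed seeds give bit-identical output. Allele coding fixes REF as the
    ancestral and ALT as the derived allele at every SNP: the ancestral
    allele frequency is drawn from Beta(a, b) and the shared ALT (derived)
    base frequency is its complement. Keeping the ancestral state a fixed
    reference (rather than, say, the major allele) keeps the derived-
    frequency contrast symmetric around zero under the null and
    statistically decoupled from the homozygosity contrast — each
    constituent then rises only for its own kind of signal.
    """
    rng = np.random.default_rng(scenario.seed)
    per_chrom = np.full(scenario.n_chrom, scenario.n_snps // scenario.n_chrom)
    per_chrom[: scenario.n_snps % scenario.n_chrom] += 1

    ids, chroms, poss = [], [], []
    for c in range(scenario.n_chrom):
        chrom = str(c + 1)
        p = _chrom_positions(rng, int(per_chrom[c]), scenario.chrom_length_bp)
        poss.append(p)
        chroms.extend([chrom] * len(p))
        ids.extend(f"snp{chrom}_{k + 1}" for k in range(len(p)))
    pos_bp = np.concatenate(poss)
    chrom_arr = np.asarray(chroms, dtype=object)

    # ancestral (REF) frequency ~ Beta(a, b); shared derived (ALT) base
    # frequency is its complement, then per-population jitter
    f_anc = rng.beta(scenario.base_freq_a, scenario.base_freq_b, size=scenario.n_snps)
    f_base = 1.0 - f_anc
    jitter = rng.normal(0.0, scenario.divergence_noise_sd, size=(2, scenario.n_snps))
    f_sel = np.clip(f_base + jitter[0], 0.0, 1.0)
    f_ref = np.clip(f_base + jitter[1], 0.0, 1.0)

    ancestral = np.full(scenario.n_snps, ANCESTRAL_REF, dtype=object)
    snp_map = SnpMap.from_arrays(ids, chrom_arr, pos_bp, ancestral)

    n_hap_sel = 2 * scenario.n_samples_sel
    n_hap_ref = 2 * scenario.n_samples_ref
    hap_sel = (rng.random((n_hap_sel, scenario.n_snps)) < f_sel).astype(np.uint8)
    hap_ref = (rng.random((n_hap_ref, scenario.n_snps)) < f_ref).astype(np.uint8)

    # plant the sweep haplotype in the SELECTED population
    on_chrom = chrom_arr == scenario.sweep_chrom
    in_interval = on_chrom & (
        np.abs(pos_bp - scenario.sweep_pos_bp) <= scenario.sweep_core_halfwidth_bp
    )
    interval_idx = np.flatnonzero(in_interval)
    chrom_idx = np.flatnonzero(on_chrom)
    focal = chrom_idx[np.argmin(np.abs(pos_bp[chrom_idx] - scenario.sweep_pos_bp))]

    carriers = np.zeros(n_hap_sel, dtype=bool)
    ref_match = 0.0
    if scenario.sweep_final_freq > 0 and len(interval_idx):
        sweep_hap = (rng.random(len(interval_idx)) < f_sel[interval_idx]).astype(np.uint8)
        sweep_hap[np.searchsorted(interval_idx, focal)] = 1  # derived (ALT) at the focus
        carriers = rng.random(n_hap_sel) < scenario.sweep_final_freq
        hap_sel[np.ix_(carriers, interval_idx)] = sweep_hap
        ref_match = float(np.all(hap_ref[:, interval_idx] == sweep_hap, axis=1).mean())

    alleles = np.concatenate([hap_sel, hap_ref], axis=0)
    sel_ids = [f"S{i + 1:04d}" for i in range(scenario.n_samples_sel)]
    ref_ids = [f"R{i + 1:04d}" for i in range(scenario.n_samples_ref)]
    panel = HaplotypePanel(alleles, tuple(sel_ids + ref_ids))
    groups = GroupAssignment(
        {**{s: SELECTED for s in sel_ids}, **{s: REFERENCE for s in ref_ids}}
    )
    truth = SweepTruth(
        sweep_chrom=scenario.sweep_chrom,
        sweep_pos_bp=int(scenario.sweep_pos_bp),
        sweep_start_bp=int(max(1, scenario.sweep_pos_bp - scenario.sweep_core_halfwidth_bp)),
        sweep_end_bp=int(scenario.sweep_pos_bp + scenario.sweep_core_halfwidth_bp),
        freq_selected=float(carriers.mean()),
        freq_reference=float(ref_match),
        is_null=scenario.sweep_final_freq == 0.0,
    )
    return snp_map, panel, groups, truth


def write_scenario_files(
    out_dir: str | Path,
    snp_map: SnpMap,
    panel: HaplotypePanel,
    groups: GroupAssignment,
    truth: SweepTruth | None = None,
) -> dict[str, Path]:
    """Write THAP + map + group (+ truth JSON) files for CLI round trips."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hap": out / "panel.thap",
        "map": out / "panel.map",
        "groups": out / "groups.txt",
    }
    np.savetxt(paths["hap"], panel.alleles.T, fmt="%d", delimiter=" ")
    with open(paths["map"], "w") as fh:
        for i in range(len(snp_map)):
            fh.write(
                f"{snp_map.snp_id[i]} {snp_map.chrom[i]} "
                f"{snp_map.pos_bp[i]} {snp_map.ancestral[i]}\n"
            )
    with open(paths["groups"], "w") as fh:
        fh.write("# sample_id group\n")
        for s in panel.sample_ids:
            fh.write(f"{s} {groups.group_of[s]}\n")
    if truth is not None:
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(truth.to_json() + "\n")
    return paths
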