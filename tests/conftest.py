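"""Shared fixtures: simulated panels and full scans reused across tests."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from csscan.pipeline import scan
from csscan.simulate import SweepScenario, null_scenario, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sweep():
    """Default sweep scenario panel (seed 1): the reference study conditions."""
    scenario = SweepScenario(seed=1)
    return (*simulate(scenario), scenario)


@pytest.fixture(scope="session")
def sweep_scan(default_sweep):
    """Full pipeline result on the default sweep panel."""
    snp_map, panel, groups, truth, _ = default_sweep
    return scan(snp_map, panel, groups), truth


@pytest.fixture(scope="session")
def null_scan():
    """Full pipeline result on the matched null (no-sweep) panel."""
    scenario = null_scenario(SweepScenario(seed=1))
    snp_map, panel, groups, truth = simulate(scenario)
    return scan(snp_map, panel, groups), truth


@pytest.fixture(scope="session")
def small_sweep():
    """A small, fast sweep scenario for end-to-end and CLI tests."""
    scenario = SweepScenario(
        n_snps=3000, n_chrom=2, chrom_length_bp=30_000_000,
        n_samples_sel=40, n_samples_ref=40,
        sweep_chrom="1", sweep_pos_bp=15_000_000, seed=5,
    )
    return (*simulate(scenario), scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
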