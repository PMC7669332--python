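"""Shared fixtures: reference configurations and batches of paired runs.

The expensive session fixtures (20-seed batches of paired network/isolated
simulations) are shared between the statistical property tests and the
acceptance tests so each batch is simulated once per session.
"""

import pytest

from eisync import experiments, io

N_SEEDS = 20


@pytest.fixture(scope="session")
def baseline_cfg():
    """Fully connected baseline, noise condition (sigma_n_s = 0.5)."""
    return io.load_reference_config("fully_connected_baseline")


@pytest.fixture(scope="session")
def nonoise_cfg(baseline_cfg):
    return baseline_cfg.replace(sigma_n_s=0.0)


@pytest.fixture(scope="session")
def hetero_cfg():
    """Randomly connected heterogeneous configuration."""
    return io.load_reference_config("random_heterogeneous")


@pytest.fixture(scope="session")
def noise_runs(baseline_cfg):
    return [experiments.run_paired(baseline_cfg, seed=s) for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def nonoise_runs(nonoise_cfg):
    return [experiments.run_paired(nonoise_cfg, seed=s) for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def hetero_runs(hetero_cfg):
    return [experiments.run_paired(hetero_cfg, seed=s) for s in range(N_SEEDS)]


@pytest.fixture()
def tiny_cfg(baseline_cfg):
    """Small, fast configuration for IO/CLI plumbing tests (weights rescaled
    to the smaller population so the dynamics stay balanced)."""
    return baseline_cfg.replace(
        n_e=40, n_i=12, duration=100.0,
        g_ee=1.2 / 52, g_ei=1.2 / 52, g_ie=7.0 / 52, g_ii=7.0 / 52,
    )
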