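"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import pytest

from mirprof import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimulationConfig:
    return sim.SimulationConfig(
        n_hairpins=30,
        seed=11,
        reads_per_library=5_000,
        stages=("A", "B"),
        replicates_per_stage=3,
        per_base_error_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_ref(small_config):
    return sim.generate_reference(small_config)


@pytest.fixture(scope="session")
def small_run(small_config, small_ref):
    """(CountMatrix, TrueState) for the small error-free design."""
    return sim.simulate_expression_matrix(small_ref, small_config)
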