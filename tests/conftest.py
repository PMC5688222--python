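"""Shared fixtures: full-scale seeded batches reused across acceptance tests."""

import pytest

from atpsim import ModelConfig, get_protocol, run_experiment

N_RUNS = 50
SEED_BASE = 1


@pytest.fixture(scope="session")
def default_model():
    return ModelConfig()


@pytest.fixture(scope="session")
def ko_expl_batch(default_model):
    """Two-lever within-subjects condition, 50 seeded runs."""
    return run_experiment(
        get_protocol("ko_expl"), default_model, n_runs=N_RUNS, seed_base=SEED_BASE
    )


@pytest.fixture(scope="session")
def svartdal_batches(default_model):
    """All three single-rule conditions, 50 seeded runs each."""
    return {
        name: run_experiment(
            get_protocol(name), default_model, n_runs=N_RUNS, seed_base=SEED_BASE
        )
        for name in ("svartdal_multi", "svartdal_high", "svartdal_low")
    }
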