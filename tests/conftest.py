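import numpy as np
import pytest

from synstress import ModelConfig, find_stationary_points, run_scenario


@pytest.fixture(scope="session")
def config():
    """Default model configuration (calibrated study conditions)."""
    return ModelConfig()


@pytest.fixture(scope="session")
def stationary_points(config):
    return find_stationary_points(config.core)


@pytest.fixture(scope="session")
def scenario_results(config):
    """All twelve stimulation scenarios, run once per session."""
    names = (
        "fig4a", "fig4b", "fig4c", "fig5a", "fig5b", "fig5c",
        "fig6_low", "fig6_high", "fig6_zero",
        "fig7_low", "fig7_high", "fig7_zero",
    )
    return {name: run_scenario(name, config) for name in names}


@pytest.fixture(scope="session")
def folds(scenario_results):
    return {k: r.fold_change for k, r in scenario_results.items()}
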