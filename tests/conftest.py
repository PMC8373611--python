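import pytest
from hypothesis import settings as hypothesis_settings

from pragmalex import MCMCSettings, default_design, default_truth, simulate_experiment

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def small_study(truth):
    """Modest three-experiment synthetic table shared by I/O and binning tests."""
    import pandas as pd
    from pragmalex import simulate_study

    return simulate_study(truth, seed=11, n_children_per_year=12)


@pytest.fixture(scope="session")
def reduced_settings():
    return MCMCSettings.reduced()


@pytest.fixture(scope="session")
def exp12_posterior(truth, reduced_settings):
    """One prediction-stage integration fit on synthetic Experiments 1-2,
    shared across prediction/evaluation tests to keep the suite fast."""
    import pandas as pd
    from pragmalex import ModelName, fit

    tables = [
        simulate_experiment(default_design("exp1", 30), truth, seed=101),
        simulate_experiment(default_design("exp2", 20), truth, seed=102),
    ]
    data = pd.concat(tables, ignore_index=True)
    return fit(ModelName.INTEGRATION, data, settings=reduced_settings, seed=5,
               stage="prediction")
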