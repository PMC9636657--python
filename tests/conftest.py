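import pytest

import callusopt as co


@pytest.fixture(scope="session")
def default_raw():
    """One seeded default-condition replicate table (192 x 24 rows)."""
    return co.simulate_experiment(co.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def summaries(default_raw):
    return co.summarize_conditions(default_raw)


@pytest.fixture(scope="session")
def summaries_desirability(default_raw):
    """Per-condition summaries with speed on the mm/day desirability scale."""
    return co.summarize_conditions(default_raw, speed_mode="inverted")


@pytest.fixture(scope="session")
def noise_free_summaries():
    """Analytic (infinite-replicate) summaries of the default effect table."""
    return co.expected_summaries()


@pytest.fixture(scope="session")
def surrogates(summaries, summaries_desirability):
    """MLP surrogates for both objectives, trained on the default data."""
    cfg = co.MLPConfig(seed=1)
    return (
        co.train_mlp(summaries, "percentage", cfg),
        co.train_mlp(summaries_desirability, "speed", cfg),
    )
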