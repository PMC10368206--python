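import numpy as np
import pytest
from hypothesis import settings

from tpsd import behavior, synth

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def _bundle(stage: str, seed: int = 0, n_trials: int = 200, n_cells: int = 40):
    cfg = synth.FixtureConfig(
        stage=stage,
        n_trials=n_trials,
        ratio=0.5,
        population=synth.PopulationSpec(
            stage=stage, n_cells=n_cells, fraction_lick_cells=0.1, lick_coupling=1.0
        ),
    )
    return synth.make_fixture(cfg, seed)


@pytest.fixture(scope="session")
def learned_bundle():
    """Balanced learned-regime session: 200 trials, 40 cells, planted truth."""
    return _bundle("learned")


@pytest.fixture(scope="session")
def naive_bundle():
    return _bundle("naive")


@pytest.fixture(scope="session")
def learned_outcomes(learned_bundle):
    return behavior.label_outcomes(
        learned_bundle.schedule, learned_bundle.licks,
        learned_bundle.config.threshold, (1.0, 2.0),
    )


@pytest.fixture(scope="session")
def naive_outcomes(naive_bundle):
    return behavior.label_outcomes(
        naive_bundle.schedule, naive_bundle.licks,
        naive_bundle.config.threshold, (1.0, 2.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
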