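"""Shared fixture handling for the numbered analysis drivers."""

from pathlib import Path

from tpsd import behavior, synth

RESULTS = Path(__file__).resolve().parent.parent / "results"
FIXTURES = RESULTS / "fixtures"

RESPONSE_WINDOW = (1.0, 2.0)


def session_config(stage: str) -> synth.FixtureConfig:
    """Demo-scale session: 200 balanced trials, 50 cells with planted truth."""
    return synth.FixtureConfig(
        stage=stage, n_trials=200, ratio=0.5,
        population=synth.PopulationSpec(
            stage=stage, n_cells=50, fraction_lick_cells=0.1, lick_coupling=1.0
        ),
    )


def load_or_simulate(stage: str, seed: int) -> synth.SessionBundle:
    path = FIXTURES / stage
    if (path / "config.yaml").exists():
        bundle = synth.SessionBundle.load(path)
        if bundle.seed == seed:
            return bundle
    bundle = synth.make_fixture(session_config(stage), seed)
    bundle.save(path)
    return bundle


def labeled(bundle: synth.SessionBundle):
    return behavior.label_outcomes(
        bundle.schedule, bundle.licks, bundle.config.threshold, RESPONSE_WINDOW
    )
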