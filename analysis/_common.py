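"""Shared paths and pipeline wiring for the analysis drivers."""

from pathlib import Path

from bivalentscope.pipeline import RunConfig, fixture_run_config, run

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "results" / "fixture"
RESULTS = ROOT / "results" / "analysis"


def run_analyses(analyses, **overrides):
    if not FIXTURE.exists():
        raise SystemExit("fixture missing - run analysis/01_simulate.py first")
    config = fixture_run_config(FIXTURE, RESULTS, analyses=list(analyses),
                                seed=2, **overrides)
    return run(config)
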