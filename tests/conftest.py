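"""Shared fixtures: rendered scenarios reused across test modules."""

from dataclasses import replace

import pytest

import zfecg
from zfecg.preprocess import FilterConfig
from zfecg.simulator import NoiseSpec

# Simulator output already models post-acquisition data (residual line
# noise only), so the detection chain skips the external-recording notch.
SIM_FILTER = FilterConfig(notch_enabled=False)

BASELINE_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def baseline_runs():
    """(truth, analysis) for 120 s baseline renders, seeds 0-9, preset noise."""
    runs = []
    for seed in BASELINE_SEEDS:
        record, truth = zfecg.render_record(zfecg.preset("baseline_ab", seed=seed))
        runs.append((truth, zfecg.analyze_record(record, SIM_FILTER)))
    return runs


@pytest.fixture(scope="session")
def clean_baseline():
    """A noise-free 60 s baseline render with its analysis."""
    spec = replace(zfecg.preset("baseline_ab", seed=0, duration_s=60.0),
                   noise=NoiseSpec.none())
    record, truth = zfecg.render_record(spec)
    return record, truth, zfecg.analyze_record(record, SIM_FILTER)
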