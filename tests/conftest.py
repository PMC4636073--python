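"""Shared fixtures: one session-scoped synthetic dataset at the default
study conditions, regenerated from code (no stored data files)."""

from __future__ import annotations

import pytest

from omicloom import synth


@pytest.fixture(scope="session")
def config() -> synth.SimulationConfig:
    return synth.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(config):
    """(genome, annotation, truth) for the default synthetic study."""
    return synth.generate_genome(config)


@pytest.fixture(scope="session")
def pileup(dataset, config):
    genome, annotation, truth = dataset
    return synth.simulate_rna_pileup(genome, annotation, truth, config)


@pytest.fixture(scope="session")
def pipeline_run(config):
    from omicloom.pipeline import run_pipeline

    manifest, outputs = run_pipeline(config)
    return manifest, outputs
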