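"""Shared fixtures: one calibration and one set of full AL runs per session."""

from __future__ import annotations

import warnings

import pytest

from probitab.active_learning import ALConfig, run_loop
from probitab.design import DesignSpace
from probitab.oracle import CompactionOracle, calibrate


@pytest.fixture(scope="session")
def calibration():
    """Full oracle calibration from package defaults (runs once)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return calibrate()


@pytest.fixture(scope="session")
def oracle(calibration):
    return CompactionOracle(calibration.params)


@pytest.fixture(scope="session")
def space():
    return DesignSpace()


@pytest.fixture(scope="session")
def al_states(oracle, space):
    """Five full default active-learning runs (seeds 1-5), shared across
    the acceptance and property tests."""
    return {seed: run_loop(oracle.survival, space, ALConfig(seed=seed))
            for seed in range(1, 6)}
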