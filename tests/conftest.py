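"""Shared fixtures: cached forward demographies and replicate frames.

The forward demography is deterministic per scenario, and replicate frames
are pure functions of (scenario, n_reps, master seed), so session-scoped
caches let tests share the expensive simulations without coupling outcomes.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

import serialcoal as sc

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None
)
settings.load_profile("suite")

_scenarios: dict = {}
_demographies: dict = {}
_frames: dict = {}


def get_scenario(name: str) -> sc.ScenarioConfig:
    if name not in _scenarios:
        _scenarios[name] = sc.load_bundled_scenario(name)
    return _scenarios[name]


def get_demography(name: str) -> sc.ForwardDemography:
    if name not in _demographies:
        _demographies[name] = sc.run_forward(get_scenario(name))
    return _demographies[name]


def get_frame(name: str, n_reps: int, seed: int):
    key = (name, n_reps, seed)
    if key not in _frames:
        _frames[key] = sc.run_replicates(
            get_scenario(name), n_reps, seed, demography=get_demography(name)
        )
    return _frames[key]


@pytest.fixture(scope="session")
def scenario():
    """Callable: bundled scenario by name (cached)."""
    return get_scenario


@pytest.fixture(scope="session")
def demography():
    """Callable: forward demography by scenario name (cached)."""
    return get_demography


@pytest.fixture(scope="session")
def frame():
    """Callable: replicate summary-stats frame by (name, reps, seed) (cached)."""
    return get_frame
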