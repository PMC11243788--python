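"""Shared fixtures: small synthetic trials and segmented datasets.

Everything is generated programmatically with fixed seeds; heavier
session-scoped fixtures are shared across test modules to keep the suite
fast.
"""

from __future__ import annotations

import pytest

import emgknee as ek


def trial_to_dataset(trial, train_frac: float = 0.6, L: int = 100):
    """Condition -> split -> normalize -> dataset, the standard path."""
    emg, ang = ek.align_streams(trial.emg, trial.angle)
    cond = ek.condition(emg)
    cycles = [ek.time_normalize(c, L)
              for c in ek.split_cycles(cond, ang, trial.events)]
    return ek.make_dataset(cycles, train_frac)


@pytest.fixture(scope="session")
def presets():
    return ek.make_presets()


@pytest.fixture(scope="session")
def hv8_trial(presets):
    """12 strides of the 8-channel healthy preset at standard noise."""
    return presets["hv8"].synthesize(n_strides=12, seed=1)


@pytest.fixture(scope="session")
def hv8_dataset(hv8_trial):
    return trial_to_dataset(hv8_trial)


@pytest.fixture(scope="session")
def shared6_trial(presets):
    return presets["shared6"].synthesize(n_strides=10, seed=2)


@pytest.fixture(scope="session")
def shared6_dataset(shared6_trial):
    return trial_to_dataset(shared6_trial)


@pytest.fixture
def tiny_cfg():
    """A deliberately small estimator for fast structural tests."""
    return ek.GruAmConfig(hidden_size=8, attn_size=6, seed=0, max_epochs=2)
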