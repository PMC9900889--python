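"""Shared fixtures: scaled trained models and their session analyses.

The heavy fixtures train real models at a reduced scale (128 hidden units,
several thousand updates instead of the full 30000) chosen so the whole
suite runs on one CPU in minutes while still producing the ring-attractor
geometry the analyses target.  They are session-scoped: each model is
trained once per pytest run and reused by every test that needs it.
"""

import dataclasses

import numpy as np
import pytest

from ringremap.session import build_session, compute_tuning_curves
from ringremap.task import TaskConfig
from ringremap.train import TrainConfig, train


def _train(n_states, n_spatial_dims, n_updates, curriculum_step, seed,
           n_units=128):
    task = TaskConfig(n_states=n_states, n_spatial_dims=n_spatial_dims)
    cfg = TrainConfig(n_updates=n_updates, curriculum_step=curriculum_step,
                      learning_rate=1e-3, seed=seed)
    params, history = train(task, cfg, n_units=n_units)
    return params, task, cfg, history


@pytest.fixture(scope="session")
def model_2state():
    """1D two-state model, 128 units, 6000 updates (curriculum to T=120)."""
    params, task, cfg, history = _train(2, 1, 6000, 50, seed=1)
    return {"params": params, "task": task, "cfg": cfg, "history": history}


@pytest.fixture(scope="session")
def model_3state():
    """1D three-state model, 128 units, 6000 updates."""
    params, task, cfg, history = _train(3, 1, 6000, 50, seed=2)
    return {"params": params, "task": task, "cfg": cfg, "history": history}


@pytest.fixture(scope="session")
def model_2d():
    """2D two-state model, 128 units, 4500 updates (curriculum to T=180)."""
    params, task, cfg, history = _train(2, 2, 4500, 25, seed=1)
    return {"params": params, "task": task, "cfg": cfg, "history": history}


@pytest.fixture(scope="session")
def session_2state(model_2state):
    """Session-mode rollout of the two-state model with tuning curves.

    Short sequences (150 steps) keep within-sequence integrator drift small
    so the position-binned manifolds are not smeared.
    """
    task = dataclasses.replace(model_2state["task"], seq_len=150)
    rec = build_session(model_2state["params"], task, seed=7,
                        n_sequences=100)
    curves = compute_tuning_curves(rec, n_bins=50)
    return {"recording": rec, "curves": curves, **model_2state}


@pytest.fixture(scope="session")
def session_3state(model_3state):
    task = dataclasses.replace(model_3state["task"], seq_len=150)
    rec = build_session(model_3state["params"], task, seed=7,
                        n_sequences=80)
    curves = compute_tuning_curves(rec, n_bins=50)
    return {"recording": rec, "curves": curves, **model_3state}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
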