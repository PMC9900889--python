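"""Scikit-learn-style estimator wrapping task generation and training."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .rnn import simulate
from .task import TaskConfig, TrialBatch, generate_trial
from .train import TrainConfig, circular_error, evaluate, train

__all__ = ["RemapRNN"]


class RemapRNN(BaseEstimator):
    """Recurrent network for circular navigation with latent-state inference.

    ``fit`` trains an Elman network by curriculum SGD on sequences generated
    internally from the task distribution (the infinite-data regime), so the
    usual ``X, y`` arguments are accepted but ignored.  ``predict`` decodes
    latent states from a :class:`~ringremap.task.TrialBatch`;
    ``predict_angle`` decodes angular position.

    Parameters mirror :class:`~ringremap.task.TaskConfig` and
    :class:`~ringremap.train.TrainConfig`; see those classes for semantics.

    Attributes
    ----------
    params_ : RNNParams
        The seven trained parameter groups {A, B, beta, C, alpha, D, gamma}.
    history_ : pandas.DataFrame
        Per-update losses, curriculum length and gradient norm.
    task_ : TaskConfig
        The task distribution the model was trained on.
    """

    def __init__(self, n_units=248, n_states=2, n_spatial_dims=1,
                 mean_drift_sd=0.1, step_noise_sd=0.3, cue_rate=1.0 / 50.0,
                 cue_duration=2, n_updates=30000, batch_size=124,
                 curriculum_step=50, start_len=1, clip_norm=2.0,
                 learning_rate=0.05, random_state=None):
        self.n_units = n_units
        self.n_states = n_states
        self.n_spatial_dims = n_spatial_dims
        self.mean_drift_sd = mean_drift_sd
        self.step_noise_sd = step_noise_sd
        self.cue_rate = cue_rate
        self.cue_duration = cue_duration
        self.n_updates = n_updates
        self.batch_size = batch_size
        self.curriculum_step = curriculum_step
        self.start_len = start_len
        self.clip_norm = clip_norm
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _task_config(self, **overrides) -> TaskConfig:
        kw = dict(n_spatial_dims=self.n_spatial_dims, n_states=self.n_states,
                  mean_drift_sd=self.mean_drift_sd,
                  step_noise_sd=self.step_noise_sd, cue_rate=self.cue_rate,
                  cue_duration=self.cue_duration)
        kw.update(overrides)
        return TaskConfig(**kw)

    def fit(self, X=None, y=None):
        """Train on freshly generated task sequences; X and y are ignored."""
        task = self._task_config()
        cfg = TrainConfig(
            n_updates=self.n_updates, batch_size=self.batch_size,
            curriculum_step=self.curriculum_step, start_len=self.start_len,
            clip_norm=self.clip_norm, learning_rate=self.learning_rate,
            seed=0 if self.random_state is None else int(self.random_state))
        self.task_ = task
        self.params_, self.history_ = train(task, cfg, n_units=self.n_units)
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("RemapRNN instance is not fitted yet")

    def simulate(self, trial: TrialBatch):
        self._check_fitted()
        return simulate(self.params_, trial)

    def predict(self, X: TrialBatch) -> np.ndarray:
        """Decoded latent-state labels, shape (n_sequences, T)."""
        return self.simulate(X).decoded_state

    def predict_angle(self, X: TrialBatch) -> np.ndarray:
        """Decoded angular position in [0, 2*pi), shape (n_sequences, T, d)."""
        return self.simulate(X).decoded_angle

    def score(self, X: TrialBatch = None, y=None) -> float:
        """Held-out state-classification accuracy as a fraction in [0, 1].

        With ``X=None`` a fresh evaluation batch is generated from the
        training task distribution.
        """
        self._check_fitted()
        if X is None:
            m = evaluate(self.params_, self.task_, seed=self.random_state)
            return m["state_accuracy"] / 100.0
        return float(np.mean(self.predict(X) == X.target_state))

    def evaluate(self, n_trials: int = 100, horizon: int = 300,
                 seed=None) -> dict:
        """Full held-out metrics (state accuracy %, angular error deg, losses)."""
        self._check_fitted()
        return evaluate(self.params_, self.task_, n_trials=n_trials,
                        horizon=horizon, seed=seed)

    def sample_trials(self, n_trials: int, seq_len: int, seed=None,
                      session_mode: bool = False) -> TrialBatch:
        """Generate trials from the training task distribution."""
        task = self._task_config(seq_len=seq_len)
        if session_mode:
            task = task.session_mode()
        return generate_trial(task, seed, n_trials=n_trials)
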