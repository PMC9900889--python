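"""Synthetic task generation: circular navigation with transiently cued latent states.

The task couples two demands on one recurrent circuit: integrate an angular
velocity signal along a periodic (circular-linear) environment in one or two
spatial dimensions, and report which of K discrete latent states ("contexts")
is currently active, given only brief cue pulses at state changes.  All data
are generated here — velocity streams, cue trains, initial-condition
encodings, and the ground-truth targets used for training and evaluation.

Two regimes are supported:

* training mode — signed velocities, state changes at an expected rate of one
  per 50 steps (the regime the networks are optimized in);
* session mode — nonnegative velocities from angle 0 and rare state changes
  (one per 500 steps), emulating trialized track traversals of a biological
  recording session.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["TaskConfig", "TrialBatch", "generate_trial", "wrap_angle"]

TWO_PI = 2.0 * np.pi


def wrap_angle(angle):
    """Wrap angles (radians) onto the periodic track, i.e. into [0, 2*pi).

    Accepts scalars or arrays; the result is congruent to the input mod 2*pi.
    """
    angle = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(angle)):
        raise ValueError("wrap_angle requires finite input")
    out = np.mod(angle, TWO_PI)
    # mod can return 2*pi for inputs just below 0 due to rounding
    out = np.where(out >= TWO_PI, out - TWO_PI, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class TaskConfig:
    """Parameterization of the navigation + latent-state-inference task.

    Parameters
    ----------
    n_spatial_dims : int
        1 (circular track) or 2 (toroidal arena).
    n_states : int
        Number of latent states K (>= 2).
    seq_len : int
        Sequence length T in time steps.
    mean_drift_sd : float
        SD (radians) of the per-sequence mean velocity, drawn N(0, .).
    step_noise_sd : float
        SD (radians) of the per-step velocity noise.
    cue_rate : float
        Expected state changes per time step (homogeneous Poisson,
        realized as per-step Bernoulli events).
    cue_duration : int
        Length of each cue pulse in time steps.
    nonnegative_velocity : bool
        Session regime: velocities are abs(mean + noise) and the initial
        angle is 0, so the trajectory sweeps the track in one direction.
    """

    n_spatial_dims: int = 1
    n_states: int = 2
    seq_len: int = 600
    mean_drift_sd: float = 0.1
    step_noise_sd: float = 0.3
    cue_rate: float = 1.0 / 50.0
    cue_duration: int = 2
    nonnegative_velocity: bool = False

    def __post_init__(self):
        if self.n_spatial_dims not in (1, 2):
            raise ValueError("n_spatial_dims must be 1 or 2")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if self.cue_duration < 1:
            raise ValueError("cue_duration must be >= 1")
        if not (0.0 < self.cue_rate < 1.0):
            raise ValueError("cue_rate must lie in (0, 1)")
        if self.mean_drift_sd < 0 or self.step_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")

    # --- derived sizes -------------------------------------------------
    @property
    def n_inputs(self) -> int:
        """M: velocity channels plus one cue channel per latent state."""
        return self.n_states + self.n_spatial_dims

    @property
    def n_outputs(self) -> int:
        """L: (cos, sin) per spatial dimension plus K state logits."""
        return self.n_states + 2 * self.n_spatial_dims

    @property
    def n_init_inputs(self) -> int:
        """M0: (sin, cos) of the initial angle per spatial dimension."""
        return 2 * self.n_spatial_dims

    def session_mode(self, cue_rate: float = 1.0 / 500.0) -> "TaskConfig":
        """Return a copy configured for biological-session emulation."""
        return dataclasses.replace(
            self, cue_rate=cue_rate, nonnegative_velocity=True
        )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TrialBatch:
    """A batch of generated sequences with ground-truth targets.

    Attributes
    ----------
    inputs : (B, T, M) float
        Per-step input u_t: velocity (radians/step) for each spatial
        dimension, then K binary cue channels.
    init_encoding : (B, M0) float
        z = (sin th0, cos th0) per spatial dimension.
    target_position : (B, T, 2*d) float
        (cos th_t, sin th_t) per spatial dimension for t = 1..T, aligned
        with the network output after consuming input u_{t-1}.
    target_state : (B, T) int
        Active latent state (0-based) aligned with target_position.
    true_angles : (B, T+1, d) float
        Angles th_0..th_T in [0, 2*pi).
    """

    inputs: np.ndarray
    init_encoding: np.ndarray
    target_position: np.ndarray
    target_state: np.ndarray
    true_angles: np.ndarray
    config: TaskConfig = field(repr=False, default=None)

    @property
    def n_trials(self) -> int:
        return self.inputs.shape[0]

    @property
    def seq_len(self) -> int:
        return self.inputs.shape[1]

    def save(self, path):
        """Serialize to an HDF5 container with one named dataset per field."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("inputs", data=self.inputs)
            fh.create_dataset("init_encoding", data=self.init_encoding)
            fh.create_dataset("target_position", data=self.target_position)
            fh.create_dataset("target_state", data=self.target_state)
            fh.create_dataset("true_angles", data=self.true_angles)
            if self.config is not None:
                fh.attrs["config"] = yaml.safe_dump(
                    dataclasses.asdict(self.config)
                )

    @classmethod
    def load(cls, path) -> "TrialBatch":
        import h5py

        with h5py.File(path, "r") as fh:
            cfg = None
            if "config" in fh.attrs:
                cfg = TaskConfig(**yaml.safe_load(fh.attrs["config"]))
            return cls(
                inputs=fh["inputs"][()],
                init_encoding=fh["init_encoding"][()],
                target_position=fh["target_position"][()],
                target_state=fh["target_state"][()],
                true_angles=fh["true_angles"][()],
                config=cfg,
            )


def _generate_states(config: TaskConfig, n_trials: int, rng: np.random.Generator):
    """Simulate the cue process and latent-state trajectory.

    Returns (cues, states): cues is (B, T, K) with unit pulses, states is
    (B, T) where states[:, t] is the state active after the cue (if any)
    at step t has been delivered — i.e. the label the network should report
    once it has consumed input u_t.

    State-change events follow a per-step Bernoulli(cue_rate) process (the
    discrete-time homogeneous Poisson approximation).  An event arriving
    while a pulse is still being emitted is deferred step by step until the
    channel is free, so pulses never overlap.  The initial state is cued by
    a pulse over the first cue_duration steps, since the init encoding z
    carries only position.
    """
    K = config.n_states
    T = config.seq_len
    B = n_trials
    cues = np.zeros((B, T, K), dtype=float)
    states = np.zeros((B, T), dtype=np.int64)

    state = rng.integers(K, size=B)
    # initial-state pulse starts at t=0
    pulse_left = np.full(B, config.cue_duration, dtype=np.int64)
    pulse_chan = state.copy()
    pending = np.zeros(B, dtype=bool)

    events = rng.random((B, T)) < config.cue_rate
    # uniform draws used to pick the new state among the K-1 inactive ones
    picks = rng.integers(K - 1, size=(B, T))

    for t in range(T):
        want = events[:, t] | pending
        free = pulse_left == 0
        start = want & free
        pending = want & ~free
        if np.any(start):
            idx = np.flatnonzero(start)
            # map pick in {0..K-2} onto the inactive states
            new = picks[idx, t]
            new = new + (new >= state[idx])
            state[idx] = new
            pulse_chan[idx] = new
            pulse_left[idx] = config.cue_duration
        active = pulse_left > 0
        cues[np.flatnonzero(active), t, pulse_chan[active]] = 1.0
        pulse_left[active] -= 1
        states[:, t] = state
    return cues, states


def generate_trial(
    config: TaskConfig, seed=None, n_trials: int = 1
) -> TrialBatch:
    """Generate a batch of random task sequences.

    Velocities are dth_t = mean + eps_t with the per-sequence mean drawn
    N(0, mean_drift_sd) and eps_t i.i.d. N(0, step_noise_sd); in session
    mode the velocity is abs(mean + eps_t) and th0 = 0, otherwise th0 is
    uniform on [0, 2*pi).  The latent-state/cue process is described in
    :func:`_generate_states`.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed)
    B, T, d = n_trials, config.seq_len, config.n_spatial_dims

    mean_v = rng.normal(0.0, config.mean_drift_sd, size=(B, 1, d))
    noise = rng.normal(0.0, config.step_noise_sd, size=(B, T, d))
    dtheta = mean_v + noise
    if config.nonnegative_velocity:
        dtheta = np.abs(dtheta)
        theta0 = np.zeros((B, d))
    else:
        theta0 = rng.uniform(0.0, TWO_PI, size=(B, d))

    angles = np.empty((B, T + 1, d))
    angles[:, 0] = theta0
    angles[:, 1:] = theta0[:, None, :] + np.cumsum(dtheta, axis=1)
    angles = wrap_angle(angles)

    cues, states = _generate_states(config, B, rng)

    inputs = np.concatenate([dtheta, cues], axis=2)

    z = np.empty((B, 2 * d))
    z[:, 0::2] = np.sin(theta0)
    z[:, 1::2] = np.cos(theta0)

    tgt = np.empty((B, T, 2 * d))
    tgt[:, :, 0::2] = np.cos(angles[:, 1:])
    tgt[:, :, 1::2] = np.sin(angles[:, 1:])

    return TrialBatch(
        inputs=inputs,
        init_encoding=z,
        target_position=tgt,
        target_state=states,
        true_angles=angles,
        config=config,
    )
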