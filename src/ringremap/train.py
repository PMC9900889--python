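"""Training: composite loss, curriculum SGD with gradient clipping, evaluation.

Networks are trained on freshly generated sequences every update (an
infinite-data regime).  The loss is the unweighted sum of (i) the mean
squared error of the (cos, sin) position predictions and (ii) the
categorical cross-entropy of the state logits, both averaged over batch and
time.  Training follows a sequence-length curriculum — start at length 1 and
add one step every ``curriculum_step`` updates — with the global gradient
norm clipped each update.  Gradients are computed by backpropagation through
time; the arithmetic runs in float32 for speed and the returned parameters
are cast back to float64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rnn import RNNParams, init_params
from .task import TWO_PI, TaskConfig, TrialBatch, generate_trial

__all__ = [
    "TrainConfig",
    "TrainingDivergence",
    "composite_loss",
    "train",
    "evaluate",
]

_GROUPS = ("A", "B", "beta", "C", "alpha", "D", "gamma")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Under the full-scale defaults (30000 updates, one length increment per
    50 updates from length 1) the final curriculum length is 600 steps.

    ``optimizer`` is "adam" (default) or "sgd".  Plain SGD learns the state
    component but destabilizes the position integrator as the curriculum
    length grows; Adam trains both components reliably (see docs/methods.md).
    """

    n_updates: int = 30000
    batch_size: int = 124
    curriculum_step: int = 50
    start_len: int = 1
    clip_norm: float = 2.0
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if self.n_updates < 0 or self.batch_size < 1 or self.start_len < 1:
            raise ValueError("invalid training sizes")
        if self.curriculum_step < 1:
            raise ValueError("curriculum_step must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")

    def seq_len_at(self, update: int) -> int:
        """Curriculum sequence length used for a given update index."""
        return self.start_len + update // self.curriculum_step


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite; carries the history so far."""

    def __init__(self, message, history):
        super().__init__(message)
        self.history = history


def _softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def composite_loss(outputs: np.ndarray, trial: TrialBatch):
    """(total, position_mse, state_xent) for outputs aligned with y_1..y_T.

    ``outputs`` has shape (B, T, L); the position block is compared to the
    (cos, sin) targets by mean squared error over all elements, the state
    block by mean cross-entropy against the true labels.
    """
    d = trial.true_angles.shape[2]
    pos = outputs[..., : 2 * d]
    logits = outputs[..., 2 * d :]
    pos_mse = float(np.mean((pos - trial.target_position) ** 2))
    p = _softmax(logits)
    B, T = trial.target_state.shape
    idx_b, idx_t = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
    nll = -np.log(np.clip(p[idx_b, idx_t, trial.target_state], 1e-12, None))
    xent = float(np.mean(nll))
    return pos_mse + xent, pos_mse, xent


def _forward_backward(P: dict, trial: TrialBatch, d: int):
    """One BPTT pass. Returns (loss triple, gradients dict).

    Forward: x_0 = D z + gamma, x_{t+1} = ReLU(A x_t + B u_t + beta),
    y_t = C x_t + alpha graded for t = 1..T.  All arrays float32.
    """
    A, B_, beta = P["A"], P["B"], P["beta"]
    C, alpha, D, gamma = P["C"], P["alpha"], P["D"], P["gamma"]
    u = trial.inputs.astype(np.float32)
    z = trial.init_encoding.astype(np.float32)
    tgt_pos = trial.target_position.astype(np.float32)
    tgt_state = trial.target_state
    B, T, _ = u.shape
    N = A.shape[0]

    xs = np.empty((B, T + 1, N), dtype=np.float32)
    masks = np.empty((B, T, N), dtype=bool)
    xs[:, 0] = z @ D.T + gamma
    x = xs[:, 0]
    for t in range(T):
        pre = x @ A.T + u[:, t] @ B_.T + beta
        m = pre > 0
        x = np.where(m, pre, 0.0)
        xs[:, t + 1] = x
        masks[:, t] = m

    y = xs[:, 1:] @ C.T + alpha  # (B, T, L)
    pos = y[..., : 2 * d]
    logits = y[..., 2 * d :]

    pos_err = pos - tgt_pos
    pos_mse = float(np.mean(pos_err.astype(np.float64) ** 2))
    p = _softmax(logits.astype(np.float64))
    ib, it = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
    xent = float(np.mean(-np.log(np.clip(p[ib, it, tgt_state], 1e-12, None))))

    # gradient of the loss w.r.t. outputs
    G = np.empty_like(y)
    G[..., : 2 * d] = 2.0 * pos_err / pos_err.size
    onehot_err = p.copy()
    onehot_err[ib, it, tgt_state] -= 1.0
    G[..., 2 * d :] = (onehot_err / (B * T)).astype(np.float32)

    # readout gradients accumulate over all steps
    Gflat = G.reshape(B * T, -1)
    dC = Gflat.T @ xs[:, 1:].reshape(B * T, N)
    dalpha = Gflat.sum(axis=0)

    dA = np.zeros_like(A)
    dB = np.zeros_like(B_)
    dbeta = np.zeros_like(beta)
    delta = np.zeros((B, N), dtype=np.float32)  # grad w.r.t. x_t
    for t in range(T, 0, -1):
        delta = delta + G[:, t - 1] @ C
        e = np.where(masks[:, t - 1], delta, 0.0)  # grad w.r.t. pre-activation
        dA += e.T @ xs[:, t - 1]
        dB += e.T @ u[:, t - 1]
        dbeta += e.sum(axis=0)
        delta = e @ A
    # delta now holds the gradient w.r.t. x_0 (linear encoder, no ReLU)
    dD = delta.T @ z
    dgamma = delta.sum(axis=0)

    grads = {"A": dA, "B": dB, "beta": dbeta, "C": dC, "alpha": dalpha,
             "D": dD, "gamma": dgamma}
    return (pos_mse + xent, pos_mse, xent), grads


def _clip_gradients(grads: dict, clip_norm: float) -> float:
    norm = float(np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                             for g in grads.values())))
    if norm > clip_norm:
        scale = np.float32(clip_norm / norm)
        for g in grads.values():
            g *= scale
    return norm


def train(task: TaskConfig, cfg: TrainConfig,
          init: RNNParams | None = None, n_units: int = 248,
          callback=None):
    """Train a network on the task with curriculum SGD.

    Returns ``(params, history)`` where ``history`` is a DataFrame with one
    row per update (total/position/state loss, curriculum length, gradient
    norm before clipping).  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if init is None:
        init = init_params(n_units, task.n_states, task.n_spatial_dims,
                           seed=rng.integers(2**31))
    P = {name: arr.astype(np.float32).copy() for name, arr in init.groups()}
    d = task.n_spatial_dims
    lr = np.float32(cfg.learning_rate)

    hist = {k: np.empty(cfg.n_updates) for k in
            ("total_loss", "position_mse", "state_xent", "grad_norm")}
    hist["seq_len"] = np.empty(cfg.n_updates, dtype=int)

    use_adam = cfg.optimizer == "adam"
    if use_adam:
        m1 = {k: np.zeros_like(v) for k, v in P.items()}
        m2 = {k: np.zeros_like(v) for k, v in P.items()}
        b1, b2, eps = np.float32(0.9), np.float32(0.999), np.float32(1e-8)

    import dataclasses as _dc

    for it in range(cfg.n_updates):
        T = cfg.seq_len_at(it)
        trial = generate_trial(_dc.replace(task, seq_len=T), rng,
                               n_trials=cfg.batch_size)
        # divergence shows up as overflow before the finiteness check fires
        with np.errstate(over="ignore", invalid="ignore"):
            (total, pos_mse, xent), grads = _forward_backward(P, trial, d)
        if not np.isfinite(total):
            history = _history_frame(hist, it)
            raise TrainingDivergence(
                f"non-finite loss at update {it}", history)
        norm = _clip_gradients(grads, cfg.clip_norm)
        if use_adam:
            c1 = np.float32(1.0 - b1 ** (it + 1))
            c2 = np.float32(1.0 - b2 ** (it + 1))
            for name in _GROUPS:
                g = grads[name]
                m1[name] = b1 * m1[name] + (1 - b1) * g
                m2[name] = b2 * m2[name] + (1 - b2) * g * g
                P[name] -= lr * (m1[name] / c1) / (
                    np.sqrt(m2[name] / c2) + eps)
        else:
            for name in _GROUPS:
                P[name] -= lr * grads[name]
        hist["total_loss"][it] = total
        hist["position_mse"][it] = pos_mse
        hist["state_xent"][it] = xent
        hist["grad_norm"][it] = norm
        hist["seq_len"][it] = T
        if callback is not None:
            callback(it, total)

    params = RNNParams(
        n_states=task.n_states, n_spatial_dims=d,
        **{name: P[name].astype(np.float64) for name in _GROUPS})
    return params, _history_frame(hist, cfg.n_updates)


def _history_frame(hist: dict, n: int) -> pd.DataFrame:
    return pd.DataFrame({k: v[:n] for k, v in hist.items()})


def circular_error(a, b):
    """Absolute circular distance between angles, in radians."""
    diff = np.abs(np.asarray(a) - np.asarray(b)) % TWO_PI
    return np.minimum(diff, TWO_PI - diff)


def evaluate(params: RNNParams, task: TaskConfig, n_trials: int = 100,
             horizon: int = 300, seed=None) -> dict:
    """Held-out performance of a trained network.

    Generates ``n_trials`` fresh sequences of length ``horizon``, rolls the
    network out, and reports the latent-state classification accuracy over
    all steps (percent), the mean absolute angular error at the final step
    (degrees, circular distance), and the two loss terms.
    """
    import dataclasses as _dc

    from .rnn import simulate

    trial = generate_trial(_dc.replace(task, seq_len=horizon), seed,
                           n_trials=n_trials)
    traj = simulate(params, trial)
    total, pos_mse, xent = composite_loss(traj.outputs, trial)
    acc = float(np.mean(traj.decoded_state == trial.target_state)) * 100.0
    err = circular_error(traj.decoded_angle[:, -1],
                         trial.true_angles[:, -1])
    return {
        "state_accuracy": acc,
        "angular_error_deg": float(np.degrees(np.mean(err))),
        "position_mse": pos_mse,
        "state_xent": xent,
        "total_loss": total,
    }
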