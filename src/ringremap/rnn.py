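"""Elman (vanilla) RNN: parameters, single-step update, readout, simulation.

The model is a discrete-time rate network with N hidden units,

    x_{t+1} = ReLU(A x_t + B u_t + beta),      y_t = C x_t + alpha,

with the initial condition produced by a linear encoder of the starting
angle, x_0 = D z + gamma (no rectification).  The readout y splits into a
position block — (cos, sin) predictions per spatial dimension, decoded with
atan2 — and K state logits decoded by argmax.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .task import TWO_PI, TaskConfig, TrialBatch

__all__ = [
    "RNNParams",
    "init_params",
    "step",
    "initial_state",
    "readout",
    "decode_angle",
    "decode_state",
    "position_readout_matrix",
    "simulate",
    "save_params",
    "load_params",
]


@dataclass
class RNNParams:
    """The seven trainable parameter groups {A, B, beta, C, alpha, D, gamma}.

    Shapes: A (N, N), B (N, M), beta (N,), C (L, N), alpha (L,),
    D (N, M0), gamma (N,), with M = K + d, L = K + 2d, M0 = 2d for K latent
    states and d spatial dimensions.
    """

    A: np.ndarray
    B: np.ndarray
    beta: np.ndarray
    C: np.ndarray
    alpha: np.ndarray
    D: np.ndarray
    gamma: np.ndarray
    n_states: int
    n_spatial_dims: int

    def __post_init__(self):
        N = self.A.shape[0]
        K, d = self.n_states, self.n_spatial_dims
        expected = {
            "A": (N, N),
            "B": (N, K + d),
            "beta": (N,),
            "C": (K + 2 * d, N),
            "alpha": (K + 2 * d,),
            "D": (N, 2 * d),
            "gamma": (N,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def n_units(self) -> int:
        return self.A.shape[0]

    def groups(self):
        """The parameter groups as an ordered (name, array) list."""
        return [(f.name, getattr(self, f.name))
                for f in dataclasses.fields(self)
                if f.name not in ("n_states", "n_spatial_dims")]

    def astype(self, dtype) -> "RNNParams":
        kw = {name: arr.astype(dtype) for name, arr in self.groups()}
        return RNNParams(n_states=self.n_states,
                         n_spatial_dims=self.n_spatial_dims, **kw)

    def copy(self) -> "RNNParams":
        return self.astype(self.A.dtype)


def init_params(n_units: int, n_states: int = 2, n_spatial_dims: int = 1,
                seed=None) -> RNNParams:
    """Random initialization of all parameter groups.

    The recurrent layer groups (A, B, beta) and readout (C, alpha) are drawn
    i.i.d. uniform on (-1/sqrt(N), 1/sqrt(N)); the initial-condition encoder
    (D, gamma) on (-1/sqrt(M0), 1/sqrt(M0)), its fan-in.
    """
    rng = np.random.default_rng(seed)
    N, K, d = n_units, n_states, n_spatial_dims
    M, L, M0 = K + d, K + 2 * d, 2 * d
    s_rec = 1.0 / np.sqrt(N)
    s_enc = 1.0 / np.sqrt(M0)

    def u(scale, *shape):
        return rng.uniform(-scale, scale, size=shape)

    return RNNParams(
        A=u(s_rec, N, N),
        B=u(s_rec, N, M),
        beta=u(s_rec, N),
        C=u(s_rec, L, N),
        alpha=u(s_rec, L),
        D=u(s_enc, N, M0),
        gamma=u(s_enc, N),
        n_states=K,
        n_spatial_dims=d,
    )


def step(params: RNNParams, x: np.ndarray, u: np.ndarray) -> np.ndarray:
    """One network update: ReLU(A x + B u + beta).

    ``x`` may be a single state (N,) or a batch (..., N); ``u`` likewise.
    """
    x = np.asarray(x)
    u = np.asarray(u)
    if x.shape[-1] != params.n_units or u.shape[-1] != params.B.shape[1]:
        raise ValueError("state or input dimension does not match parameters")
    pre = x @ params.A.T + u @ params.B.T + params.beta
    return np.maximum(pre, 0.0)


def initial_state(params: RNNParams, z: np.ndarray) -> np.ndarray:
    """Initial condition x_0 = D z + gamma (linear, not rectified)."""
    z = np.asarray(z)
    if z.shape[-1] != params.D.shape[1]:
        raise ValueError("init encoding length does not match parameters")
    return z @ params.D.T + params.gamma


def readout(params: RNNParams, x: np.ndarray) -> np.ndarray:
    """Linear readout y = C x + alpha."""
    return np.asarray(x) @ params.C.T + params.alpha


def position_readout_matrix(params: RNNParams) -> np.ndarray:
    """W: the (2d, N) block of C predicting (cos, sin) per spatial dim."""
    return params.C[: 2 * params.n_spatial_dims]


def decode_angle(y: np.ndarray, n_spatial_dims: int) -> np.ndarray:
    """Decode angles from the position block via atan2(sin, cos), in [0, 2*pi).

    Scale-invariant: any positive rescaling of a (cos, sin) pair decodes to
    the same angle.
    """
    y = np.asarray(y)
    cos_p = y[..., 0 : 2 * n_spatial_dims : 2]
    sin_p = y[..., 1 : 2 * n_spatial_dims : 2]
    return np.mod(np.arctan2(sin_p, cos_p), TWO_PI)


def decode_state(y: np.ndarray, n_spatial_dims: int) -> np.ndarray:
    """Decode the latent state as the argmax over the K state logits."""
    return np.argmax(np.asarray(y)[..., 2 * n_spatial_dims :], axis=-1)


@dataclass
class Trajectory:
    """Full rollout of the network on a trial batch.

    ``hidden`` holds x_0..x_T, shape (B, T+1, N); x_0 comes from the linear
    encoder and may contain negative entries, all later states are ReLU
    outputs.  Decoded quantities are aligned with outputs y_1..y_T (the
    readout after consuming inputs u_0..u_{T-1}).
    """

    hidden: np.ndarray
    outputs: np.ndarray
    decoded_angle: np.ndarray
    decoded_state: np.ndarray
    trial: TrialBatch


def simulate(params: RNNParams, trial: TrialBatch) -> Trajectory:
    """Deterministic rollout of the network on every sequence of a batch."""
    B, T, _ = trial.inputs.shape
    N = params.n_units
    hidden = np.empty((B, T + 1, N))
    x = initial_state(params, trial.init_encoding)
    hidden[:, 0] = x
    for t in range(T):
        x = step(params, x, trial.inputs[:, t])
        hidden[:, t + 1] = x
    outputs = readout(params, hidden[:, 1:])
    return Trajectory(
        hidden=hidden,
        outputs=outputs,
        decoded_angle=decode_angle(outputs, params.n_spatial_dims),
        decoded_state=decode_state(outputs, params.n_spatial_dims),
        trial=trial,
    )


def save_params(params: RNNParams, path, metadata: dict | None = None):
    """Checkpoint to HDF5 with one dataset per parameter group."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name, arr in params.groups():
            fh.create_dataset(name, data=arr)
        fh.attrs["n_states"] = params.n_states
        fh.attrs["n_spatial_dims"] = params.n_spatial_dims
        fh.attrs["n_units"] = params.n_units
        for key, val in (metadata or {}).items():
            fh.attrs[key] = val


def load_params(path) -> RNNParams:
    import h5py

    with h5py.File(path, "r") as fh:
        kw = {name: fh[name][()] for name in
              ("A", "B", "beta", "C", "alpha", "D", "gamma")}
        return RNNParams(n_states=int(fh.attrs["n_states"]),
                         n_spatial_dims=int(fh.attrs["n_spatial_dims"]), **kw)
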