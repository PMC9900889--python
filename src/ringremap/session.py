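"""Biological-session emulation: traversals, tuning curves, map detection.

A trained network is rolled out in session mode (nonnegative velocity from
angle 0, rare state changes at ~1/500 steps) and the resulting trajectory is
organized the way a circular-track recording session is: split into track
traversals, each traversal labeled by its predominant latent state ("map"),
with position-binned tuning curves per map, per-traversal population
vectors, trial-by-trial correlation matrices, k-means map detection, and a
spatial-stability filter.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .rnn import RNNParams, simulate
from .task import TWO_PI, TaskConfig, generate_trial

__all__ = [
    "SessionRecording",
    "TuningCurves",
    "TrialMatrix",
    "build_session",
    "compute_tuning_curves",
    "compute_tuning_curves_2d",
    "build_trial_matrix",
    "detect_maps_kmeans",
    "stability_filter",
]


@dataclass
class SessionRecording:
    """Trialized hidden-state trajectories with ground truth and map labels.

    All per-step arrays cover only steps belonging to complete traversals;
    ``traversal`` indexes them (0-based, global across the concatenated
    sequences) and ``traversal_labels[k]`` is the predominant latent state
    of traversal k.
    """

    hidden: np.ndarray          # (n_steps, N), ReLU outputs, >= 0
    true_angle: np.ndarray      # (n_steps,)
    true_state: np.ndarray      # (n_steps,)
    decoded_angle: np.ndarray   # (n_steps,)
    decoded_state: np.ndarray   # (n_steps,)
    traversal: np.ndarray       # (n_steps,) int
    traversal_labels: np.ndarray  # (n_traversals,) int

    @property
    def n_traversals(self) -> int:
        return len(self.traversal_labels)

    @property
    def map_ids(self) -> np.ndarray:
        return np.unique(self.traversal_labels)


@dataclass
class TuningCurves:
    """Per-map position-binned trial-averaged activity.

    ``curves[i]`` is the (P, N) manifold estimate for ``map_ids[i]``: the
    mean hidden activation over every step whose true angle falls in each
    of P equal bins of [0, 2*pi) (left-closed, right-open).
    """

    curves: np.ndarray       # (n_maps, P, N)
    map_ids: np.ndarray
    bin_edges: np.ndarray    # (P+1,)

    @property
    def n_bins(self) -> int:
        return self.curves.shape[1]

    def for_map(self, map_id) -> np.ndarray:
        return self.curves[int(np.flatnonzero(self.map_ids == map_id)[0])]


@dataclass
class TrialMatrix:
    """Per-traversal position-binned population vectors and correlations."""

    vectors: np.ndarray        # (n_traversals, P, N)
    labels: np.ndarray         # (n_traversals,)
    correlations: np.ndarray   # (n_traversals, n_traversals), Pearson

    @property
    def n_traversals(self) -> int:
        return self.vectors.shape[0]


def build_session(params: RNNParams, task: TaskConfig, seed=None,
                  n_sequences: int = 50,
                  cue_rate: float = 1.0 / 500.0) -> SessionRecording:
    """Roll the trained network out as a biological-session analogue.

    Generates ``n_sequences`` session-mode sequences (state changes at the
    rare session ``cue_rate``, velocity abs(mean + noise), initial angle 0),
    truncates each to complete track traversals, concatenates them, and
    labels every traversal with its most common true latent state.
    """
    if task.n_spatial_dims != 1:
        raise ValueError("sessions are defined for the 1D circular track")
    cfg = task.session_mode(cue_rate=cue_rate)
    trial = generate_trial(cfg, seed, n_trials=n_sequences)
    traj = simulate(params, trial)

    # unwrapped cumulative angle per sequence; traversal k spans
    # [2*pi*k, 2*pi*(k+1)).  Step t (1..T) carries angle th_t.
    dtheta = trial.inputs[:, :, 0]
    unwrapped = np.cumsum(dtheta, axis=1)  # angle after step t
    lap = np.floor(unwrapped / TWO_PI).astype(int)

    hidden, ang, st, dec_a, dec_s, trav = [], [], [], [], [], []
    labels = []
    offset = 0
    for b in range(n_sequences):
        n_laps = lap[b, -1]  # completed traversals in this sequence
        if n_laps < 1:
            continue
        keep = lap[b] < n_laps
        hidden.append(traj.hidden[b, 1:][keep])
        ang.append(trial.true_angles[b, 1:, 0][keep])
        st.append(trial.target_state[b][keep])
        dec_a.append(traj.decoded_angle[b, :, 0][keep])
        dec_s.append(traj.decoded_state[b][keep])
        trav.append(lap[b][keep] + offset)
        for k in range(n_laps):
            states_k = trial.target_state[b][lap[b] == k]
            labels.append(np.bincount(states_k).argmax())
        offset += n_laps

    if not labels:
        raise RuntimeError("session produced no complete traversals")
    return SessionRecording(
        hidden=np.concatenate(hidden),
        true_angle=np.concatenate(ang),
        true_state=np.concatenate(st),
        decoded_angle=np.concatenate(dec_a),
        decoded_state=np.concatenate(dec_s),
        traversal=np.concatenate(trav),
        traversal_labels=np.asarray(labels),
    )


def _bin_index(angles: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.floor(angles / TWO_PI * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def compute_tuning_curves(session: SessionRecording, n_bins: int = 50,
                          group_by: str = "state") -> TuningCurves:
    """Per-map position-binned mean activations.

    ``group_by='state'`` averages by the true latent state of each step;
    ``group_by='traversal_label'`` pools steps by the map label of their
    traversal (the session-style grouping).  Raises if any (map, bin) cell
    is empty.
    """
    if group_by == "state":
        step_map = session.true_state
    elif group_by == "traversal_label":
        step_map = session.traversal_labels[session.traversal]
    else:
        raise ValueError("group_by must be 'state' or 'traversal_label'")

    map_ids = np.unique(step_map)
    bins = _bin_index(session.true_angle, n_bins)
    N = session.hidden.shape[1]
    curves = np.empty((len(map_ids), n_bins, N))
    for i, m in enumerate(map_ids):
        sel = step_map == m
        counts = np.bincount(bins[sel], minlength=n_bins)
        if np.any(counts == 0):
            empty = np.flatnonzero(counts == 0)
            raise ValueError(
                f"map {m}: empty position bin(s) {empty.tolist()} "
                f"with n_bins={n_bins}; record a longer session")
        sums = np.zeros((n_bins, N))
        np.add.at(sums, bins[sel], session.hidden[sel])
        curves[i] = sums / counts[:, None]
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    return TuningCurves(curves=curves, map_ids=map_ids, bin_edges=edges)


def compute_tuning_curves_2d(params, task: TaskConfig, n_bins: int = 20,
                             n_trials: int = 100, seed=None) -> TuningCurves:
    """Toroidal tuning curves for a 2D model, binned on an n_bins x n_bins
    grid over both angles and flattened row-major to (n_bins**2, N).

    There is no traversal structure in 2D, so activity is pooled from
    training-regime rollouts; each latent state contributes one flattened
    torus manifold.  Raises if any (state, grid cell) is unvisited.
    """
    from .rnn import simulate

    if task.n_spatial_dims != 2:
        raise ValueError("compute_tuning_curves_2d requires a 2D task")
    trial = generate_trial(task, seed, n_trials=n_trials)
    traj = simulate(params, trial)
    hidden = traj.hidden[:, 1:].reshape(-1, params.n_units)
    ang = trial.true_angles[:, 1:].reshape(-1, 2)
    states = trial.target_state.reshape(-1)
    cell = (_bin_index(ang[:, 0], n_bins) * n_bins
            + _bin_index(ang[:, 1], n_bins))
    map_ids = np.unique(states)
    curves = np.empty((len(map_ids), n_bins * n_bins, params.n_units))
    for i, m in enumerate(map_ids):
        sel = states == m
        counts = np.bincount(cell[sel], minlength=n_bins * n_bins)
        if np.any(counts == 0):
            raise ValueError(
                f"state {m}: {int((counts == 0).sum())} unvisited torus "
                f"cells at n_bins={n_bins}; simulate more trials")
        sums = np.zeros((n_bins * n_bins, params.n_units))
        np.add.at(sums, cell[sel], hidden[sel])
        curves[i] = sums / counts[:, None]
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    return TuningCurves(curves=curves, map_ids=map_ids, bin_edges=edges)


def _interpolate_empty_bins(vec: np.ndarray, filled: np.ndarray) -> np.ndarray:
    """Fill empty position bins by circular linear interpolation per unit."""
    P, N = vec.shape
    if filled.all():
        return vec
    if not filled.any():
        raise ValueError("traversal visited no position bins")
    x = np.arange(P, dtype=float)
    xp = x[filled]
    out = vec.copy()
    for j in range(N):
        out[~filled, j] = np.interp(x[~filled], xp, vec[filled, j], period=P)
    return out


def build_trial_matrix(session: SessionRecording, n_bins: int = 80,
                       labels: np.ndarray | None = None) -> TrialMatrix:
    """Per-traversal position-binned population vectors and their Pearson
    correlation matrix.

    A single traversal rarely samples every one of the ``n_bins`` position
    bins; empty bins are filled by circular linear interpolation across
    bins, per unit, before correlating.
    """
    if labels is None:
        labels = session.traversal_labels
    n_trav = session.n_traversals
    bins = _bin_index(session.true_angle, n_bins)
    N = session.hidden.shape[1]
    vectors = np.empty((n_trav, n_bins, N))
    for k in range(n_trav):
        sel = session.traversal == k
        counts = np.bincount(bins[sel], minlength=n_bins)
        sums = np.zeros((n_bins, N))
        np.add.at(sums, bins[sel], session.hidden[sel])
        with np.errstate(invalid="ignore"):
            vec = sums / counts[:, None]
        vectors[k] = _interpolate_empty_bins(vec, counts > 0)
    flat = vectors.reshape(n_trav, -1)
    corr = np.corrcoef(flat)
    return TrialMatrix(vectors=vectors, labels=np.asarray(labels), correlations=corr)


def detect_maps_kmeans(trials: TrialMatrix, k: int, seed=None) -> np.ndarray:
    """k-means map detection on per-traversal population vectors.

    Each traversal vector (concatenated position-binned rates) is z-scored
    per unit across traversals; clustering uses Euclidean k-means with
    k-means++ initialization and 50 restarts.  Returns labels in {0..k-1}.
    """
    n = trials.n_traversals
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available traversals")
    X = trials.vectors.reshape(n, -1)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    seed = None if seed is None else int(np.random.default_rng(seed).integers(2**31))
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    return km.fit_predict(Xz)


def stability_filter(trials: TrialMatrix, labels: np.ndarray | None = None,
                     threshold: float = 0.25) -> np.ndarray:
    """Spatial-stability mask: keep a traversal iff its mean Pearson
    correlation with all other traversals of the same map is >= threshold.

    Maps with fewer than two traversals are kept trivially (with a warning).
    """
    if labels is None:
        labels = trials.labels
    labels = np.asarray(labels)
    corr = trials.correlations
    keep = np.ones(trials.n_traversals, dtype=bool)
    for m in np.unique(labels):
        idx = np.flatnonzero(labels == m)
        if len(idx) < 2:
            warnings.warn(f"map {m} has fewer than 2 traversals; kept trivially")
            continue
        sub = corr[np.ix_(idx, idx)]
        mean_off = (sub.sum(axis=1) - 1.0) / (len(idx) - 1)
        keep[idx] = mean_off >= threshold
    return keep
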