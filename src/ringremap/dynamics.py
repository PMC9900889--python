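"""Fixed-point analysis of the trained network at zero input.

Approximate fixed points x* with x* ~ ReLU(A x* + beta) are found by
minimizing the squared residual q(x) = ||x - ReLU(A x + beta)||^2 from many
initial states sampled off recorded trajectories (gradient descent with a
per-point adaptive backtracking step).  Each retained point is linearized:
the Jacobian of the update map at x* is diag(g) A with g the ReLU activity
pattern, and its spectrum classifies the point as marginally stable
(|lambda|_max ~ 1, the slow ring directions) or unstable (|lambda|_max > 1,
the saddles that route activity between ring attractors during remapping).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rnn import RNNParams

__all__ = [
    "FixedPointRecord",
    "sample_initial_states",
    "find_fixed_points",
    "jacobian_at",
    "classify_fixed_point",
    "remap_projection",
]

MARGINALLY_STABLE = "marginally-stable"
UNSTABLE = "unstable"
DISCARDED = "discarded"


@dataclass
class FixedPointRecord:
    """One converged fixed point with its local linearization."""

    x: np.ndarray                  # (N,) state vector
    residual: float                # ||x - ReLU(Ax + beta)||^2
    eigenvalues: np.ndarray = None       # complex spectrum of the Jacobian
    principal_eigenvector: np.ndarray = None  # eigvec of max-|lambda| eigenvalue
    label: str = DISCARDED
    init_index: int = -1           # which initialization produced it
    remap_coordinate: float = field(default=np.nan)

    @property
    def max_abs_eigenvalue(self) -> float:
        return float(np.max(np.abs(self.eigenvalues)))


def sample_initial_states(hidden: np.ndarray, n_init: int = 1024,
                          noise_frac: float = 0.1, seed=None) -> np.ndarray:
    """Initialization pool: states sampled from a rollout, half perturbed.

    Draws ``n_init`` states uniformly from the rows of ``hidden``; every
    second one is perturbed with isotropic Gaussian noise of SD equal to
    ``noise_frac`` times the mean state norm, to probe off-manifold basins.
    """
    rng = np.random.default_rng(seed)
    H = np.asarray(hidden, dtype=float).reshape(-1, hidden.shape[-1])
    idx = rng.integers(H.shape[0], size=n_init)
    X = H[idx].copy()
    sd = noise_frac * float(np.mean(np.linalg.norm(H, axis=1)))
    perturb = np.arange(n_init) % 2 == 1
    X[perturb] += rng.normal(0.0, sd, size=(perturb.sum(), H.shape[1]))
    return X


def _residual_and_grad(A, beta, X):
    pre = X @ A.T + beta
    g = pre > 0
    r = X - np.where(g, pre, 0.0)
    q = np.sum(r * r, axis=1)
    grad = 2.0 * (r - (g * r) @ A)
    return q, grad


def find_fixed_points(params: RNNParams, init_states: np.ndarray,
                      tol: float = 1e-8, merge_radius: float = 0.01,
                      max_iter: int = 10000) -> list[FixedPointRecord]:
    """Locate approximate fixed points of the zero-input dynamics.

    Minimizes q(x) = ||x - ReLU(Ax + beta)||^2 from every row of
    ``init_states`` by gradient descent with per-point adaptive step sizes
    (grow on improvement, backtrack otherwise).  Minima with q < ``tol``
    are retained and deduplicated: points closer than ``merge_radius``
    (Euclidean) keep only the lowest-residual representative.  Deterministic
    given the initial states.
    """
    A = params.A
    beta = params.beta
    X = np.asarray(init_states, dtype=float).copy()
    n = X.shape[0]
    step = np.full(n, 0.1)
    q, grad = _residual_and_grad(A, beta, X)
    active = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        ia = np.flatnonzero(active)
        cand = X[ia] - step[ia, None] * grad[ia]
        q_new, g_new = _residual_and_grad(A, beta, cand)
        better = q_new <= q[ia]
        ib = ia[better]
        X[ib] = cand[better]
        q[ib] = q_new[better]
        grad[ib] = g_new[better]
        step[ib] *= 1.1
        step[ia[~better]] *= 0.5
        # a point is done when converged or its step has collapsed
        done = (q[ia] < tol * 0.01) | (step[ia] < 1e-16)
        active[ia[done]] = False

    keep = np.flatnonzero(q < tol)
    if keep.size == 0:
        warnings.warn("no initialization converged below tol; empty result")
        return []
    order = keep[np.argsort(q[keep])]
    records: list[FixedPointRecord] = []
    kept_states = []
    for i in order:
        if kept_states:
            d = np.linalg.norm(np.asarray(kept_states) - X[i], axis=1)
            if d.min() < merge_radius:
                continue
        kept_states.append(X[i])
        records.append(FixedPointRecord(x=X[i], residual=float(q[i]),
                                        init_index=int(i)))
    return records


def jacobian_at(params: RNNParams, x_star: np.ndarray) -> np.ndarray:
    """Jacobian of the update map at x*, input held at zero: diag(g) A.

    g_i = 1 where the pre-activation (A x* + beta)_i is positive, else 0
    (subgradient 0 at an exact kink, which is flagged with a warning since
    the derivative is undefined there).
    """
    pre = params.A @ np.asarray(x_star, dtype=float) + params.beta
    if np.any(pre == 0.0):
        warnings.warn("pre-activation exactly at the ReLU kink; "
                      "using subgradient 0")
    g = pre > 0
    return params.A * g[:, None]


def classify_fixed_point(record: FixedPointRecord, params: RNNParams,
                         marginality_band: float = 0.05) -> FixedPointRecord:
    """Attach the Jacobian spectrum and a stability label to a fixed point.

    Marginally stable iff max |lambda| lies in [1 - band, 1 + band];
    unstable iff above the band; otherwise discarded (contracting points
    are not part of the ring/saddle picture).
    """
    J = jacobian_at(params, record.x)
    vals, vecs = np.linalg.eig(J)
    k = int(np.argmax(np.abs(vals)))
    record.eigenvalues = vals
    record.principal_eigenvector = vecs[:, k]
    lam = np.abs(vals[k])
    if 1.0 - marginality_band <= lam <= 1.0 + marginality_band:
        record.label = MARGINALLY_STABLE
    elif lam > 1.0 + marginality_band:
        record.label = UNSTABLE
    else:
        record.label = DISCARDED
    return record


def remap_projection(x_star: np.ndarray, centroid_1: np.ndarray,
                     centroid_2: np.ndarray) -> float:
    """Signed coordinate of x* along the centroid-difference direction.

    Scaled so the map-1 centroid maps to -1, the map-2 centroid to +1, and
    the midpoint between the manifolds to 0; components orthogonal to the
    remapping dimension do not contribute.
    """
    c1 = np.asarray(centroid_1, dtype=float)
    c2 = np.asarray(centroid_2, dtype=float)
    diff = c2 - c1
    half = np.linalg.norm(diff) / 2.0
    if half == 0:
        raise ValueError("identical centroids")
    mid = (c1 + c2) / 2.0
    u = diff / np.linalg.norm(diff)
    return float((np.asarray(x_star, dtype=float) - mid) @ u / half)
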