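"""Population-geometry statistics of remapping.

Given per-map manifold estimates (position-binned tuning-curve matrices),
this module quantifies:

* dimensionality — cumulative PCA variance spectra;
* alignment — Procrustes misalignment of two manifolds, scored against an
  optimal rotation (score 0) and a random-rotation null (score 1 at the
  null's reference percentile);
* the position subspace (top-2 PCs of position-binned activity across maps)
  and the remapping dimension (unit centroid difference between maps);
* the remapping vectors xi_p = x_p^(2) - x_p^(1), their mean v, the
  nullspace identity W xi_p ~ 0 imposed by the shared linear position
  readout W, and a rotation control confined to the nullspace of W that
  scrambles ring alignment without touching decoded position;
* weight/eigenvector-to-subspace cosine similarities and pairwise acute
  angles between remapping dimensions for K >= 3 maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space, svd

__all__ = [
    "Manifold",
    "AlignmentResult",
    "RemapVectors",
    "preprocess_manifold",
    "pca_variance_spectrum",
    "procrustes_misalignment",
    "position_subspace",
    "remapping_dimension",
    "remap_vector_analysis",
    "nullspace_rotation_control",
    "subspace_cosine",
    "pairwise_remap_angles",
    "random_rotation",
]


@dataclass
class Manifold:
    """A preprocessed (P, N) manifold: column means 0, Frobenius norm 1."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("manifold must be a (P, N) matrix")


def preprocess_manifold(curves: np.ndarray) -> Manifold:
    """Mean-center each unit (column) and rescale to unit Frobenius norm."""
    X = np.asarray(curves, dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(X)
    if norm == 0:
        raise ValueError("degenerate manifold: zero variance")
    return Manifold(X / norm)


@dataclass
class AlignmentResult:
    """Procrustes alignment of two manifolds against a rotation null."""

    observed_rmse: float
    optimal_rmse: float
    null_rmse: np.ndarray
    score: float
    rotation: np.ndarray  # the optimal rotation (N, N), det +1


@dataclass
class RemapVectors:
    """The remapping vectors between two maps and their structure."""

    xi: np.ndarray                 # (P, N) per-bin remapping vectors
    v: np.ndarray                  # (N,) mean remapping vector
    readout_residuals: np.ndarray  # (P,) ||W xi_p||
    normalized_residuals: np.ndarray  # (P,) ||xi_p - v|| / mean_p ||xi_p||
    explained_variance_ratio: np.ndarray  # PCA spectrum of the xi matrix
    covariance: np.ndarray         # (P, P) covariance of xi across bins


def pca_variance_spectrum(activity: np.ndarray) -> np.ndarray:
    """Cumulative fraction of variance explained by successive PCs.

    ``activity`` is samples x units (time steps or stacked tuning-curve
    bins).  Nondecreasing, ends at 1; rank-deficient data contribute
    trailing zeros to the per-component spectrum.
    """
    X = np.asarray(activity, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = X - X.mean(axis=0, keepdims=True)
    s = svd(X, compute_uv=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("zero-variance activity")
    return np.cumsum(var) / total


def random_rotation(n: int, rng) -> np.ndarray:
    """A rotation matrix drawn from the Haar measure on SO(n)."""
    M = rng.standard_normal((n, n))
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _best_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||src R - dst||_F."""
    U, _, Vt = svd(src.T @ dst)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] = -U[:, -1]
        R = U @ Vt
    return R


def procrustes_misalignment(m1, m2, n_null: int = 1000, seed=None,
                            null_percentile: float = 25.0) -> AlignmentResult:
    """Shape alignment of two bin-matched manifolds.

    Both inputs (raw (P, N) tuning-curve matrices or already-preprocessed
    :class:`Manifold` objects) are mean-centered and unit-normalized.  The
    score normalizes the observed RMSE between the anchors
    ``score = (obs - opt) / (null_ref - opt)`` where ``opt`` is the RMSE
    after the optimal rotation of m2 onto m1 and ``null_ref`` is the given
    percentile (default 25th) of RMSEs under random rotations of m2 —
    score 0 means perfectly aligned, score 1 matches the null reference.
    """
    A = (m1 if isinstance(m1, Manifold) else preprocess_manifold(m1)).points
    B = (m2 if isinstance(m2, Manifold) else preprocess_manifold(m2)).points
    if A.shape != B.shape:
        raise ValueError("manifolds must be bin- and unit-matched")
    observed = _rmse(A, B)
    R = _best_rotation(B, A)
    optimal = _rmse(B @ R, A)
    rng = np.random.default_rng(seed)
    n = A.shape[1]
    null = np.array([_rmse(B @ random_rotation(n, rng), A)
                     for _ in range(n_null)])
    ref = float(np.percentile(null, null_percentile))
    denom = ref - optimal
    score = 0.0 if denom <= 0 else (observed - optimal) / denom
    return AlignmentResult(observed_rmse=observed, optimal_rmse=optimal,
                           null_rmse=null, score=float(score), rotation=R)


def position_subspace(curves: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Top principal axes of position-binned activity.

    ``curves`` stacks the (P, N) tuning-curve matrices of the maps being
    considered (a single map's matrix is equally valid input — the per-map
    subspace).  ``n_components`` is 2 for a ring (1D track) and 4 for a
    torus (2D arena).  Returns an (N, n_components) orthonormal basis.
    """
    X = np.asarray(curves, dtype=float)
    if X.ndim == 3:
        X = X.reshape(-1, X.shape[-1])
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = svd(X, full_matrices=False)
    if (s > 1e-12).sum() < n_components:
        raise ValueError(f"activity has rank < {n_components}")
    return Vt[:n_components].T


def remapping_dimension(curves_i: np.ndarray, curves_j: np.ndarray) -> np.ndarray:
    """Unit vector along the difference of the two maps' mean activations."""
    ci = np.asarray(curves_i, dtype=float).mean(axis=0)
    cj = np.asarray(curves_j, dtype=float).mean(axis=0)
    diff = cj - ci
    norm = np.linalg.norm(diff)
    if norm == 0:
        raise ValueError("identical map centroids: remapping dimension undefined")
    return diff / norm


def remap_vector_analysis(curves_1: np.ndarray, curves_2: np.ndarray,
                          W: np.ndarray) -> RemapVectors:
    """Structure of the remapping vectors xi_p = x_p^(2) - x_p^(1).

    Uses the raw (unpreprocessed) bin-matched tuning curves so that the
    linear-decoder identity W xi_p = W x_p^(2) - W x_p^(1) holds exactly.
    Reports per-bin readout residuals ||W xi_p||, the mean vector v, the
    per-bin normalized deviations ||xi_p - v|| / mean_p ||xi_p||, the PCA
    spectrum of the (P, N) xi matrix, and the (P, P) bin-by-bin covariance
    of the centered xi (smooth variation over position shows up as a
    diagonal band).
    """
    x1 = np.asarray(curves_1, dtype=float)
    x2 = np.asarray(curves_2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("manifolds must be bin- and unit-matched")
    xi = x2 - x1
    v = xi.mean(axis=0)
    centered = xi - v
    res = np.linalg.norm(centered, axis=1)
    scale = np.mean(np.linalg.norm(xi, axis=1))
    norm_res = res / scale if scale > 0 else res
    # spectrum of the raw (uncentered) xi matrix: a pure translation
    # (xi_p = v for all p) is exactly rank 1 with first axis v
    s = svd(xi, compute_uv=False)
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    cov = centered @ centered.T / xi.shape[1]
    return RemapVectors(
        xi=xi, v=v,
        readout_residuals=np.linalg.norm(xi @ np.asarray(W).T, axis=1),
        normalized_residuals=norm_res,
        explained_variance_ratio=evr,
        covariance=cov,
    )


def nullspace_rotation_control(curves_2: np.ndarray, W: np.ndarray,
                               seed=None) -> np.ndarray:
    """Rotate map 2 within the nullspace of the position readout W.

    The deviations of the manifold from its centroid are decomposed into a
    row-space component (visible to W) and a nullspace component; a random
    rotation is applied to the latter only.  Decoded position W x_p is
    preserved exactly for every bin while the ring's orientation relative
    to map 1 is scrambled — the chance benchmark for ring alignment.
    """
    X = np.asarray(curves_2, dtype=float)
    W = np.asarray(W, dtype=float)
    Q = null_space(W)  # (N, N - rank(W)), orthonormal
    if Q.shape[1] == 0:
        raise ValueError("W has no nullspace")
    rng = np.random.default_rng(seed)
    R = random_rotation(Q.shape[1], rng)
    c = X.mean(axis=0)
    dev = X - c
    y = dev @ Q                       # nullspace coordinates
    return c + (dev - y @ Q.T) + (y @ R.T) @ Q.T


def subspace_cosine(vec: np.ndarray, basis: np.ndarray) -> float:
    """Cosine similarity between a vector and a subspace, in [0, 1].

    ``basis`` is an (N, k) orthonormal basis (a 1-D array is treated as a
    single direction).  1 means the vector lies in the subspace, 0 means it
    is orthogonal to it.  Complex vectors are handled via the Hermitian
    inner product (useful for principal eigenvectors of nonsymmetric
    Jacobians).
    """
    v = np.asarray(vec)
    Bs = np.asarray(basis)
    if Bs.ndim == 1:
        Bs = Bs[:, None]
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero vector has no direction")
    proj = np.conjugate(Bs.T) @ v
    return float(np.linalg.norm(proj) / norm)


def pairwise_remap_angles(curves: np.ndarray) -> dict:
    """Acute angles (degrees) between remapping dimensions of all map pairs.

    ``curves`` is (n_maps, P, N) with n_maps >= 3 (K maps of one session);
    the angle for pair (i, j) vs (i, l) is arccos of the absolute cosine
    similarity between the unit centroid-difference vectors of each pair.
    Returns a dict keyed by ((i, j), (i2, j2)) map-pair index tuples.
    """
    curves = np.asarray(curves)
    n_maps = curves.shape[0]
    if n_maps < 3:
        raise ValueError("need at least 3 maps for pairwise remap angles")
    pairs = [(i, j) for i in range(n_maps) for j in range(i + 1, n_maps)]
    dims = {p: remapping_dimension(curves[p[0]], curves[p[1]]) for p in pairs}
    out = {}
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            cos = abs(float(dims[pairs[a]] @ dims[pairs[b]]))
            out[(pairs[a], pairs[b])] = float(
                np.degrees(np.arccos(np.clip(cos, 0.0, 1.0))))
    return out
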