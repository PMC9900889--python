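"""Single-unit remapping characterization.

Each unit's pair of smoothed spatial tuning curves (one per map) is scored
along two axes: rate remapping — the percent change in peak activation —
and global remapping — a spatial dissimilarity score, one minus the cosine
similarity of the two curves (0 identical spatial firing, 1 orthogonal).
Real and model populations are heterogeneous in this plane: some units
mostly rescale their fields, others relocate them.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "smooth_curves",
    "rate_remapping_score",
    "spatial_dissimilarity",
    "unit_remap_scores",
]


def smooth_curves(curves: np.ndarray, sd_bins: float = 2.0) -> np.ndarray:
    """Circular Gaussian smoothing along the position-bin axis.

    ``curves`` is (P, N) (bins x units) or (n_maps, P, N); the filter wraps
    around the track boundary and preserves each unit's total mass.
    """
    curves = np.asarray(curves, dtype=float)
    axis = curves.ndim - 2
    if curves.shape[axis] < 5:
        raise ValueError("need at least 5 position bins to smooth")
    return gaussian_filter1d(curves, sd_bins, axis=axis, mode="wrap")


def rate_remapping_score(c1: np.ndarray, c2: np.ndarray) -> float:
    """Percent change in peak activation between maps, |pk2 - pk1|/pk1 * 100.

    The map-1 curve is the reference; a zero reference peak leaves the
    score undefined (NaN) and the unit should be flagged by the caller.
    """
    p1 = float(np.max(c1))
    p2 = float(np.max(c2))
    if p1 <= 0:
        return float("nan")
    return abs(p2 - p1) / p1 * 100.0


def spatial_dissimilarity(c1: np.ndarray, c2: np.ndarray) -> float:
    """1 - cosine similarity of the two binned curves (0 same, 1 orthogonal).

    Invariant to positive rescaling of either curve; NaN if either curve
    is identically zero.
    """
    n1 = np.linalg.norm(c1)
    n2 = np.linalg.norm(c2)
    if n1 == 0 or n2 == 0:
        return float("nan")
    return float(1.0 - np.dot(c1, c2) / (n1 * n2))


def unit_remap_scores(curves_1: np.ndarray, curves_2: np.ndarray,
                      sd_bins: float = 2.0):
    """Per-unit (rate score, dissimilarity) for a pair of (P, N) maps.

    Curves are smoothed circularly (SD ``sd_bins`` bins) before scoring.
    Returns a DataFrame with one row per unit; units with an undefined
    score carry NaN and are flagged in the ``flagged`` column.
    """
    import pandas as pd

    s1 = smooth_curves(np.asarray(curves_1, dtype=float), sd_bins)
    s2 = smooth_curves(np.asarray(curves_2, dtype=float), sd_bins)
    n_units = s1.shape[1]
    rate = np.array([rate_remapping_score(s1[:, j], s2[:, j])
                     for j in range(n_units)])
    dis = np.array([spatial_dissimilarity(s1[:, j], s2[:, j])
                    for j in range(n_units)])
    return pd.DataFrame({
        "unit": np.arange(n_units),
        "rate_remapping_pct": rate,
        "spatial_dissimilarity": dis,
        "flagged": ~(np.isfinite(rate) & np.isfinite(dis)),
    })
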