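"""Principal coordinates analysis (classical/metric MDS) of a distance matrix.

Gower double centering of the element-wise squared distances,

    B = -1/2 * J D^(2) J,   J = I - 11'/n,

followed by an eigendecomposition of B. Sample coordinates on axis k are
eigenvector_k * sqrt(eigenvalue_k), taken over the largest positive
eigenvalues. Negative eigenvalues (non-Euclidean distances) are dropped
rather than corrected; proportion explained uses the sum of positive
eigenvalues as denominator. Each retained axis is sign-flipped so its
largest-magnitude coordinate is positive, making output files
reproducible across LAPACK builds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .io import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["Ordination", "pcoa"]

# eigenvalues below this (relative to the largest) are numerical zeros
_EIG_RTOL = 1e-10


@dataclass
class Ordination:
    """PCoA embedding: samples x axes scores plus eigenvalue spectrum."""

    sample_ids: list[str]
    coordinates: np.ndarray          # samples x axes
    eigenvalues: np.ndarray          # retained (positive) eigenvalues, descending
    proportion_explained: np.ndarray
    truncated: bool = False          # fewer positive axes than requested

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCoA{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(distance_matrix: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Embed ``distance_matrix`` into ``n_axes`` principal coordinates.

    If fewer positive eigenvalues than ``n_axes`` exist, all available
    axes are returned and the result is flagged ``truncated`` with a
    warning.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d = distance_matrix.values
    n = d.shape[0]
    d2 = d * d
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = scipy.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = _EIG_RTOL * max(abs(eigvals[0]), 1.0) if n else 0.0
    positive = eigvals > tol
    n_pos = int(positive.sum())
    k = min(n_axes, n_pos)
    truncated = k < n_axes
    if truncated:
        logger.warning("pcoa: only %d positive eigenvalue(s); requested %d axes",
                       n_pos, n_axes)
    vals = eigvals[:k]
    coords = eigvecs[:, :k] * np.sqrt(vals)
    # deterministic sign: largest-|.| coordinate positive per axis
    for a in range(k):
        col = coords[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    pos_sum = eigvals[positive].sum()
    prop = vals / pos_sum if pos_sum > 0 else np.zeros(k)
    return Ordination(
        sample_ids=list(distance_matrix.ids),
        coordinates=coords,
        eigenvalues=vals,
        proportion_explained=prop,
        truncated=truncated,
    )
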