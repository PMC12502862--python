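"""Singular value decomposition of the scattering matrix F.

A rapidly decaying singular spectrum means the family of 2D maps lives on a
low-dimensional manifold, so a smooth inverse map to the energy parameters is
plausible; projecting rows onto the first few right singular vectors
(FV0, FV1, FV2) gives a compact coordinate system in which the inversion
targets should vary smoothly. F is decomposed directly, without mean
centering, so the squared singular values are proportional to the (uncentered)
variance captured per axis; a centering flag exists for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SVDResult", "decompose", "project", "spectrum_report"]


@dataclass
class SVDResult:
    """Thin (economy) SVD of a data matrix.

    ``right_vectors`` holds V with singular vectors as columns
    (n_features × rank); ``left_vectors`` holds U (n_samples × rank). Each
    right vector's largest-magnitude entry is made positive so projections are
    reproducible across linear-algebra backends.
    """

    singular_values: np.ndarray
    right_vectors: np.ndarray
    left_vectors: np.ndarray
    centered: bool = False
    mean: np.ndarray | None = None

    @property
    def rank(self) -> int:
        return self.singular_values.size


def decompose(F: np.ndarray, center: bool = False) -> SVDResult:
    """Thin SVD ``F = U Σ Vᵀ`` with deterministic sign convention.

    Raises on non-finite entries. Reconstruction holds to 1e-8 relative and
    singular values come out non-increasing (checked in tests, not here).
    """
    F = np.asarray(F, dtype=float)
    if F.size == 0:
        raise ValueError("empty matrix")
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite entries in F")
    mean = None
    if center:
        mean = F.mean(axis=0)
        F = F - mean
    u, s, vt = np.linalg.svd(F, full_matrices=False)
    # sign fix: largest-|entry| of each right vector positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    return SVDResult(s, vt.T, u, centered=center, mean=mean)


def project(F: np.ndarray, svd: SVDResult, k: int) -> np.ndarray:
    """Coordinates F·V_j of each row on the first ``k`` right singular vectors."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > svd.rank:
        raise ValueError(f"k={k} exceeds rank {svd.rank}")
    F = np.asarray(F, dtype=float)
    if svd.centered and svd.mean is not None:
        F = F - svd.mean
    return F @ svd.right_vectors[:, :k]


def spectrum_report(svd: SVDResult, top_k: int) -> pd.DataFrame:
    """Table of (rank, value, cumulative variance fraction) for the top ranks.

    Cumulative fractions use squared singular values, whose entries are
    proportional to the variance of the data projected on each axis.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    s = svd.singular_values
    var = s**2
    cum = np.cumsum(var) / var.sum()
    k = min(top_k, s.size)
    return pd.DataFrame(
        {
            "rank": np.arange(k),
            "singular_value": s[:k],
            "cumulative_variance_fraction": cum[:k],
        }
    )
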