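"""PCA pathway for data above the critical dimension.

Direct histogramming becomes impractical above ~5 dimensions: run time, the
number of events needed for an adequate histogram and the memory for the grid
all grow super-linearly with dimension.  Higher-dimensional data is therefore
projected onto the subspace spanned by the eigenvectors of the data covariance
matrix belonging to the largest eigenvalues (5 by default), clustered there,
and each cluster's member events are carried back to their original positions;
cluster centers are reported in the original data space.

The projection can fold otherwise-separated density peaks onto each other, in
which case fewer clusters than populations are found; the fraction of variance
retained by the kept eigenvalues is exposed as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binning import CRITICAL_DIM, as_events
from .sweep import ClusterResult, cluster

__all__ = ["ProjectionBasis", "pca_basis", "cluster_high_dimensional"]


@dataclass(frozen=True)
class ProjectionBasis:
    """Orthonormal principal axes of the data covariance (strongest first)."""

    mean: np.ndarray
    axes: np.ndarray         # (target_dim, D), rows orthonormal
    eigenvalues: np.ndarray  # (target_dim,), non-increasing
    total_variance: float

    @property
    def variance_retained(self) -> float:
        """Fraction of total variance captured by the kept axes."""
        if self.total_variance == 0:
            return 1.0
        return float(self.eigenvalues.sum() / self.total_variance)

    def project(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, dtype=float) - self.mean) @ self.axes.T


def pca_basis(data, target_dim: int = CRITICAL_DIM) -> ProjectionBasis:
    """Top eigenvectors of the covariance matrix of the (centered) data.

    Eigenvector signs follow the convention that each axis's largest-magnitude
    component is positive, for reproducibility.  Rank-deficient data with fewer
    than ``target_dim`` positive eigenvalues triggers a warning; the surplus
    zero-variance axes are kept (eigh returns a deterministic orthonormal
    completion).
    """
    data = as_events(data)
    n, ndim = data.shape
    if ndim <= target_dim:
        raise ValueError(
            f"data dimension {ndim} does not exceed the target dimension {target_dim}"
        )
    if n <= ndim:
        raise ValueError(f"need more events ({n}) than dimensions ({ndim})")
    mean = data.mean(axis=0)
    cov = np.cov(data, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:target_dim]
    evals = np.clip(evals[order], 0.0, None)
    axes = evecs[:, order].T
    if np.sum(evals > 0) < target_dim:
        warnings.warn(
            "fewer positive-variance directions than the target dimension; "
            "zero-variance axes retained"
        )
    for i in range(axes.shape[0]):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    total = float(np.clip(np.linalg.eigvalsh(cov), 0.0, None).sum())
    return ProjectionBasis(mean=mean, axes=axes, eigenvalues=evals, total_variance=total)


def cluster_high_dimensional(
    data, critical_dim: int = CRITICAL_DIM, **options
) -> list[ClusterResult]:
    """Cluster data of any dimension, projecting above ``critical_dim``.

    At or below the critical dimension this is identical to
    :func:`densitygate.sweep.cluster`.  Above it, the data is projected onto
    its top ``critical_dim`` principal axes, clustered in the subspace, and
    memberships are mapped back: member row indices refer to the input rows
    and centers are per-coordinate means of the members in the original space.
    """
    data = as_events(data)
    if data.shape[1] <= critical_dim:
        return cluster(data, critical_dim=critical_dim, **options)
    basis = pca_basis(data, target_dim=critical_dim)
    projected = basis.project(data)
    results = cluster(projected, critical_dim=critical_dim, **options)
    for r in results:
        r.center = data[r.members].mean(axis=0) if len(r.members) else np.full(
            data.shape[1], np.nan
        )
    return results
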