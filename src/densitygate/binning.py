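"""Optimal equal-per-axis histogram binning.

The bin number shared by all axes is chosen by maximizing Knuth's Bayesian
log-posterior for equal-width histograms,

    log p(N | d) = n log N^D + log Gamma(N^D / 2) - N^D log Gamma(1/2)
                   - log Gamma(n + N^D / 2) + sum_k log Gamma(n_k + 1/2) + const,

where ``n`` is the number of events, ``D`` the dimension of the data space and
``n_k`` the content of the k-th of the N^D bins.  Empty bins contribute
``log Gamma(1/2)`` each, which cancels against the third term, so the posterior
is evaluated from the occupied bins only and scales to sparse high-dimensional
grids.

Bins are upper-edge inclusive: along each axis the range [min, max] is split
into N equal widths and a value x falls in bin ``ceil((x - lo) / w) - 1``
(clipped), so the column minimum sits in bin 0 and the maximum in bin N - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GridSpec",
    "HistogramGrid",
    "as_events",
    "build_histogram",
    "log_binning_posterior",
    "optimal_bin_number",
    "DENSE_BIN_BUDGET",
    "MAX_TOTAL_BINS",
    "CRITICAL_DIM",
]

# Dense count arrays are materialized only up to this many cells; larger grids
# stay sparse (occupied bins + counts).
DENSE_BIN_BUDGET = 20_000_000
# Hard capacity: N^D above this cannot be addressed with 64-bit flat indices.
MAX_TOTAL_BINS = 2**62
# Dimension above which direct histogramming is refused and the PCA pathway
# (densitygate.highdim) should be used instead.
CRITICAL_DIM = 5


class CapacityError(ValueError):
    """Requested grid exceeds the addressable bin budget."""


def as_events(data) -> np.ndarray:
    """Validate and coerce an event table to a float (n, D) array.

    Accepts anything ``np.asarray`` handles (lists, DataFrames, 1-D vectors,
    which become a single channel).  Raises ``ValueError`` on non-finite
    entries or empty input.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError(f"event table must be 2-dimensional, got shape {x.shape}")
    if x.shape[0] < 1 or x.shape[1] < 1:
        raise ValueError(f"event table must be non-empty, got shape {x.shape}")
    if not np.isfinite(x).all():
        bad = np.argwhere(~np.isfinite(x))[0]
        raise ValueError(f"non-finite value at row {bad[0]}, column {bad[1]}")
    return x


@dataclass(frozen=True)
class GridSpec:
    """Equal-per-axis grid: N bins per axis between per-axis lo/hi edges."""

    N: int
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        if np.any(hi < lo):
            raise ValueError("hi must be >= lo on every axis")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def ndim(self) -> int:
        return self.lo.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.N,) * self.ndim


@dataclass
class HistogramGrid:
    """Sparse D-dimensional count grid plus the per-event bin assignment.

    ``occupied`` holds the flat (C-order) indices of nonzero bins in ascending
    order, ``occ_counts`` their contents; ``event_bins`` maps each source event
    to its flat bin.  ``level_max`` is the highest bin content.
    """

    spec: GridSpec
    occupied: np.ndarray
    occ_counts: np.ndarray
    event_bins: np.ndarray
    total: int
    level_max: int
    _count_lookup: dict = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.spec.shape

    @property
    def ndim(self) -> int:
        return self.spec.ndim

    @property
    def nbins(self) -> int:
        return self.spec.N ** self.spec.ndim

    def counts_dense(self) -> np.ndarray:
        """Materialize the full count array (small grids only)."""
        if self.nbins > DENSE_BIN_BUDGET:
            raise CapacityError(
                f"grid of {self.nbins} cells exceeds the dense budget"
            )
        out = np.zeros(self.nbins, dtype=np.int64)
        out[self.occupied] = self.occ_counts
        return out.reshape(self.shape)

    def count_at(self, idx) -> int:
        """Bin content at a multi-index (zero for unoccupied bins)."""
        idx = tuple(int(i) for i in np.atleast_1d(idx))
        if len(idx) != self.ndim:
            raise IndexError(f"expected {self.ndim} indices, got {len(idx)}")
        for i in idx:
            if not 0 <= i < self.spec.N:
                raise IndexError(f"bin {idx} outside {self.shape} grid")
        flat = int(np.ravel_multi_index(idx, self.shape))
        if self._count_lookup is None:
            self._count_lookup = dict(
                zip(self.occupied.tolist(), self.occ_counts.tolist())
            )
        return self._count_lookup.get(flat, 0)


def _grid_spec(data: np.ndarray, N: int) -> GridSpec:
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    if np.any(hi == lo) and N > 1:
        warnings.warn(
            "constant column(s): degenerate axis binned into a single bin",
            stacklevel=3,
        )
    return GridSpec(N=N, lo=lo, hi=hi)


def _bin_indices(data: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Flat C-order bin index per event under the upper-edge-inclusive rule."""
    n, ndim = data.shape
    N = spec.N
    flat = np.zeros(n, dtype=np.int64)
    for k in range(ndim):
        width = spec.hi[k] - spec.lo[k]
        if width == 0.0:
            axis_idx = np.zeros(n, dtype=np.int64)
        else:
            z = (data[:, k] - spec.lo[k]) / width
            axis_idx = np.ceil(z * N).astype(np.int64) - 1
            np.clip(axis_idx, 0, N - 1, out=axis_idx)
        flat = flat * N + axis_idx
    return flat


def build_histogram(data, N: int) -> HistogramGrid:
    """Bin events on an N-per-axis equal-width grid spanning each column's range."""
    data = as_events(data)
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if N ** data.shape[1] > MAX_TOTAL_BINS:
        raise CapacityError(
            f"N={N} in {data.shape[1]}D exceeds the addressable bin budget"
        )
    spec = _grid_spec(data, N)
    flat = _bin_indices(data, spec)
    occupied, occ_counts = np.unique(flat, return_counts=True)
    return HistogramGrid(
        spec=spec,
        occupied=occupied,
        occ_counts=occ_counts.astype(np.int64),
        event_bins=flat,
        total=data.shape[0],
        level_max=int(occ_counts.max()),
    )


def _log_posterior_from_counts(n: int, occ_counts: np.ndarray, nbins: int) -> float:
    # Empty bins: log Gamma(n_k + 1/2) = log Gamma(1/2), which cancels inside
    # the "- N^D log Gamma(1/2)" term, leaving only occupied-bin contributions.
    m = float(nbins)
    return float(
        n * np.log(m)
        + gammaln(0.5 * m)
        - len(occ_counts) * gammaln(0.5)
        - gammaln(n + 0.5 * m)
        + gammaln(np.asarray(occ_counts, dtype=float) + 0.5).sum()
    )


def log_binning_posterior(data, N: int) -> float:
    """Knuth log-posterior (up to an additive constant) of an N-per-axis grid."""
    data = as_events(data)
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if N ** data.shape[1] > MAX_TOTAL_BINS:
        raise CapacityError(
            f"N={N} in {data.shape[1]}D exceeds the addressable bin budget"
        )
    spec = _grid_spec(data, N)
    flat = _bin_indices(data, spec)
    _, occ_counts = np.unique(flat, return_counts=True)
    return _log_posterior_from_counts(data.shape[0], occ_counts, N ** data.shape[1])


def default_n_max(n: int, ndim: int) -> int:
    """Default upper end of the exhaustive bin-number scan."""
    return int(min(200, np.ceil(n ** (1.0 / ndim)) + 50))


def optimal_bin_number(data, N_max: int | None = None) -> int:
    """Bin number per axis maximizing the posterior over N = 1..N_max.

    The scan is exhaustive because the posterior can be multimodal.  Ties are
    broken toward smaller N.  All-identical data degenerates to N = 1 (with a
    warning).
    """
    data = as_events(data)
    n, ndim = data.shape
    if N_max is None:
        N_max = default_n_max(n, ndim)
    if N_max < 1:
        raise ValueError(f"N_max must be >= 1, got {N_max}")
    if np.all(data == data[0]):
        warnings.warn("all events identical: degenerate single-bin histogram")
        return 1
    spec_full = _grid_spec(data, 1)  # per-axis ranges are N-independent
    lo, hi = spec_full.lo, spec_full.hi
    best_N, best_lp = 1, -np.inf
    for N in range(1, N_max + 1):
        if N ** ndim > MAX_TOTAL_BINS:
            break
        flat = _bin_indices(data, GridSpec(N=N, lo=lo, hi=hi))
        _, occ_counts = np.unique(flat, return_counts=True)
        lp = _log_posterior_from_counts(n, occ_counts, N ** ndim)
        if lp > best_lp:
            best_N, best_lp = N, lp
    return best_N
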