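import numpy as np
import pytest
import scipy.ndimage as ndi

import densitygate as dg


def flood_fill_partition(mask: np.ndarray):
    """Independent Moore-connectivity component partition via scipy.ndimage."""
    labels, n = ndi.label(mask, structure=np.ones((3,) * mask.ndim, dtype=int))
    return labels, n


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two label grids induce the same partition of nonzero cells."""
    fa, fb = a.ravel(), b.ravel()
    if not np.array_equal(fa > 0, fb > 0):
        return False
    pairs = set(zip(fa[fa > 0].tolist(), fb[fb > 0].tolist()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


def hist_from_counts(counts):
    """HistogramGrid with prescribed bin contents plus matching synthetic events.

    Events sit at the centers of their bins on a unit grid, one row per count,
    so extract_clusters sees a consistent (events, histogram) pair.
    """
    counts = np.asarray(counts, dtype=np.int64)
    N = counts.shape[0]
    assert all(s == N for s in counts.shape), "grid must be N^D"
    ndim = counts.ndim
    flat_counts = counts.ravel()
    occupied = np.flatnonzero(flat_counts)
    occ_counts = flat_counts[occupied]
    event_bins = np.repeat(occupied, occ_counts)
    centers = (np.array(np.unravel_index(event_bins, counts.shape)).T + 0.5) / N
    spec = dg.GridSpec(N=N, lo=np.zeros(ndim), hi=np.ones(ndim))
    hist = dg.HistogramGrid(
        spec=spec,
        occupied=occupied,
        occ_counts=occ_counts,
        event_bins=event_bins,
        total=int(flat_counts.sum()),
        level_max=int(occ_counts.max()),
    )
    return hist, centers


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
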