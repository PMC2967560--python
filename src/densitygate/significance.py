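"""Poisson counting-fluctuation test separating major from small peaks.

Bin contents of a histogram of n independent events are binomial and, once the
local mean content exceeds ~10, well approximated by a Poisson distribution
whose mean is estimated by the average b_bar of the bin and its face-adjacent
neighbors and whose standard deviation is sqrt(b_bar).

When aggregates coalesce during the level sweep, a constituent peak of top
level Lp meeting the others at saddle level Ls is *major* when its height
above the saddle exceeds twice the combined Poisson fluctuation,

    Lp - Ls > 2 * sqrt(b_bar_peak + b_bar_saddle),

and *small* otherwise.  When b_bar_peak < 10 the Poisson approximation fails
and the peak is always considered small.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["local_mean", "is_major_peak", "POISSON_VALIDITY_MEAN"]

# Minimum local mean content for the Poisson approximation to hold.
POISSON_VALIDITY_MEAN = 10.0


def local_mean(hist, bin_index) -> float:
    """Mean content of a bin and its existing face-adjacent (+-1 single-axis) neighbors.

    Boundary bins average over fewer terms; unoccupied neighbor bins count as
    zero content.
    """
    idx = tuple(int(i) for i in np.atleast_1d(bin_index))
    total = hist.count_at(idx)  # raises on out-of-grid bins
    terms = 1
    N = hist.spec.N
    for axis in range(hist.ndim):
        for step in (-1, 1):
            j = idx[axis] + step
            if 0 <= j < N:
                nb = idx[:axis] + (j,) + idx[axis + 1:]
                total += hist.count_at(nb)
                terms += 1
    return total / terms


def is_major_peak(Lp: int, Ls: int, b_bar_p: float, b_bar_s: float) -> bool:
    """True iff the peak's height above its saddle beats 2x the Poisson SD."""
    if Lp < 0 or Ls < 0 or b_bar_p < 0 or b_bar_s < 0:
        raise ValueError("Lp, Ls and local means must be non-negative")
    if Lp < Ls:
        raise ValueError(f"peak level {Lp} below saddle level {Ls}")
    if b_bar_p < POISSON_VALIDITY_MEAN:
        return False
    return (Lp - Ls) > 2.0 * math.sqrt(b_bar_p + b_bar_s)
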