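"""Synthetic event data: sums of regular or distorted Gaussian populations.

Each population is a D-dimensional Gaussian with independent per-axis means
and standard deviations, optionally distorted by coupling one axis
quadratically onto another.  With k1 and k2 the two distortion axes of a
population and s the distortion strength, the K-th coordinate of an event is

    X_K = mean_K + delta   * sd_K                          K != k1, k2
    X_K = mean_K + delta_1 * sd_K                          K == k1
    X_K = mean_K + delta   * sd_K + s * (delta_1 * sd_k1)^2   K == k2

where delta_1 is drawn once per event (shared between k1 and the quadratic
term) and every other delta is an independent standard normal deviate produced
by the Box-Muller transform.  Setting s = 0 recovers a plain Gaussian; values
around 0.002-0.004 give the banana-shaped populations typical of fluorescence
channels.

Besides the generic mixture sampler this module ships the benchmark
generators used throughout the test suite: a four-component 2D mixture with
distinct histogram peaks and nonzero saddles, a non-convex (crescent + blob)
dataset, a uniform background contaminator, and a randomized 8-population 10D
mixture for the PCA pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComponentSpec",
    "normal_deviate",
    "sample_distorted_gaussian",
    "make_mixture",
    "four_gaussian_mixture_2d",
    "crescent_with_blob_2d",
    "add_uniform_background",
    "random_distorted_mixture",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One mixture component: per-axis mean/sd, distortion axes and strength.

    ``truncate`` optionally bounds the standardized deviate vector of each
    event (rejection sampling, so the shape of the retained density is
    unchanged and there is no boundary pile-up).  Real cytometers acquire into
    a bounded ADC range, so benchmark fixtures use a generous truncation
    radius to give populations the compact support of instrument data;
    ``None`` (the default) keeps the unbounded tails of the plain equations.
    """

    mean: tuple
    sd: tuple
    count: int
    k1: int = 0
    k2: int = 1
    s: float = 0.0
    truncate: float | None = None

    def __post_init__(self):
        mean = tuple(float(v) for v in np.atleast_1d(self.mean))
        sd = tuple(float(v) for v in np.atleast_1d(self.sd))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        ndim = len(mean)
        if len(sd) != ndim:
            raise ValueError("mean and sd must have the same length")
        if any(v <= 0 for v in sd):
            raise ValueError("standard deviations must be positive")
        if self.count < 1:
            raise ValueError("count must be positive")
        if ndim > 1:
            if not (0 <= self.k1 < ndim and 0 <= self.k2 < ndim):
                raise ValueError("distortion axes outside data dimension")
            if self.k1 == self.k2:
                raise ValueError("distortion axes k1 and k2 must differ")
        if self.s < 0:
            raise ValueError("distortion strength s must be non-negative")
        if self.truncate is not None and self.truncate <= 0:
            raise ValueError("truncation radius must be positive")

    @property
    def ndim(self) -> int:
        return len(self.mean)


def normal_deviate(rng, size=None):
    """Standard normal deviate(s) via the Box-Muller transform.

    delta = sqrt(-2 ln u1) * cos(2 pi u2) with u1, u2 uniform on (0, 1).
    ``rng`` is any object with a ``random(size)`` method (e.g. a
    ``numpy.random.Generator``); u1 is mapped to (0, 1] so the log is finite.
    """
    u1 = 1.0 - rng.random(size)
    u2 = rng.random(size)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


def _deviate_matrix(rng, m: int, ndim: int, truncate: float | None):
    """(m, D) standard-normal deviates, optionally rejection-truncated by radius."""
    mat = normal_deviate(rng, (m, ndim))
    if truncate is not None:
        r2 = truncate**2
        bad = np.flatnonzero((mat**2).sum(axis=1) > r2)
        while bad.size:
            mat[bad] = normal_deviate(rng, (bad.size, ndim))
            bad = bad[(mat[bad] ** 2).sum(axis=1) > r2]
    return mat


def sample_distorted_gaussian(spec: ComponentSpec, rng, count: int | None = None):
    """Draw events from one (possibly distorted) Gaussian component.

    Returns a (count, D) array; ``count`` defaults to ``spec.count``.  Column 0
    of the per-event deviate vector is delta_1, applied on axis k1 and reused
    for the quadratic term on axis k2; the remaining axes get independent
    deltas.
    """
    m = spec.count if count is None else int(count)
    ndim = spec.ndim
    mean = np.asarray(spec.mean)
    sd = np.asarray(spec.sd)
    dev = _deviate_matrix(rng, m, ndim, spec.truncate)
    out = np.empty((m, ndim))
    if ndim == 1:
        out[:, 0] = mean[0] + dev[:, 0] * sd[0]
        return out
    delta1 = dev[:, 0]
    col = 1
    for k in range(ndim):
        if k == spec.k1:
            out[:, k] = mean[k] + delta1 * sd[k]
        else:
            out[:, k] = mean[k] + dev[:, col] * sd[k]
            col += 1
            if k == spec.k2 and spec.s > 0:
                out[:, k] += spec.s * (delta1 * sd[spec.k1]) ** 2
    return out


def make_mixture(specs, seed):
    """Concatenate component samples; returns (events, ground-truth labels).

    Labels are 0-based component indices in spec order.  Fully reproducible
    from the seed.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one component")
    ndim = specs[0].ndim
    if any(s.ndim != ndim for s in specs):
        raise ValueError("all components must share the same dimension")
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for i, spec in enumerate(specs):
        parts.append(sample_distorted_gaussian(spec, rng))
        labels.append(np.full(spec.count, i, dtype=np.int64))
    return np.concatenate(parts), np.concatenate(labels)


def truncation_radius(ndim: int, mass: float = 0.995) -> float:
    """Standardized radius containing ``mass`` of a D-dim Gaussian (chi-square)."""
    from scipy.stats import chi2

    return float(np.sqrt(chi2.ppf(mass, df=ndim)))


def four_gaussian_mixture_2d(n: int = 100_000, s: float = 0.002, seed=0):
    """Benchmark 2D mixture of four distorted Gaussians.

    The component centers sit on the corners of a square of side 420 with
    per-axis SD 130, so pairwise center separations are 3.2 (sides) to 4.6
    (diagonal) within-component SDs: four distinct histogram peaks joined by
    nonzero saddles, the union of supports connected as in instrument data
    (components carry the 99.5% truncation radius).  Mixing fractions are
    0.3/0.3/0.2/0.2.  Returns (events, labels).
    """
    fractions = (0.3, 0.3, 0.2, 0.2)
    centers = ((300.0, 300.0), (720.0, 300.0), (300.0, 720.0), (720.0, 720.0))
    counts = [int(round(n * f)) for f in fractions]
    counts[0] += n - sum(counts)
    radius = truncation_radius(2)
    specs = [
        ComponentSpec(
            mean=c, sd=(130.0, 130.0), count=m, k1=0, k2=1, s=s, truncate=radius
        )
        for c, m in zip(centers, counts)
    ]
    return make_mixture(specs, seed)


def crescent_with_blob_2d(n: int = 40_000, seed=0):
    """Non-convex benchmark: a crescent-shaped population plus a separated blob.

    70% of events form a crescent: an arc of radius 250 around (500, 500) with
    radial SD 30 and a truncated-Gaussian angular spread of SD 0.33 rad (about
    a 98-degree arc), so the crest has a single density maximum whose
    along-arc scale (radius x angular SD ~ 83) is comparable to the radial SD
    — one smooth, strongly curved ridge whose convex hull is mostly empty.
    30% form a Gaussian blob at (1080, 500) with SD 40, several bin widths
    clear of the crescent.  Both populations carry the benchmark truncation
    radius so their supports stay disjoint.  Returns (events, labels) with
    label 0 = crescent, 1 = blob.
    """
    rng = np.random.default_rng(seed)
    n_arc = int(round(0.7 * n))
    n_blob = n - n_arc
    r_trunc = truncation_radius(2)
    angular_sd = 0.33
    theta = _deviate_matrix(rng, n_arc, 1, 2.6)[:, 0] * angular_sd
    radial = _deviate_matrix(rng, n_arc, 1, r_trunc)[:, 0]
    radius = 250.0 + radial * 30.0
    arc = np.column_stack(
        [500.0 + radius * np.cos(theta), 500.0 + radius * np.sin(theta)]
    )
    blob_spec = ComponentSpec(
        mean=(1080.0, 500.0), sd=(40.0, 40.0), count=n_blob, truncate=r_trunc
    )
    blob = sample_distorted_gaussian(blob_spec, rng)
    events = np.concatenate([arc, blob])
    labels = np.concatenate(
        [np.zeros(n_arc, dtype=np.int64), np.ones(n_blob, dtype=np.int64)]
    )
    return events, labels


def add_uniform_background(events, fraction: float = 0.05, seed=0):
    """Append uniform background events over the bounding box of the data.

    Returns (events_with_background, is_background flags).  The number of
    added events is ``fraction`` times the input size.
    """
    events = np.asarray(events, dtype=float)
    rng = np.random.default_rng(seed)
    m = int(round(fraction * events.shape[0]))
    lo, hi = events.min(axis=0), events.max(axis=0)
    noise = lo + rng.random((m, events.shape[1])) * (hi - lo)
    out = np.concatenate([events, noise])
    flags = np.concatenate(
        [np.zeros(events.shape[0], dtype=bool), np.ones(m, dtype=bool)]
    )
    return out, flags


def random_distorted_mixture(
    n_components: int = 8,
    ndim: int = 10,
    n: int = 500_000,
    s: float = 0.004,
    center_range: tuple = (0.0, 1000.0),
    sd_range: tuple = (0.0, 200.0),
    truncate: float | str | None = "auto",
    seed=0,
):
    """Randomized high-dimensional benchmark of distorted Gaussians.

    Component centers are uniform on ``center_range`` and per-axis SDs uniform
    on ``sd_range`` (open at zero: a tiny floor keeps them positive), with the
    two distortion axes drawn at random per component and roughly equal
    component sizes.  ``truncate="auto"`` applies the benchmark 99.5%
    truncation radius for ``ndim`` (instrument-like compact support); pass
    ``None`` for unbounded tails.  Returns (events, labels, specs).
    """
    if truncate == "auto":
        truncate = truncation_radius(ndim)
    rng = np.random.default_rng(seed)
    counts = np.full(n_components, n // n_components, dtype=int)
    counts[: n % n_components] += 1
    specs = []
    for i in range(n_components):
        mean = rng.uniform(center_range[0], center_range[1], size=ndim)
        sd = np.maximum(rng.uniform(sd_range[0], sd_range[1], size=ndim), 1e-6)
        k1, k2 = rng.choice(ndim, size=2, replace=False)
        specs.append(
            ComponentSpec(
                mean=tuple(mean), sd=tuple(sd), count=int(counts[i]),
                k1=int(k1), k2=int(k2), s=s, truncate=truncate,
            )
        )
    events, labels = make_mixture(specs, rng.integers(2**31))
    return events, labels, specs
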