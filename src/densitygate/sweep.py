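"""Top-down level sweep over histogram cross sections.

Cross sections are taken at integer levels from ``level_max - 1`` down to 0;
the section at LEVEL holds the bins whose content strictly exceeds LEVEL, so a
histogram whose fullest bin holds ``level_max`` events is swept through
``level_max`` cross sections.  Aggregates (Moore-connected components of a
cross section) nest as the level drops, and the sweep maintains a registry of
peaks — one per aggregate at its emergence — that it tracks through merges:

* a new aggregate with no registered peak inside starts a new *single* peak;
* an aggregate holding exactly one peak simply grows;
* when several peaks share an aggregate for the first time, each constituent
  that was single is tested against the Poisson fluctuation rule at the merge
  level.  If all constituents were single and at most one is major, only the
  highest peak is retained and the rest are discarded as noise.  Otherwise
  small single peaks are discarded, and each major single peak is finalized:
  its aggregate from one level above the merge — its largest still-separated
  cross section — is copied into the final label grid and the merge level is
  recorded as its saddle.

Peaks still single at level 0 contribute their level-0 aggregate.  Events in
bins of the final grid form the clusters; everything else stays unassigned
(tight clustering).  Per cluster the reliability of membership is
``f = (Lp - Ls) / Lp`` with Lp the peak top level and Ls its saddle level
(0 for peaks that never met a retained peak).

Two sweep engines share the per-aggregate dispatch logic: the default engine
visits only the levels where the thresholded bin set changes, activating bins
in decreasing content order into an incremental union-find; the reference
engine relabels every integer level from scratch.  Both produce bit-identical
results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .binning import (
    CRITICAL_DIM,
    HistogramGrid,
    as_events,
    build_histogram,
    optimal_bin_number,
)
from .labeling import label_aggregates, moore_offsets, threshold_cross_section
from .significance import is_major_peak, local_mean

__all__ = [
    "PeakType",
    "PeakRecord",
    "PeakRegistry",
    "FinalLabelGrid",
    "ClusterResult",
    "AggregateGroup",
    "reliability",
    "sweep_levels",
    "process_aggregate",
    "extract_clusters",
    "cluster",
]

logger = logging.getLogger("densitygate")

MIN_EVENTS_DEFAULT = 100


class PeakType(IntEnum):
    """Peak life-cycle state: single, eliminated noise, or finalized major."""

    SINGLE = 1
    MERGED_SMALL = 0
    MERGED_MAJOR = -1


@dataclass
class PeakRecord:
    """Bookkeeping for one histogram peak."""

    code: int
    char_bin: int        # characteristic position: first bin of the emergence aggregate
    top_bin: int         # fullest bin of the emergence aggregate (for the local mean)
    ptype: PeakType
    top_level: int
    saddle_level: int = 0
    finalized: bool = False


@dataclass
class PeakRegistry:
    """All peaks ever created, plus the set still tracked by the sweep."""

    peaks: dict[int, PeakRecord] = field(default_factory=dict)
    ncl: int = 0
    live: set[int] = field(default_factory=set)

    def new_peak(self, char_bin: int, top_bin: int, level: int) -> PeakRecord:
        self.ncl += 1
        rec = PeakRecord(
            code=self.ncl,
            char_bin=char_bin,
            top_bin=top_bin,
            ptype=PeakType.SINGLE,
            top_level=level,
        )
        self.peaks[rec.code] = rec
        self.live.add(rec.code)
        return rec

    def eliminate(self, code: int) -> None:
        self.peaks[code].ptype = PeakType.MERGED_SMALL
        self.live.discard(code)

    def live_singles(self):
        return [
            self.peaks[c]
            for c in sorted(self.live)
            if self.peaks[c].ptype is PeakType.SINGLE
        ]


@dataclass
class FinalLabelGrid:
    """Sparse final label grid: flat bin index -> cluster (peak) code."""

    shape: tuple[int, ...]
    codes: dict[int, int] = field(default_factory=dict)

    def copy_aggregate(self, bins, code: int) -> None:
        for b in bins:
            self.codes[int(b)] = code

    def labels_dense(self) -> np.ndarray:
        out = np.zeros(int(np.prod(self.shape)), dtype=np.int64)
        for b, c in self.codes.items():
            out[b] = c
        return out.reshape(self.shape)


@dataclass
class ClusterResult:
    """One gated population."""

    code: int            # output code: 1 = most populous cluster
    peak_code: int       # internal peak code in the registry / final grid
    Lp: int
    Ls: int
    bins: np.ndarray     # flat bin indices, ascending
    members: np.ndarray  # row indices of member events
    C: int
    f: float
    center: np.ndarray
    grid_shape: tuple[int, ...]

    @property
    def bin_count(self) -> int:
        return len(self.bins)

    def bin_vectors(self) -> set[tuple[int, ...]]:
        return set(map(tuple, np.array(np.unravel_index(self.bins, self.grid_shape)).T))


def reliability(Lp: int, Ls: int) -> float:
    """Cluster reliability f = (Lp - Ls) / Lp; 1 for peaks that never merged.

    A degenerate peak with Lp = 0 (content-1 bins emerging at level 0) never
    merged, so its reliability is 1.
    """
    if Lp < Ls or Ls < 0:
        raise ValueError(f"need Lp >= Ls >= 0, got Lp={Lp}, Ls={Ls}")
    if Lp == 0:
        return 1.0
    return (Lp - Ls) / Lp


@dataclass
class AggregateGroup:
    """One aggregate of the current cross section, as seen by the dispatcher.

    ``new_bins`` are the bins that entered the section at this level.
    ``prev_bins`` maps each live single peak inside the aggregate to its
    aggregate of the previous cross section (needed when a merge finalizes it).
    """

    peak_codes: list[int]
    new_bins: list[int]
    prev_bins: dict[int, list[int]]
    sort_key: int


def _argbest_bin(bins, hist: HistogramGrid) -> int:
    """Fullest bin of a set, ties broken toward the lexicographically first."""
    best, best_count = None, -1
    for b in sorted(bins):
        c = hist.occ_counts[np.searchsorted(hist.occupied, b)]
        if c > best_count:
            best, best_count = b, c
    return int(best)


def process_aggregate(
    group: AggregateGroup,
    level: int,
    hist: HistogramGrid,
    registry: PeakRegistry,
    final: FinalLabelGrid,
) -> None:
    """Dispatch one aggregate of the current cross section.

    Case a (no peak inside): a peak is just emerging — register it.
    Case b (one peak): the peak is still single; nothing to decide.
    Case c (several peaks): run the merge logic described in the module
    docstring (retention of the highest peak, elimination of small peaks,
    finalization of major peaks at their saddle).
    """
    shape = hist.shape
    codes = group.peak_codes
    if not codes:
        # case a: emerging peak; its aggregate consists of this level's new bins
        if not group.new_bins:
            raise RuntimeError("aggregate with no peak and no new bins")
        char_bin = min(group.new_bins)
        top_bin = _argbest_bin(group.new_bins, hist)
        rec = registry.new_peak(char_bin, top_bin, level)
        logger.debug(
            "level %d: peak %d emerges at bin %s",
            level, rec.code, np.unravel_index(char_bin, shape),
        )
        return
    if len(codes) == 1:
        return  # case b: still a single peak (or a lone finalized peak growing)

    # case c: several peaks share the aggregate
    singles = [registry.peaks[c] for c in codes if registry.peaks[c].ptype is PeakType.SINGLE]
    if singles and not group.new_bins:
        raise RuntimeError("merge without bridging bins")
    if not singles:
        return  # c23 only: previously merged peaks stay finalized

    saddle_bin = _argbest_bin(group.new_bins, hist)
    b_bar_s = local_mean(hist, np.unravel_index(saddle_bin, shape))
    major: dict[int, bool] = {}
    for rec in singles:
        b_bar_p = local_mean(hist, np.unravel_index(rec.top_bin, shape))
        major[rec.code] = is_major_peak(rec.top_level, level, b_bar_p, b_bar_s)
    inew = len(singles)
    ihigh = sum(major.values())

    if inew == len(codes) and ihigh <= 1:
        # c1: every constituent was single and at most one is major; keep the
        # highest peak, discard the rest as noise
        keep = sorted(singles, key=lambda r: (-r.top_level, r.code))[0]
        for rec in singles:
            if rec.code != keep.code:
                registry.eliminate(rec.code)
                logger.debug(
                    "level %d: peak %d eliminated (absorbed by peak %d)",
                    level, rec.code, keep.code,
                )
        return

    # c2: mixed merge
    for rec in singles:
        if major[rec.code]:
            # c22: finalize — store the last separated cross section
            rec.ptype = PeakType.MERGED_MAJOR
            rec.saddle_level = level
            rec.finalized = True
            final.copy_aggregate(group.prev_bins[rec.code], rec.code)
            logger.debug(
                "level %d: peak %d finalized with saddle %d (%d bins)",
                level, rec.code, level, len(group.prev_bins[rec.code]),
            )
        else:
            # c21: small single peak eliminated
            registry.eliminate(rec.code)
            logger.debug("level %d: peak %d eliminated (small at merge)", level, rec.code)
    # c23: previously merged peaks need no further storage


def _finalize_survivors(registry, final, comp_bins_of_peak) -> None:
    """Copy each still-single peak's level-0 aggregate into the final grid."""
    for rec in registry.live_singles():
        bins = comp_bins_of_peak(rec)
        final.copy_aggregate(bins, rec.code)
        rec.finalized = True
        logger.debug(
            "level 0: peak %d survives single (%d bins)", rec.code, len(bins)
        )


# ---------------------------------------------------------------------------
# fast engine: incremental union-find over bins in decreasing content order
# ---------------------------------------------------------------------------

class _BinForest:
    """Union-find over active bins carrying component bin lists and peak lists."""

    def __init__(self):
        self.parent: dict[int, int] = {}
        self.bins: dict[int, list[int]] = {}
        self.peaks: dict[int, list[int]] = {}
        self.min_bin: dict[int, int] = {}

    def add(self, b: int) -> None:
        self.parent[b] = b
        self.bins[b] = [b]
        self.peaks[b] = []
        self.min_bin[b] = b

    def find(self, b: int) -> int:
        root = b
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[b] != root:
            self.parent[b], b = root, self.parent[b]
        return root

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        if len(self.bins[ra]) < len(self.bins[rb]):
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.bins[ra].extend(self.bins.pop(rb))
        self.peaks[ra].extend(self.peaks.pop(rb))
        self.min_bin[ra] = min(self.min_bin[ra], self.min_bin.pop(rb))
        return ra


def _sweep_fast(hist: HistogramGrid) -> tuple[PeakRegistry, FinalLabelGrid]:
    shape = hist.shape
    strides = np.array(
        [int(np.prod(shape[k + 1:], dtype=object)) for k in range(len(shape))],
        dtype=np.int64,
    )
    offsets = moore_offsets(hist.ndim)
    off_flat = [int(np.dot(off, strides)) for off in offsets]

    # occupied bins grouped by content, visited in decreasing content order
    order = np.lexsort((hist.occupied, -hist.occ_counts))
    occ_sorted = hist.occupied[order]
    cnt_sorted = hist.occ_counts[order]
    coords = np.array(np.unravel_index(occ_sorted, shape)).T

    forest = _BinForest()
    registry = PeakRegistry()
    final = FinalLabelGrid(shape=shape)

    i = 0
    B = len(occ_sorted)
    while i < B:
        content = int(cnt_sorted[i])
        level = content - 1
        j = i
        while j < B and cnt_sorted[j] == content:
            j += 1
        new_bins = [int(b) for b in occ_sorted[i:j]]
        new_coords = coords[i:j]
        new_set = set(new_bins)

        # discover the edges this activation creates
        edges: list[tuple[int, int]] = []          # new bin <-> active bin
        touched_roots: dict[int, set[int]] = {}    # new bin -> old roots hit
        for b, m in zip(new_bins, new_coords):
            roots = set()
            for off, df in zip(offsets, off_flat):
                ok = True
                for k in range(len(shape)):
                    v = m[k] + off[k]
                    if v < 0 or v >= shape[k]:
                        ok = False
                        break
                if not ok:
                    continue
                nb = b + df
                if nb in new_set:
                    edges.append((b, nb))
                elif nb in forest.parent:
                    roots.add(forest.find(nb))
            touched_roots[b] = roots

        # group the affected old components and new bins without mutating the
        # forest, so previous-cross-section aggregates stay intact for copies
        gparent: dict[int, int] = {}

        def gfind(x: int) -> int:
            root = x
            while gparent[root] != root:
                root = gparent[root]
            while gparent[x] != root:
                gparent[x], x = root, gparent[x]
            return root

        def gunion(a: int, b: int) -> None:
            ra, rb = gfind(a), gfind(b)
            if ra != rb:
                gparent[rb] = ra

        for b in new_bins:
            gparent.setdefault(b, b)
        for b, roots in touched_roots.items():
            for r in roots:
                key = -r - 1  # old roots on a separate key range
                gparent.setdefault(key, key)
                gunion(b, key)
        for a, b in edges:
            gunion(a, b)

        groups: dict[int, dict] = {}
        for x in list(gparent):
            g = groups.setdefault(gfind(x), {"new": [], "old": []})
            if x >= 0:
                g["new"].append(x)
            else:
                g["old"].append(-x - 1)

        # dispatch groups in canonical (lexicographically-first-bin) order
        ordered = []
        for g in groups.values():
            mins = [min(g["new"])] if g["new"] else []
            mins += [forest.min_bin[r] for r in g["old"]]
            ordered.append((min(mins), g))
        ordered.sort(key=lambda t: t[0])

        for sort_key, g in ordered:
            peak_codes = sorted(
                c for r in g["old"] for c in forest.peaks[r] if c in registry.live
            )
            prev_bins = {}
            for c in peak_codes:
                rec = registry.peaks[c]
                if rec.ptype is PeakType.SINGLE and len(peak_codes) > 1:
                    prev_bins[c] = forest.bins[forest.find(rec.char_bin)]
            process_aggregate(
                AggregateGroup(
                    peak_codes=peak_codes,
                    new_bins=sorted(g["new"]),
                    prev_bins=prev_bins,
                    sort_key=sort_key,
                ),
                level,
                hist,
                registry,
                final,
            )

        # apply the activation to the forest
        for b in new_bins:
            forest.add(b)
        for b, roots in touched_roots.items():
            for r in roots:
                forest.union(b, r)
        for a, b in edges:
            forest.union(a, b)
        # keep only live peaks attached to components; new case-a peaks attach
        # to the component holding their characteristic bin
        for root in {forest.find(b) for b in new_bins}:
            forest.peaks[root] = [c for c in forest.peaks[root] if c in registry.live]
        for c in registry.live:
            rec = registry.peaks[c]
            if rec.char_bin in new_set:
                forest.peaks[forest.find(rec.char_bin)].append(c)

        i = j

    _finalize_survivors(
        registry, final, lambda rec: forest.bins[forest.find(rec.char_bin)]
    )
    return registry, final


# ---------------------------------------------------------------------------
# reference engine: relabel every integer level from scratch
# ---------------------------------------------------------------------------

def _sweep_naive(hist: HistogramGrid) -> tuple[PeakRegistry, FinalLabelGrid]:
    shape = hist.shape
    counts = hist.counts_dense().ravel()
    registry = PeakRegistry()
    final = FinalLabelGrid(shape=shape)

    prev_active = np.zeros(counts.shape, dtype=bool)
    prev_comp_of_bin: dict[int, int] = {}
    prev_comps: dict[int, list[int]] = {}
    comps: dict[int, list[int]] = {}

    for level in range(hist.level_max - 1, -1, -1):
        active = counts > level
        lg = label_aggregates(active.reshape(shape))
        labels = lg.labels.ravel()
        new_flags = active & ~prev_active

        comps = {}
        for b in np.flatnonzero(active):
            comps.setdefault(int(labels[b]), []).append(int(b))

        peaks_in: dict[int, list[int]] = {lab: [] for lab in comps}
        for c in sorted(registry.live):
            lab = int(labels[registry.peaks[c].char_bin])
            if lab == 0:
                raise RuntimeError(f"live peak {c} missing from cross section")
            peaks_in[lab].append(c)

        for lab, bins in sorted(comps.items(), key=lambda kv: kv[1][0]):
            codes = peaks_in[lab]
            prev_bins = {}
            for c in codes:
                rec = registry.peaks[c]
                if rec.ptype is PeakType.SINGLE and len(codes) > 1:
                    prev_bins[c] = prev_comps[prev_comp_of_bin[rec.char_bin]]
            process_aggregate(
                AggregateGroup(
                    peak_codes=codes,
                    new_bins=[b for b in bins if new_flags[b]],
                    prev_bins=prev_bins,
                    sort_key=bins[0],
                ),
                level,
                hist,
                registry,
                final,
            )

        prev_active = active
        prev_comps = comps
        prev_comp_of_bin = {b: lab for lab, bins in comps.items() for b in bins}

    last_comp_of_bin = prev_comp_of_bin
    last_comps = comps
    _finalize_survivors(
        registry, final, lambda rec: last_comps[last_comp_of_bin[rec.char_bin]]
    )
    return registry, final


def sweep_levels(
    hist: HistogramGrid, *, every_level: bool = False
) -> tuple[PeakRegistry, FinalLabelGrid]:
    """Run the top-down sweep and return the peak registry and final labels.

    ``every_level=True`` selects the reference engine that thresholds and
    relabels each of the ``level_max`` integer levels from scratch; the default
    engine visits only levels where the cross section changes.  Results are
    identical.
    """
    if hist.level_max < 1:
        raise ValueError("histogram is empty")
    logger.info(
        "sweeping %s grid, level_max=%d", "x".join(map(str, hist.shape)), hist.level_max
    )
    if every_level:
        return _sweep_naive(hist)
    return _sweep_fast(hist)


def extract_clusters(
    data, hist: HistogramGrid, final: FinalLabelGrid, registry: PeakRegistry
) -> list[ClusterResult]:
    """Collect events of each final aggregate into ClusterResults.

    Clusters are sorted by descending population and assigned output codes
    1, 2, ... (1 = most populous); events in unlabeled bins stay unassigned.
    """
    data = as_events(data)
    if not final.codes:
        warnings.warn("empty final label grid: all peaks were eliminated")
        return []

    bins_sorted = np.fromiter(sorted(final.codes), dtype=np.int64)
    code_for_bin = np.array([final.codes[b] for b in bins_sorted], dtype=np.int64)
    pos = np.searchsorted(bins_sorted, hist.event_bins)
    pos_ok = pos < len(bins_sorted)
    hit = np.zeros(len(hist.event_bins), dtype=bool)
    hit[pos_ok] = bins_sorted[pos[pos_ok]] == hist.event_bins[pos_ok]
    event_code = np.zeros(len(hist.event_bins), dtype=np.int64)
    event_code[hit] = code_for_bin[pos[hit]]

    results = []
    for peak_code in sorted(set(final.codes.values())):
        rec = registry.peaks[peak_code]
        members = np.flatnonzero(event_code == peak_code)
        bins = bins_sorted[code_for_bin == peak_code]
        results.append(
            ClusterResult(
                code=0,
                peak_code=peak_code,
                Lp=rec.top_level,
                Ls=rec.saddle_level,
                bins=bins,
                members=members,
                C=len(members),
                f=reliability(rec.top_level, rec.saddle_level),
                center=data[members].mean(axis=0) if len(members) else np.full(data.shape[1], np.nan),
                grid_shape=hist.shape,
            )
        )
    results.sort(key=lambda r: (-r.C, r.peak_code))
    for rank, r in enumerate(results, start=1):
        r.code = rank
    return results


def cluster(
    data,
    *,
    N: int | None = None,
    N_max: int | None = None,
    critical_dim: int = CRITICAL_DIM,
    min_events: int = MIN_EVENTS_DEFAULT,
    every_level: bool = False,
) -> list[ClusterResult]:
    """Full pipeline: optimal binning, level sweep, cluster extraction.

    Deterministic given the data and options.  Data of dimension above
    ``critical_dim`` is refused here; use
    :func:`densitygate.highdim.cluster_high_dimensional`, which projects to a
    manageable subspace first.
    """
    data = as_events(data)
    n, ndim = data.shape
    if n < min_events:
        raise ValueError(f"need at least {min_events} events, got {n}")
    if ndim > critical_dim:
        raise ValueError(
            f"{ndim}D data exceeds the critical dimension {critical_dim}; "
            "use densitygate.highdim.cluster_high_dimensional"
        )
    if np.all(data == data[0]):
        raise ValueError("all events identical: no histogram structure")
    if N is None:
        N = optimal_bin_number(data, N_max)
    logger.info("histogram: %d bins per axis in %dD", N, ndim)
    hist = build_histogram(data, N)
    registry, final = sweep_levels(hist, every_level=every_level)
    clusters = extract_clusters(data, hist, final, registry)
    for r in clusters:
        logger.info(
            "cluster %d: Lp=%d Ls=%d C=%d bins=%d f=%.3f",
            r.code, r.Lp, r.Ls, r.C, r.bin_count, r.f,
        )
    return clusters
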