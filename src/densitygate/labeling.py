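"""Connected-component labeling of histogram cross sections.

A cross section at a given level is the binary grid marking bins whose content
strictly exceeds the level.  Aggregates (components) are labeled with the
three-step raster-scan procedure used in percolation theory for spin clusters,
extended with the next-nearest-neighbor links so that elongated slanted
aggregates are labeled as one: in 2D the scanned predecessors of cell (I, J)
are (I-1, J-1), (I-1, J), (I-1, J+1) and (I, J-1); in D dimensions they are
all previously scanned cells of the full 3^D - 1 Moore neighborhood.

Label equivalences discovered during the first scan are recorded in a
count-map vector whose chains terminate in the smallest label of each
aggregate; the second scan replaces every provisional label by that root.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "LabelGrid",
    "threshold_cross_section",
    "label_aggregates",
    "resolve_label",
    "causal_offsets",
    "moore_offsets",
]


@dataclass
class LabelGrid:
    """Labeled cross section: 0 below level, positive aggregate labels above."""

    labels: np.ndarray
    level: int | None
    count_map: np.ndarray
    max_label: int

    @property
    def n_aggregates(self) -> int:
        roots = np.unique(self.labels)
        return int((roots > 0).sum())


def threshold_cross_section(hist, level: int) -> np.ndarray:
    """Binary grid marking bins whose content strictly exceeds ``level``."""
    if not 0 <= level <= hist.level_max:
        raise ValueError(
            f"level {level} outside [0, {hist.level_max}]"
        )
    return (hist.counts_dense() > level).astype(np.uint8)


def moore_offsets(ndim: int) -> list[tuple[int, ...]]:
    """All 3^D - 1 nonzero offsets of the diagonal-inclusive neighborhood."""
    return [o for o in product((-1, 0, 1), repeat=ndim) if any(o)]


def causal_offsets(ndim: int) -> list[tuple[int, ...]]:
    """Moore offsets pointing at cells already visited by a C-order raster scan.

    These are the offsets whose first nonzero component is -1; in 2D exactly
    (-1,-1), (-1,0), (-1,+1), (0,-1).
    """
    out = []
    for o in moore_offsets(ndim):
        first = next(c for c in o if c)
        if first < 0:
            out.append(o)
    return out


def resolve_label(label: int, count_map) -> int:
    """Follow the equivalence chain until it reaches its fixed point (the root)."""
    seen = 0
    limit = len(count_map)
    current = int(label)
    while True:
        nxt = int(count_map[current])
        if nxt == current:
            return current
        current = nxt
        seen += 1
        if seen > limit:
            raise RuntimeError("cyclic label-equivalence chain")


def label_aggregates(mask) -> LabelGrid:
    """Label the aggregates of a binary grid (Moore connectivity).

    Step 1 marks every set cell with a sentinel; step 2 raster-scans in
    lexicographic order, creating a new label when all causal predecessors are
    empty and otherwise pointing every predecessor's root (and the cell) at the
    smallest root JM; step 3 rewrites each cell to its resolved root, so the
    final label of an aggregate is the smallest label ever created inside it.
    """
    mask = np.asarray(mask)
    shape = mask.shape
    ndim = mask.ndim
    offsets = causal_offsets(ndim)

    labels = np.zeros(shape, dtype=np.int64)
    count_map = [0]  # 1-based; count_map[l] is the equivalence pointer of l
    next_label = 0

    cells = np.argwhere(mask)  # lexicographic (C) order
    cell_labels = {}
    for cell in map(tuple, cells):
        pred_roots = []
        for off in offsets:
            nb = tuple(c + o for c, o in zip(cell, off))
            if all(0 <= v < s for v, s in zip(nb, shape)):
                lab = cell_labels.get(nb, 0)
                if lab:
                    pred_roots.append(resolve_label(lab, count_map))
        if not pred_roots:
            next_label += 1
            count_map.append(next_label)
            cell_labels[cell] = next_label
        else:
            jm = min(pred_roots)
            for r in pred_roots:
                count_map[r] = jm
            cell_labels[cell] = jm

    cmap = np.asarray(count_map, dtype=np.int64)
    for cell, lab in cell_labels.items():
        labels[cell] = resolve_label(lab, cmap)
    return LabelGrid(labels=labels, level=None, count_map=cmap, max_label=next_label)
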