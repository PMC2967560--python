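"""Readers and writers for event tables, cluster outputs and run configs.

Delimited text (CSV/TSV with a header row) is the interchange format: one row
per event, one column per channel.  Outputs are an assignment file (event row
index and cluster code, 0 = unassigned) and a summary table with one row per
cluster (code, Lp, Ls, C, bin count, f, center coordinates), ordered by
descending population so that code 1 is the most populous cluster.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binning import as_events
from .simulate import ComponentSpec

__all__ = [
    "read_points",
    "write_points",
    "write_assignments",
    "write_summary",
    "read_component_specs",
    "read_config",
]


def _separator(path: Path, fmt: str | None) -> str:
    if fmt == "tsv":
        return "\t"
    if fmt == "csv":
        return ","
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_points(path, channels=None, fmt: str | None = None) -> np.ndarray:
    """Read selected channels of a delimited event table as an (n, D) array.

    ``channels`` may be column names, 0-based integer indices, or None for all
    columns.  Non-numeric cells raise a ValueError naming the offending row
    and column.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_separator(path, fmt), float_precision="round_trip")
    if channels is not None:
        channels = list(channels)
        if not channels:
            raise ValueError("empty channel selection")
        cols = []
        for ch in channels:
            if isinstance(ch, (int, np.integer)):
                if not 0 <= ch < frame.shape[1]:
                    raise ValueError(f"channel index {ch} out of range")
                cols.append(frame.columns[ch])
            elif ch in frame.columns:
                cols.append(ch)
            else:
                raise ValueError(f"unknown channel {ch!r}; file has {list(frame.columns)}")
        frame = frame[cols]
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {frame[col].iloc[row]!r} at row {row}, column {col!r}"
            )
        frame[col] = numeric
    if frame.isna().any().any():
        raise ValueError("missing values in event table")
    return as_events(frame.to_numpy(dtype=float))


def write_points(events, path, labels=None, channel_names=None) -> None:
    """Write an event table as CSV, optionally with a ground-truth label column."""
    events = as_events(events)
    names = channel_names or [f"ch{k + 1}" for k in range(events.shape[1])]
    frame = pd.DataFrame(events, columns=names)
    if labels is not None:
        frame["label"] = np.asarray(labels)
    # %.17g keeps the write -> read round trip bit-identical for float64
    frame.to_csv(path, index=False, float_format="%.17g")


def write_assignments(events, clusters, path) -> None:
    """One row per event: original row index and cluster code (0 = unassigned)."""
    events = as_events(events)
    codes = np.zeros(events.shape[0], dtype=np.int64)
    for r in clusters:
        codes[r.members] = r.code
    pd.DataFrame({"index": np.arange(events.shape[0]), "cluster": codes}).to_csv(
        path, index=False
    )


def write_summary(clusters, path) -> None:
    """Tab-delimited cluster table sorted by descending population."""
    rows = []
    for r in sorted(clusters, key=lambda r: (-r.C, r.code)):
        row = {
            "code": r.code,
            "Lp": r.Lp,
            "Ls": r.Ls,
            "C": r.C,
            "bins": r.bin_count,
            "f": f"{r.f:.3f}",
        }
        for k, v in enumerate(np.atleast_1d(r.center), start=1):
            row[f"center_{k}"] = f"{v:.6g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_component_specs(path) -> list[ComponentSpec]:
    """Load mixture component specs from a YAML file.

    Layout::

        components:
          - mean: [300, 300]
            sd: [100, 100]
            count: 30000
            k1: 0        # optional, default 0
            k2: 1        # optional, default 1
            s: 0.002     # optional, default 0
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "components" not in doc:
        raise ValueError("spec file must contain a 'components' list")
    specs = []
    for entry in doc["components"]:
        specs.append(
            ComponentSpec(
                mean=entry["mean"],
                sd=entry["sd"],
                count=int(entry["count"]),
                k1=int(entry.get("k1", 0)),
                k2=int(entry.get("k2", 1)),
                s=float(entry.get("s", 0.0)),
                truncate=(
                    float(entry["truncate"]) if entry.get("truncate") else None
                ),
            )
        )
    return specs


def read_config(path) -> dict:
    """Flat key=value config file mirroring the CLI flags (CLI overrides it)."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line {lineno}: {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            out[key.replace("-", "_")] = value
    return out
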