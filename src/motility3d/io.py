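"""Data model and delimited-text I/O for 3D cell trajectories.

A :class:`Track` is one cell's ordered ``(t, x, y, z)`` samples (seconds /
micrometres) together with its cell, imaging-frame (field) and tissue
identity.  A :class:`TrackSet` groups tracks hierarchically as
tissue -> frame -> cells, mirroring how intravital two-photon data are
acquired: each frame is one imaging field, each tissue pools the frames of
all animals imaged in that tissue.

The on-disk format is a delimited text table with a header, one row per
cell per time point.  Canonical columns are
``cell_id, frame_id, tissue, time_s, x_um, y_um, z_um``; a *dialect*
mapping lets externally exported tables (Imaris/TrackMate-style) be adapted
by renaming columns before load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "TrackPoint",
    "Track",
    "TrackSet",
    "SchemaError",
    "TrackValidationError",
    "CANONICAL_COLUMNS",
    "read_tracks",
    "write_tracks",
]

#: canonical column order of the track table
CANONICAL_COLUMNS = ("cell_id", "frame_id", "tissue", "time_s", "x_um", "y_um", "z_um")


class SchemaError(ValueError):
    """A required column cannot be resolved in the input table."""


class TrackValidationError(ValueError):
    """Row- or track-level contents violate the track data contract."""


class TrackPoint(NamedTuple):
    """One observation of a cell: time in seconds, position in micrometres."""

    t: float
    x: float
    y: float
    z: float


@dataclass
class Track:
    """One cell's trajectory: strictly time-ordered 3D positions.

    Parameters
    ----------
    cell_id, frame_id, tissue
        Opaque identity strings.  ``cell_id`` must be unique within its frame.
    t
        Sample times in seconds, strictly increasing, non-negative, finite.
    xyz
        ``(n, 3)`` positions in micrometres, finite.
    """

    cell_id: str
    frame_id: str
    tissue: str
    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise TrackValidationError(
                f"track {self.cell_id!r}: t must be 1-D and xyz (n, 3); "
                f"got t{self.t.shape} xyz{self.xyz.shape}"
            )
        if self.t.size < 2:
            raise TrackValidationError(
                f"track {self.cell_id!r}: needs at least 2 points, got {self.t.size}"
            )
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xyz)):
            raise TrackValidationError(f"track {self.cell_id!r}: non-finite values")
        if np.any(self.t < 0):
            raise TrackValidationError(f"track {self.cell_id!r}: negative times")
        if np.any(np.diff(self.t) <= 0):
            raise TrackValidationError(
                f"track {self.cell_id!r}: times must be strictly increasing "
                "(duplicate or unordered time points)"
            )

    @property
    def n_points(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> float:
        """Total tracked time in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def points(self) -> list[TrackPoint]:
        return [TrackPoint(float(t), *map(float, p)) for t, p in zip(self.t, self.xyz)]

    @property
    def key(self) -> tuple[str, str]:
        """(frame_id, cell_id): unique within a TrackSet."""
        return (self.frame_id, self.cell_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Track):
            return NotImplemented
        return (
            self.cell_id == other.cell_id
            and self.frame_id == other.frame_id
            and self.tissue == other.tissue
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.xyz, other.xyz)
        )


@dataclass
class TrackSet:
    """A collection of tracks with tissue -> frame -> cell grouping.

    ``metadata`` carries provenance: source description, nominal time step in
    seconds, and load/resample bookkeeping counts.
    """

    tracks: list[Track] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for tr in self.tracks:
            if tr.key in seen:
                raise TrackValidationError(
                    f"duplicate cell {tr.cell_id!r} in frame {tr.frame_id!r}"
                )
            seen.add(tr.key)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrackSet):
            return NotImplemented
        if len(self) != len(other):
            return False
        a = sorted(self.tracks, key=lambda tr: tr.key)
        b = sorted(other.tracks, key=lambda tr: tr.key)
        return all(x == y for x, y in zip(a, b))

    @property
    def tissues(self) -> list[str]:
        return sorted({tr.tissue for tr in self.tracks})

    @property
    def grouping(self) -> dict[str, dict[str, list[str]]]:
        """tissue -> frame_id -> sorted cell_ids; every track appears once."""
        out: dict[str, dict[str, list[str]]] = {}
        for tr in self.tracks:
            out.setdefault(tr.tissue, {}).setdefault(tr.frame_id, []).append(tr.cell_id)
        for frames in out.values():
            for cells in frames.values():
                cells.sort()
        return out

    def subset(
        self,
        tissue: str | None = None,
        frame_ids: Iterable[str] | None = None,
    ) -> "TrackSet":
        frames = set(frame_ids) if frame_ids is not None else None
        kept = [
            tr
            for tr in self.tracks
            if (tissue is None or tr.tissue == tissue)
            and (frames is None or tr.frame_id in frames)
        ]
        return TrackSet(kept, dict(self.metadata))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table with the canonical columns, tracks in sorted key order."""
        rows = []
        for tr in sorted(self.tracks, key=lambda tr: tr.key):
            for t, (x, y, z) in zip(tr.t, tr.xyz):
                rows.append((tr.cell_id, tr.frame_id, tr.tissue, t, x, y, z))
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _resolve_columns(
    df: pd.DataFrame, dialect: Mapping[str, str] | None
) -> pd.DataFrame:
    mapping = {c: c for c in CANONICAL_COLUMNS}
    if dialect:
        mapping.update(dialect)
    missing = [f"{k} (looked for {v!r})" for k, v in mapping.items() if v not in df.columns]
    if missing:
        raise SchemaError("missing required column(s): " + ", ".join(missing))
    out = df[[mapping[c] for c in CANONICAL_COLUMNS]].copy()
    out.columns = list(CANONICAL_COLUMNS)
    return out


def read_tracks(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> TrackSet:
    """Load a track table (comma- or tab-delimited, header required).

    Rows are sorted by time within each cell, so input row order is
    irrelevant.  Tracks with a single point are dropped; the count of dropped
    tracks is recorded in ``metadata['n_dropped_short_tracks']``.

    Raises
    ------
    SchemaError
        If a required column is missing.
    TrackValidationError
        On a non-numeric coordinate (reported with its line number) or a
        duplicate ``(cell, t)`` observation.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str, encoding="utf-8")
    df = _resolve_columns(raw, dialect)

    numeric = {}
    for col in ("time_s", "x_um", "y_um", "z_um"):
        # float() round-trips shortest-repr values exactly (pd.to_numeric does not)
        raw_vals = df[col].to_numpy()
        vals = np.empty(len(raw_vals))
        bad_lines = []
        for i, s in enumerate(raw_vals):
            try:
                vals[i] = float(s)
            except (TypeError, ValueError):
                bad_lines.append(int(df.index[i]) + 2)  # +2: header + 1-based
        if bad_lines:
            raise TrackValidationError(
                f"non-numeric value in column {col!r} at line(s) {bad_lines[:5]}"
            )
        numeric[col] = vals

    for col in ("cell_id", "frame_id", "tissue"):
        df[col] = df[col].astype(str)

    keys = pd.DataFrame(
        {
            "frame_id": df["frame_id"],
            "cell_id": df["cell_id"],
            "tissue": df["tissue"],
            "time_s": numeric["time_s"],
        }
    )
    dup = keys.duplicated(subset=["frame_id", "cell_id", "time_s"])
    if dup.any():
        lines = [int(i) + 2 for i in keys.index[dup][:5]]
        raise TrackValidationError(f"duplicate (cell, time) observation at line(s) {lines}")

    tracks: list[Track] = []
    n_short = 0
    full = df.assign(**numeric)
    for (frame_id, cell_id), grp in full.groupby(["frame_id", "cell_id"], sort=True):
        tissues = grp["tissue"].unique()
        if len(tissues) > 1:
            raise TrackValidationError(
                f"cell {cell_id!r} in frame {frame_id!r} spans multiple tissues: "
                f"{sorted(tissues)}"
            )
        grp = grp.sort_values("time_s")
        if len(grp) < 2:
            n_short += 1
            continue
        tracks.append(
            Track(
                cell_id=str(cell_id),
                frame_id=str(frame_id),
                tissue=str(tissues[0]),
                t=grp["time_s"].to_numpy(),
                xyz=grp[["x_um", "y_um", "z_um"]].to_numpy(),
            )
        )
    tracks.sort(key=lambda tr: tr.key)
    return TrackSet(
        tracks,
        metadata={
            "source": str(path),
            "n_rows": int(len(df)),
            "n_dropped_short_tracks": n_short,
        },
    )


def write_tracks(ts: TrackSet, path: str | Path) -> None:
    """Write a TrackSet to the canonical CSV.  Round-trips exactly through
    :func:`read_tracks` (float values are written with shortest-repr precision)."""
    df = ts.to_dataframe()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
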