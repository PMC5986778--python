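"""Marker-track file I/O and dominant-plane projection.

Tracks are exchanged as long (tidy) delimited text with a header row
``marker,time,x,y,z`` -- one row per sample per marker, comma or tab
separated, lengths in mm (or m, rescaled on read) and time in seconds.
The z column is optional and treated as 0 when absent.  The long format
is deliberately strict and unambiguous; wide multi-header motion-capture
exports should be melted to it beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PlanarTrajectory
from .errors import ParameterError, TrackFormatError

__all__ = [
    "MarkerTrack3D",
    "PlaneProjection",
    "read_tracks",
    "write_tracks",
    "write_trajectory",
    "project_dominant_plane",
]

_REQUIRED = ("marker", "time", "x", "y")


@dataclass(frozen=True)
class MarkerTrack3D:
    """One marker's uniformly sampled 3D track (times s, coordinates mm)."""

    marker_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if not (t.size == self.x.size == self.y.size == self.z.size):
            raise ParameterError("times, x, y, z must have equal lengths")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ParameterError("times must be strictly increasing, n >= 2")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_tracks(path, dialect: str | None = None, units: str = "mm") -> list[MarkerTrack3D]:
    """Read a long-format delimited track file into per-marker tracks.

    ``dialect`` is 'comma' or 'tab' (auto-detected from the header when
    omitted).  Sampling must be uniform per marker: any time step larger
    than 1.5x the median step is reported as a gap with its location.
    Errors cite 1-based file line numbers (header is line 1).
    """
    if dialect is None:
        sep = _detect_sep(path)
    elif dialect in ("comma", ","):
        sep = ","
    elif dialect in ("tab", "\t"):
        sep = "\t"
    else:
        raise ParameterError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'")
    if units not in ("mm", "m"):
        raise ParameterError(f"units must be 'mm' or 'm', got {units!r}")

    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TrackFormatError(
            f"{path}: missing required column(s) {missing}; header must contain "
            "marker,time,x,y[,z]"
        )
    if "z" not in df.columns:
        df["z"] = "0"

    numeric = {}
    for col in ("time", "x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad) > 0:
            raise TrackFormatError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} in column "
                f"'{col}' at line {bad[0] + 2}"
            )
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2
            raise TrackFormatError(f"{path}: empty cell in column '{col}' at line {line}")
        numeric[col] = vals.to_numpy(float)

    scale = 1000.0 if units == "m" else 1.0
    tracks = []
    for marker, grp in df.groupby("marker", sort=False):
        idx = grp.index.to_numpy()
        t = numeric["time"][idx]
        order = np.argsort(t, kind="stable")
        idx, t = idx[order], t[order]
        steps = np.diff(t)
        if t.size < 2:
            raise TrackFormatError(f"{path}: marker {marker!r} has fewer than 2 samples")
        if np.any(steps <= 0):
            line = int(idx[np.argmax(steps <= 0) + 1]) + 2
            raise TrackFormatError(
                f"{path}: duplicate or non-increasing time for marker {marker!r} "
                f"near line {line}"
            )
        med = float(np.median(steps))
        gaps = np.nonzero(steps > 1.5 * med)[0]
        if gaps.size:
            g = int(gaps[0])
            raise TrackFormatError(
                f"{path}: sampling gap for marker {marker!r} between t={t[g]:g} s "
                f"and t={t[g + 1]:g} s (step {steps[g]:g} s vs median {med:g} s), "
                f"near line {int(idx[g + 1]) + 2}"
            )
        tracks.append(
            MarkerTrack3D(
                marker_id=str(marker),
                times=t,
                x=numeric["x"][idx] * scale,
                y=numeric["y"][idx] * scale,
                z=numeric["z"][idx] * scale,
            )
        )
    if not tracks:
        raise TrackFormatError(f"{path}: file contains no samples")
    return tracks


def write_tracks(path, tracks, dialect: str = "comma") -> None:
    """Write tracks in the long format read by :func:`read_tracks`.

    Values are written with 12 significant digits, so a write/read cycle
    is exact well beyond the 9 significant digits the format guarantees.
    """
    sep = "\t" if dialect in ("tab", "\t") else ","
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["marker", "time", "x", "y", "z"]) + "\n")
        for tr in tracks:
            for t, x, y, z in zip(tr.times, tr.x, tr.y, tr.z):
                fh.write(
                    sep.join([tr.marker_id] + [f"{v:.12g}" for v in (t, x, y, z)]) + "\n"
                )


def write_trajectory(path, traj: PlanarTrajectory, dialect: str = "comma") -> None:
    """Write a planar trajectory as a track file with z = 0."""
    track = MarkerTrack3D(
        marker_id=traj.marker_id,
        times=traj.times,
        x=traj.x,
        y=traj.y,
        z=np.zeros_like(traj.x),
    )
    write_tracks(path, [track], dialect=dialect)


@dataclass(frozen=True)
class PlaneProjection:
    """Result of projecting a 3D track onto its dominant motion plane."""

    trajectory: PlanarTrajectory
    #: fraction of total displacement variance in the discarded direction
    discarded_variance_fraction: float
    #: unit normal of the retained plane, measurement frame
    normal: np.ndarray


def project_dominant_plane(track: MarkerTrack3D) -> PlaneProjection:
    """Project a 3D track onto the plane of its two dominant displacement axes.

    Coordinates are centred on their means; the direction of least
    displacement variance (from the SVD of the centred cloud) is
    discarded.  The in-plane basis is anchored to the measurement axes --
    the projection of the measurement x-axis (or y-axis, if x is nearly
    normal to the plane) -- so a track whose z is constant comes back as
    exactly (x - mean, y - mean); basis vectors are then ordered by
    variance of their scores.
    """
    pts = np.column_stack([track.x, track.y, track.z]).astype(float)
    if pts.shape[0] < 10:
        raise ParameterError("need at least 10 samples to identify the plane")
    centered = pts - pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] <= 0:
        raise ParameterError("degenerate track: all points identical")
    normal = vt[2]
    if normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal  # deterministic orientation
    total = float(np.sum(svals**2))
    discarded = float(svals[2] ** 2) / total

    # in-plane basis anchored to the measurement axes
    ex = np.array([1.0, 0.0, 0.0])
    u = ex - (ex @ normal) * normal
    if np.linalg.norm(u) < 1e-6:
        ey = np.array([0.0, 1.0, 0.0])
        u = ey - (ey @ normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    su = centered @ u
    sv = centered @ v
    if sv.var() > su.var():
        su, sv = sv, -su  # keep the basis right-handed about the normal
    return PlaneProjection(
        trajectory=PlanarTrajectory(
            times=track.times,
            x=su,
            y=sv,
            sample_rate=track.sample_rate,
            marker_id=track.marker_id,
        ),
        discarded_variance_fraction=discarded,
        normal=normal,
    )
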