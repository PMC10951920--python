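"""Track, ROI and image-stack data model with CSV/TIFF readers and writers.

Canonical internal units are micrometres for coordinates and seconds for
time; pixel coordinates are converted at the I/O boundary using the pixel
size, never downstream.  Frames are 0-based integers counted from the start
of the acquisition; the image convention applies (origin at the top-left,
x rightward, y downward).  Tracks may contain frame gaps (a linker with gap
closing produces them) and gaps are preserved, never interpolated, because
interpolation would bias every displacement-based statistic downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

logger = logging.getLogger("gliotrack")

TRACK_CSV_COLUMNS = ("track_id", "frame", "x_um", "y_um", "intensity")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """In-memory data violate a structural invariant."""


@dataclass(frozen=True)
class Localization:
    """A single detection: 0-based frame index and position in micrometres."""

    frame: int
    x: float
    y: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValidationError(f"frame must be >= 0, got {self.frame}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError("localization coordinates must be finite")


@dataclass
class Track:
    """An ordered sequence of localizations sharing one particle identity.

    ``frames`` are strictly increasing but need not be contiguous.
    Coordinates are micrometres.
    """

    id: str
    frames: np.ndarray
    xy: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.intensity is None:
            self.intensity = np.zeros(len(self.frames), dtype=np.float64)
        else:
            self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.frames.ndim != 1 or self.xy.shape != (len(self.frames), 2):
            raise ValidationError(
                f"track {self.id!r}: frames and xy shapes are inconsistent"
            )
        if len(self.frames) < 2:
            raise ValidationError(f"track {self.id!r}: needs >= 2 points")
        if np.any(self.frames < 0):
            raise ValidationError(f"track {self.id!r}: negative frame index")
        if np.any(np.diff(self.frames) <= 0):
            raise ValidationError(
                f"track {self.id!r}: frames must be strictly increasing"
            )
        if not np.all(np.isfinite(self.xy)):
            raise ValidationError(f"track {self.id!r}: non-finite coordinate")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def points(self) -> list[Localization]:
        return [
            Localization(int(f), float(x), float(y), float(i))
            for f, (x, y), i in zip(self.frames, self.xy, self.intensity)
        ]

    @classmethod
    def from_points(cls, id: str, points: Sequence[Localization]) -> "Track":
        pts = sorted(points, key=lambda p: p.frame)
        return cls(
            id=id,
            frames=np.array([p.frame for p in pts]),
            xy=np.array([[p.x, p.y] for p in pts]),
            intensity=np.array([p.intensity for p in pts]),
        )


@dataclass(frozen=True)
class Polygon:
    """A simple closed polygon in micrometres (implicitly closed)."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValidationError("polygon needs >= 3 vertices")

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        """Boundary-inclusive point-in-polygon test (even-odd rule)."""
        poly = self.to_shapely()
        pts = shapely.points(np.asarray(xy, dtype=float))
        return shapely.covers(poly, pts)


@dataclass
class TrackSet:
    """All tracks of one imaged cell plus acquisition metadata."""

    tracks: list[Track]
    frame_interval: float = 0.03
    pixel_size: float = 0.1
    cell_id: str = ""
    stage: str = ""
    roi: Polygon | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        ids = [t.id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise ValidationError("track ids must be unique within a TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


@dataclass
class FrameStack:
    """A T x H x W time-lapse of non-negative 16-bit intensities."""

    data: np.ndarray
    pixel_size: float = 0.1
    frame_interval: float = 0.03

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValidationError("stack must be T x H x W with T >= 1")
        if self.data.min() < 0 or self.data.max() > 65535:
            raise ValidationError("intensities must lie in [0, 65535]")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# CSV track I/O
# ---------------------------------------------------------------------------

def read_tracks_csv(
    path: str | Path,
    frame_interval: float = 0.03,
    pixel_size: float = 0.1,
    cell_id: str = "",
    stage: str = "",
) -> TrackSet:
    """Read a track table (``track_id,frame,x_um,y_um,intensity``).

    Rows are grouped by ``track_id`` and sorted by frame.  Rows with
    unparseable numeric fields are rejected with a logged warning; duplicated
    (track_id, frame) pairs raise :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"track_id": str})
    missing = [c for c in TRACK_CSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    if "intensity" not in df.columns:
        df["intensity"] = 0.0

    for col in ("frame", "x_um", "y_um", "intensity"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["frame", "x_um", "y_um"]].isna().any(axis=1)
    if bad.any():
        logger.warning("%s: rejected %d malformed row(s)", path.name, int(bad.sum()))
        df = df[~bad]

    if df.duplicated(subset=["track_id", "frame"]).any():
        raise ValidationError(f"{path.name}: duplicate (track_id, frame) pair")

    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        if len(g) < 2:
            logger.warning("%s: dropping single-point track %r", path.name, tid)
            continue
        tracks.append(
            Track(
                id=str(tid),
                frames=g["frame"].to_numpy(dtype=np.int64),
                xy=g[["x_um", "y_um"]].to_numpy(dtype=np.float64),
                intensity=g["intensity"].fillna(0.0).to_numpy(dtype=np.float64),
            )
        )
    return TrackSet(tracks, frame_interval, pixel_size, cell_id=cell_id, stage=stage)


def write_tracks_csv(trackset: TrackSet, path: str | Path) -> None:
    """Write a TrackSet as a track table; round-trips losslessly."""
    rows = []
    for t in trackset:
        for f, (x, y), i in zip(t.frames, t.xy, t.intensity):
            rows.append((t.id, int(f), float(x), float(y), float(i)))
    df = pd.DataFrame(rows, columns=list(TRACK_CSV_COLUMNS))
    df.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# TIFF stack I/O
# ---------------------------------------------------------------------------

def read_tiff_stack(
    path: str | Path,
    pixel_size: float = 0.1,
    frame_interval: float = 0.03,
) -> FrameStack:
    """Read a multipage grayscale TIFF as a FrameStack (one page per frame)."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various types on bad magic
        raise FormatError(f"{path.name}: not a readable TIFF ({exc})") from exc
    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:2]):
        raise FormatError(f"{path.name}: RGB(A) TIFF; grayscale required")
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim == 4:
        raise FormatError(f"{path.name}: RGB(A) TIFF; grayscale required")
    if data.ndim != 3:
        raise FormatError(f"{path.name}: expected 2D pages, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"{path.name}: expected integer pixel type, got {data.dtype}")
    return FrameStack(data, pixel_size=pixel_size, frame_interval=frame_interval)


def write_tiff_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a FrameStack as a multipage 16-bit grayscale TIFF."""
    tifffile.imwrite(Path(path), stack.data.astype(np.uint16), photometric="minisblack")


# ---------------------------------------------------------------------------
# ROI curation
# ---------------------------------------------------------------------------

def clip_to_roi(trackset: TrackSet, polygon: Polygon) -> TrackSet:
    """Keep only tracks whose every point lies inside or on the ROI boundary.

    This mirrors manual curation of tracks to the visible extent of the cell:
    a track with any excursion outside the region is discarded whole.
    """
    kept = [t for t in trackset if bool(polygon.contains_points(t.xy).all())]
    out = replace(trackset, tracks=kept)
    out.roi = polygon
    return out
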