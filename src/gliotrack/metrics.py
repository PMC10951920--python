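"""Per-track and per-cell motion statistics.

Three quantities summarize each tracked particle or cell:

* **Diffusion coefficient** ``D = mean_tau MSD(tau) / (q * tau)`` with the
  2D dimensionality constant ``q = 4``.  The time-averaged MSD uses every
  overlapping frame pair at each lag, and D averages the per-lag estimates
  over all lags available in the track, which controls the bias caused by
  variable track lengths at the cost of imprecision for non-Brownian tracks.
* **Confinement ratio** ``(d_net / d_tot) * t_track`` — net over total
  displacement, duration-corrected.  Because the literal duration product is
  debatable (it breaks the dimensionless [0, 1] interpretation), three modes
  are exposed: ``as_printed`` (x t_track in seconds, the default),
  ``sqrt_duration`` (x sqrt(t_track)) and ``plain`` (no correction).
* **Circularity** ``r_circ = 4*pi*A / p**2`` of the cell's motion-profile
  outline: every track re-plotted from a common origin, outline traced as
  the convex hull of the pooled displacement cloud, area by the shoelace
  formula, perimeter as summed edge lengths.  1 means an isotropic
  (circular) cloud, 0 a perfectly linear one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely import MultiPoint

from .io import Polygon, Track, TrackSet

logger = logging.getLogger("gliotrack")

__all__ = [
    "MSDCurve",
    "TrackMetrics",
    "MotionProfile",
    "VectorDiagram",
    "msd_curve",
    "diffusion_coefficient",
    "displacements",
    "confinement_ratio",
    "zero_origin",
    "motion_profile",
    "circularity",
    "polygon_area_perimeter",
    "direction_vectors",
    "track_metrics",
    "trackset_metrics",
    "CONFINEMENT_MODES",
]

CONFINEMENT_MODES = ("as_printed", "sqrt_duration", "plain")

# broadcasting a full pairwise displacement matrix is fastest for short
# tracks; beyond this length a per-lag loop avoids the quadratic memory
_PAIRWISE_MAX_LEN = 400


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged mean squared displacement per lag time."""

    lags: np.ndarray  # seconds
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray  # displacement pairs contributing per lag


@dataclass(frozen=True)
class TrackMetrics:
    track_id: str
    D: float  # um^2/s
    d_net: float  # um
    d_tot: float  # um
    t_track: float  # s
    confinement: float
    confinement_mode: str
    n_points: int


@dataclass(frozen=True)
class MotionProfile:
    """Origin-zeroed displacement cloud of one cell with its traced outline."""

    cell_id: str
    zeroed_points: np.ndarray  # (n, 2) um
    outline: Polygon | None  # None when the cloud is degenerate (collinear)
    area: float  # um^2
    perimeter: float  # um
    r_circ: float


@dataclass(frozen=True)
class VectorDiagram:
    n_sectors: int
    sector_mass: np.ndarray  # fractions, sum to 1
    n_tracks: int
    n_zero_net: int  # tracks excluded for zero net displacement


# ---------------------------------------------------------------------------
# MSD and diffusion
# ---------------------------------------------------------------------------

def msd_curve(track: Track, frame_interval: float) -> MSDCurve:
    """Time-averaged MSD over all overlapping frame pairs at each lag.

    Gaps are respected: a pair only contributes when both frames exist, so a
    track with frames {0, 1, 3} has one pair each at lags 1, 2 and 3.
    """
    f = track.frames
    xy = track.xy
    n = len(f)
    span = int(f[-1] - f[0])
    sums = np.zeros(span + 1)
    counts = np.zeros(span + 1, dtype=np.int64)

    if n <= _PAIRWISE_MAX_LEN:
        iu, ju = np.triu_indices(n, k=1)
        lag = (f[ju] - f[iu]).astype(np.int64)
        sq = ((xy[ju] - xy[iu]) ** 2).sum(axis=1)
        np.add.at(sums, lag, sq)
        np.add.at(counts, lag, 1)
    else:
        # dense frame grid with NaN holes, then one vector op per lag
        grid = np.full((span + 1, 2), np.nan)
        grid[f - f[0]] = xy
        for k in range(1, span + 1):
            d = grid[k:] - grid[:-k]
            sq = (d**2).sum(axis=1)
            ok = ~np.isnan(sq)
            counts[k] = int(ok.sum())
            if counts[k]:
                sums[k] = float(sq[ok].sum())

    have = np.nonzero(counts)[0]
    have = have[have >= 1]
    return MSDCurve(
        lags=have * frame_interval,
        msd=sums[have] / counts[have],
        n_pairs=counts[have],
    )


def diffusion_coefficient(curve: MSDCurve, q: float = 4.0, max_lag: float | None = None) -> float:
    """Per-track D: unweighted mean of MSD(tau)/(q*tau) over available lags.

    ``q = 4`` is the 2D dimensionality constant.  ``max_lag`` (seconds)
    optionally truncates noisy long lags; by default every lag enters.
    """
    lags, msd = curve.lags, curve.msd
    if max_lag is not None:
        keep = lags <= max_lag
        lags, msd = lags[keep], msd[keep]
    if len(lags) == 0:
        raise ValueError("diffusion_coefficient needs at least one lag")
    return float(np.mean(msd / (q * lags)))


# ---------------------------------------------------------------------------
# displacement statistics
# ---------------------------------------------------------------------------

def displacements(track: Track, frame_interval: float) -> tuple[float, float, float]:
    """(d_net, d_tot, t_track): net start-to-end distance, summed path length
    (gap segments measured as single straight segments), and duration."""
    xy = track.xy
    d_net = float(np.hypot(*(xy[-1] - xy[0])))
    steps = np.diff(xy, axis=0)
    d_tot = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    t_track = float((track.frames[-1] - track.frames[0]) * frame_interval)
    return d_net, d_tot, t_track


def confinement_ratio(
    d_net: float, d_tot: float, t_track: float, mode: str = "as_printed"
) -> float:
    """Duration-corrected net-over-total displacement ratio.

    A fully stationary path (d_tot = 0) is defined as maximally confined
    (ratio 0) with a logged warning rather than an error.
    """
    if mode not in CONFINEMENT_MODES:
        raise ValueError(f"unknown confinement mode {mode!r}")
    if d_tot <= 0:
        logger.warning("confinement_ratio: stationary track (d_tot = 0) -> 0")
        return 0.0
    base = d_net / d_tot
    if mode == "as_printed":
        return base * t_track
    if mode == "sqrt_duration":
        return base * math.sqrt(t_track)
    return base


# ---------------------------------------------------------------------------
# motion profiles and circularity
# ---------------------------------------------------------------------------

def zero_origin(track: Track) -> np.ndarray:
    """Displacement sequence relative to the track's first point."""
    return track.xy - track.xy[0]


def polygon_area_perimeter(vertices: np.ndarray) -> tuple[float, float]:
    """Shoelace area and summed edge lengths of a closed polygon."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    edges = np.diff(np.vstack([v, v[:1]]), axis=0)
    perimeter = float(np.hypot(edges[:, 0], edges[:, 1]).sum())
    return float(area), perimeter


def circularity(area: float, perimeter: float) -> float:
    """``4*pi*A / p**2``, clipped to [0, 1] only for float overshoot."""
    if perimeter <= 0:
        raise ValueError("circularity needs perimeter > 0")
    if area < 0:
        raise ValueError("circularity needs area >= 0")
    r = 4.0 * math.pi * area / perimeter**2
    if 1.0 < r <= 1.0 + 1e-9:
        r = 1.0
    return r


def motion_profile(trackset: TrackSet) -> MotionProfile:
    """One motion profile per cell: pooled zeroed points + hull circularity.

    The outline is the convex hull of the pooled displacement cloud —
    deterministic and parameter-free; note it biases r_circ upward for
    concave clouds.  An all-collinear cloud yields area 0 and r_circ 0.
    """
    if len(trackset) == 0:
        raise ValueError("motion_profile needs at least one track")
    pts = np.vstack([zero_origin(t) for t in trackset])
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":
        # collinear or single-point cloud: zero area, linear by definition
        return MotionProfile(trackset.cell_id, pts, None, 0.0, 0.0, 0.0)
    verts = np.asarray(hull.exterior.coords)[:-1]
    area, perim = polygon_area_perimeter(verts)
    return MotionProfile(
        cell_id=trackset.cell_id,
        zeroed_points=pts,
        outline=Polygon(tuple(map(tuple, verts))),
        area=area,
        perimeter=perim,
        r_circ=circularity(area, perim),
    )


def direction_vectors(trackset: TrackSet, n_sectors: int = 8) -> VectorDiagram:
    """Angular distribution of net-displacement vectors.

    Sector 0 is centred on the +x axis; tracks with zero net displacement
    carry no direction and are excluded (but counted).
    """
    vecs = np.array([t.xy[-1] - t.xy[0] for t in trackset])
    norms = np.hypot(vecs[:, 0], vecs[:, 1])
    nz = norms > 0
    n_zero = int((~nz).sum())
    angles = np.arctan2(vecs[nz, 1], vecs[nz, 0])
    width = 2.0 * np.pi / n_sectors
    idx = np.floor((angles + width / 2.0) / width).astype(int) % n_sectors
    mass = np.bincount(idx, minlength=n_sectors).astype(float)
    total = mass.sum()
    if total == 0:
        raise ValueError("direction_vectors needs >= 1 track with d_net > 0")
    return VectorDiagram(n_sectors, mass / total, n_tracks=len(trackset), n_zero_net=n_zero)


# ---------------------------------------------------------------------------
# per-track convenience
# ---------------------------------------------------------------------------

def track_metrics(
    track: Track,
    frame_interval: float,
    q: float = 4.0,
    confinement_mode: str = "as_printed",
    max_lag: float | None = None,
) -> TrackMetrics:
    curve = msd_curve(track, frame_interval)
    d = diffusion_coefficient(curve, q=q, max_lag=max_lag)
    d_net, d_tot, t_track = displacements(track, frame_interval)
    return TrackMetrics(
        track_id=track.id,
        D=d,
        d_net=d_net,
        d_tot=d_tot,
        t_track=t_track,
        confinement=confinement_ratio(d_net, d_tot, t_track, confinement_mode),
        confinement_mode=confinement_mode,
        n_points=len(track),
    )


def trackset_metrics(
    trackset: TrackSet,
    q: float = 4.0,
    confinement_mode: str = "as_printed",
    max_lag: float | None = None,
):
    """Per-track metrics table for a cell, as a pandas DataFrame."""
    import pandas as pd

    rows = [
        track_metrics(t, trackset.frame_interval, q, confinement_mode, max_lag)
        for t in trackset
    ]
    return pd.DataFrame(
        {
            "track_id": [r.track_id for r in rows],
            "D": [r.D for r in rows],
            "d_net": [r.d_net for r in rows],
            "d_tot": [r.d_tot for r in rows],
            "t_track": [r.t_track for r in rows],
            "confinement": [r.confinement for r in rows],
            "n_points": [r.n_points for r in rows],
            "cell_id": trackset.cell_id,
            "stage": trackset.stage,
        }
    )
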