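"""Spot detection, greedy nearest-neighbour linking and track filtering.

The detection front-end expects sparse, bright, roughly 3-pixel-diameter
spots on a dark background.  Detection is LoG-style: a difference-of-Gaussian
band-pass at the spot scale, local maxima gated by a robust intensity
threshold (median + k * 1.4826*MAD of the raw frame), then optional subpixel
refinement by per-axis Gaussian (log-parabola) interpolation, which is exact
for Gaussian spots and avoids the shrinkage bias of windowed centroids.

Linking is a deterministic greedy frame-to-frame assignment: candidate
(track-end, detection) pairs are sorted by distance (ties broken by detection
index) and accepted while both partners are unused and the displacement is
within ``max_disp_px``; unmatched track ends stay alive for ``max_gap``
frames, producing gap-closed tracks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import Localization, Polygon, Track, TrackSet, ValidationError, clip_to_roi

logger = logging.getLogger("gliotrack")

__all__ = [
    "DetectionParams",
    "LinkParams",
    "PrecisionEstimate",
    "detect_spots",
    "detect_stack",
    "link_spots",
    "filter_tracks",
    "estimate_precision",
]


@dataclass(frozen=True)
class DetectionParams:
    spot_diameter_px: float = 3.0
    threshold_factor: float = 5.0
    subpixel: bool = True

    def __post_init__(self) -> None:
        if self.spot_diameter_px < 1:
            raise ValueError("spot_diameter_px must be >= 1")


@dataclass(frozen=True)
class LinkParams:
    max_disp_px: float = 3.0
    max_gap: int = 1
    min_frames: int = 10

    def __post_init__(self) -> None:
        if self.max_disp_px <= 0:
            raise ValueError("max_disp_px must be > 0")
        if self.max_gap < 0 or self.min_frames < 2:
            raise ValueError("need max_gap >= 0 and min_frames >= 2")


@dataclass(frozen=True)
class PrecisionEstimate:
    """Per-axis localization precision, mean (+/- SD) across particles, nm."""

    mean_sd_x: float
    mean_sd_y: float
    sd_of_sd_x: float
    sd_of_sd_y: float
    n_particles: int


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_spots(frame: np.ndarray, params: DetectionParams | None = None) -> list[Localization]:
    """Detect spots in one 2D frame; coordinates returned in pixels.

    Deterministic.  An empty list is a valid result (blank frame).
    """
    params = params or DetectionParams()
    img = np.asarray(frame, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a single 2D frame")

    sigma = params.spot_diameter_px / 2.355  # FWHM -> Gaussian sd
    bandpass = ndimage.gaussian_filter(img, sigma) - ndimage.gaussian_filter(img, 2.0 * sigma)

    background = float(np.median(img))
    mad = float(np.median(np.abs(img - background)))
    robust_sd = 1.4826 * mad
    intensity_gate = background + params.threshold_factor * robust_sd

    # strict local maxima of the band-passed image
    footprint = np.ones((3, 3), dtype=bool)
    local_max = bandpass == ndimage.maximum_filter(bandpass, footprint=footprint)
    candidates = local_max & (img > intensity_gate) & (bandpass > 0)
    ys, xs = np.nonzero(candidates)

    out: list[Localization] = []
    h, w = img.shape
    for y, x in zip(ys, xs):
        if params.subpixel:
            xc, yc = _subpixel_refine(img, int(y), int(x), background)
        else:
            xc, yc = float(x), float(y)
        out.append(Localization(frame=0, x=xc, y=yc, intensity=float(img[y, x] - background)))
    out.sort(key=lambda p: (p.y, p.x))
    return out


def _subpixel_refine(img: np.ndarray, y: int, x: int, background: float) -> tuple[float, float]:
    """Gaussian (log-parabola) interpolation of a maximum, per axis.

    Exact for a Gaussian spot sampled on the pixel grid; falls back to the
    integer maximum at image borders or when the 3-point stencil is not
    concave (e.g. flat or corrupted neighbourhoods).
    """
    h, w = img.shape
    if not (1 <= y < h - 1 and 1 <= x < w - 1):
        return float(x), float(y)

    def offset(a: float, b: float, c: float) -> float:
        a, b, c = (max(v - background, 1e-3) for v in (a, b, c))
        la, lb, lc = math.log(a), math.log(b), math.log(c)
        denom = la - 2.0 * lb + lc
        if denom >= 0:
            return 0.0
        return float(np.clip(0.5 * (la - lc) / denom, -1.0, 1.0))

    dx = offset(img[y, x - 1], img[y, x], img[y, x + 1])
    dy = offset(img[y - 1, x], img[y, x], img[y + 1, x])
    return x + dx, y + dy


def detect_stack(stack, params: DetectionParams | None = None) -> list[list[Localization]]:
    """Run detect_spots on every frame; localizations carry their frame index."""
    per_frame = []
    for fi in range(stack.n_frames):
        dets = detect_spots(stack.data[fi], params)
        per_frame.append([replace(d, frame=fi) for d in dets])
    return per_frame


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_spots(
    detections: list[list[Localization]],
    params: LinkParams | None = None,
    frame_interval: float = 0.03,
    pixel_size: float = 0.1,
) -> TrackSet:
    """Greedy nearest-neighbour linking of per-frame detections into tracks.

    ``detections`` is a list ordered by frame (index = frame number), each a
    list of pixel-coordinate localizations.  Output coordinates are converted
    to micrometres with ``pixel_size``.  Tracks shorter than 2 points are
    discarded (a single unlinked detection is not a trajectory).
    """
    params = params or LinkParams()
    active: list[dict] = []  # {'points': [...], 'last': Localization}
    finished: list[list[Localization]] = []

    for fi, dets in enumerate(detections):
        # retire tracks whose last detection is too old to bridge
        still = []
        for tr in active:
            if fi - tr["points"][-1].frame > params.max_gap + 1:
                finished.append(tr["points"])
            else:
                still.append(tr)
        active = still

        pairs = []
        for ti, tr in enumerate(active):
            last = tr["points"][-1]
            for di, d in enumerate(dets):
                dist = math.hypot(d.x - last.x, d.y - last.y)
                if dist <= params.max_disp_px:
                    pairs.append((dist, di, ti))
        pairs.sort()
        used_d: set[int] = set()
        used_t: set[int] = set()
        for dist, di, ti in pairs:
            if di in used_d or ti in used_t:
                continue
            used_d.add(di)
            used_t.add(ti)
            active[ti]["points"].append(replace(dets[di], frame=fi))
        for di, d in enumerate(dets):
            if di not in used_d:
                active.append({"points": [replace(d, frame=fi)]})

    finished.extend(tr["points"] for tr in active)
    finished.sort(key=lambda pts: (pts[0].frame, pts[0].y, pts[0].x))

    tracks = []
    for i, pts in enumerate(finished):
        if len(pts) < 2:
            continue
        tracks.append(
            Track(
                id=f"t{i:05d}",
                frames=np.array([p.frame for p in pts]),
                xy=np.array([[p.x, p.y] for p in pts]) * pixel_size,
                intensity=np.array([p.intensity for p in pts]),
            )
        )
    return TrackSet(tracks, frame_interval=frame_interval, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_tracks(
    trackset: TrackSet,
    params: LinkParams | None = None,
    roi: Polygon | None = None,
) -> TrackSet:
    """Remove exceptionally short tracks, then optionally clip to an ROI.

    A track survives the length filter when it holds at least ``min_frames``
    localizations (the count of detected frames, not the frame span; the
    boundary is inclusive, so 10-point tracks survive a 10-frame cut).
    """
    params = params or LinkParams()
    n0 = len(trackset)
    kept = [t for t in trackset if len(t) >= params.min_frames]
    n_short = n0 - len(kept)
    out = replace(trackset, tracks=kept)
    n_roi = 0
    if roi is not None:
        before = len(out)
        out = clip_to_roi(out, roi)
        n_roi = before - len(out)
    logger.info(
        "filter_tracks: %d in, %d removed short (<%d), %d removed by ROI, %d kept",
        n0, n_short, params.min_frames, n_roi, len(out),
    )
    return out


# ---------------------------------------------------------------------------
# localization precision
# ---------------------------------------------------------------------------

def estimate_precision(stationary_trackset: TrackSet) -> PrecisionEstimate:
    """Tracking precision from repeated localizations of stationary emitters.

    For each particle (track) the sample SD of x and of y across frames is
    computed; the estimate reports the mean and SD of these per-axis values
    across particles, in nanometres — the conventional mean (+/- SD) format.
    Tracks with fewer than 3 localizations are ignored.
    """
    sds = []
    for t in stationary_trackset:
        if len(t) < 3:
            continue
        sds.append([t.xy[:, 0].std(ddof=1), t.xy[:, 1].std(ddof=1)])
    if not sds:
        raise ValidationError("estimate_precision needs >= 1 track with >= 3 points")
    sds_nm = np.asarray(sds) * 1000.0
    n = len(sds_nm)
    spread = sds_nm.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
    return PrecisionEstimate(
        mean_sd_x=float(sds_nm[:, 0].mean()),
        mean_sd_y=float(sds_nm[:, 1].mean()),
        sd_of_sd_x=float(spread[0]),
        sd_of_sd_y=float(spread[1]),
        n_particles=n,
    )
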