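"""Synthetic trajectory populations and synthetic single-molecule movies.

The generator emulates sparse photoswitched-emitter tracking at a 30 ms frame
interval in three cell geometries: a narrow process (rectangle), a small
membrane bubble (small disc) and a large membrane sheet (large disc).  Each
track follows one of three motion models:

``brownian``
    isotropic 2D diffusion — per-axis step ~ Normal(0, sqrt(2*D*dt));
``directed``
    diffusion plus a constant drift velocity;
``confined``
    diffusion inside a reflecting circular corral centred on the track's
    starting point.

Track lengths are geometric (memoryless photobleaching) truncated to
[2, max_frames].  Localization error is modelled at the trajectory level as
independent Normal(0, sigma) noise per axis per frame; the camera model
(Poisson shot noise + Gaussian read noise) is applied separately at render
time so that trajectory-level analyses can bypass imaging entirely.

Stage presets (OPC / eOL / mOL) are motion-mixture fixtures chosen to
reproduce the qualitative developmental orderings this kind of experiment
reports — progressive loss of isotropy, lowest confinement in early
myelinating cells, and a fast-diffusive subpopulation present in precursors
and mature sheets but absent at the early myelinating stage.  They are not
estimates of real per-stage motion parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import FrameStack, Track, TrackSet, ValidationError

__all__ = [
    "MotionModel",
    "Geometry",
    "SimulationConfig",
    "PSFModel",
    "simulate_tracks",
    "stage_preset",
    "render_movie",
    "make_stationary_stack",
    "STAGES",
]

STAGES = ("OPC", "eOL", "mOL")


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class MotionModel:
    """One motion class of the mixture; D in um^2/s, drift in um/s."""

    kind: str  # brownian | confined | directed
    D: float = 0.0
    drift: tuple[float, float] = (0.0, 0.0)
    corral_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("brownian", "confined", "directed"):
            raise ConfigError(f"unknown motion kind {self.kind!r}")
        if self.D < 0:
            raise ConfigError("D must be >= 0")
        if self.kind == "confined" and self.corral_radius <= 0:
            raise ConfigError("confined motion requires corral_radius > 0")


@dataclass(frozen=True)
class Geometry:
    """Reflecting cell-region boundary: 'process' rectangle or disc."""

    kind: str  # process | bubble | sheet
    width: float = 0.0  # rectangle only, um
    length: float = 0.0  # rectangle only, um
    radius: float = 0.0  # disc only, um

    def __post_init__(self) -> None:
        if self.kind == "process":
            if self.width <= 0 or self.length <= 0:
                raise ConfigError("process geometry needs width > 0 and length > 0")
        elif self.kind in ("bubble", "sheet"):
            if self.radius <= 0:
                raise ConfigError(f"{self.kind} geometry needs radius > 0")
        else:
            raise ConfigError(f"unknown geometry kind {self.kind!r}")


@dataclass
class SimulationConfig:
    mixture: list[tuple[MotionModel, float]]
    geometry: Geometry
    localization_sigma: float = 0.02  # um per axis
    bleach_prob: float = 0.03  # per-frame termination probability
    n_tracks: int = 1300
    frame_interval: float = 0.03  # s
    max_frames: int = 2500
    pixel_size: float = 0.1  # um/px, used when rendering
    seed: int = 0
    stage: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        fracs = [f for _, f in self.mixture]
        if abs(sum(fracs) - 1.0) > 1e-9 or any(f < 0 for f in fracs):
            raise ConfigError("mixture fractions must be >= 0 and sum to 1")
        if not (0.0 <= self.bleach_prob <= 1.0):
            raise ConfigError("bleach_prob must lie in [0, 1]")
        if self.localization_sigma < 0:
            raise ConfigError("localization_sigma must be >= 0")
        if self.n_tracks < 1 or self.max_frames < 2:
            raise ConfigError("need n_tracks >= 1 and max_frames >= 2")


@dataclass(frozen=True)
class PSFModel:
    """Gaussian point-spread function and camera noise model (counts)."""

    sigma_px: float = 3.0 / 2.355  # FWHM of 3 px, the expected spot size
    amplitude: float = 2000.0
    background: float = 100.0
    read_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ConfigError("sigma_px must be > 0")


# ---------------------------------------------------------------------------
# geometry helpers: reflecting boundaries
# ---------------------------------------------------------------------------

def _fold(value: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (triangle-wave fold, handles any excursion)."""
    span = hi - lo
    v = np.mod(value - lo, 2.0 * span)
    v = np.where(v > span, 2.0 * span - v, v)
    return v + lo

def _reflect_disc(xy: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    d = xy - center
    r = np.hypot(d[..., 0], d[..., 1])
    r_f = _fold(r, 0.0, radius)
    scale = np.where(r > 0, r_f / np.where(r > 0, r, 1.0), 1.0)
    return center + d * scale[..., None]

def _reflect_geometry(xy: np.ndarray, geom: Geometry) -> np.ndarray:
    if geom.kind == "process":
        out = xy.copy()
        out[..., 0] = _fold(xy[..., 0], 0.0, geom.length)
        out[..., 1] = _fold(xy[..., 1], 0.0, geom.width)
        return out
    return _reflect_disc(xy, np.zeros(2), geom.radius)

def _uniform_start(geom: Geometry, rng: np.random.Generator) -> np.ndarray:
    if geom.kind == "process":
        return rng.uniform([0.0, 0.0], [geom.length, geom.width])
    while True:  # rejection sampling in the disc
        p = rng.uniform(-geom.radius, geom.radius, size=2)
        if p @ p <= geom.radius**2:
            return p


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _simulate_one(
    model: MotionModel,
    n_frames: int,
    dt: float,
    geom: Geometry,
    rng: np.random.Generator,
) -> np.ndarray:
    start = _uniform_start(geom, rng)
    step_sd = math.sqrt(2.0 * model.D * dt)
    steps = rng.normal(0.0, step_sd, size=(n_frames - 1, 2)) if step_sd > 0 else np.zeros((n_frames - 1, 2))
    if model.kind == "directed":
        steps = steps + np.asarray(model.drift) * dt

    if model.kind == "confined":
        # corral reflection is path-dependent: integrate frame by frame
        pos = np.empty((n_frames, 2))
        pos[0] = start
        for i in range(1, n_frames):
            p = pos[i - 1] + steps[i - 1]
            p = _reflect_disc(p, start, model.corral_radius)
            pos[i] = p
        pos = _reflect_geometry(pos, geom)
        pos[0] = start  # start is inside by construction
        return pos

    pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
    # reflecting cell boundary via path folding: exact for axis-aligned
    # walls, and a good approximation for the disc when steps << radius
    return _reflect_geometry(pos, geom)


def simulate_tracks(config: SimulationConfig) -> TrackSet:
    """Draw a full track population from the configured mixture.

    Fully reproducible: the same config (including seed) yields the same
    TrackSet, and writing it to CSV is byte-stable.
    """
    rng = np.random.default_rng(config.seed)
    models = [m for m, _ in config.mixture]
    fracs = np.array([f for _, f in config.mixture])
    dt = config.frame_interval

    tracks: list[Track] = []
    for i in range(config.n_tracks):
        midx = rng.choice(len(models), p=fracs / fracs.sum())
        model = models[midx]
        if config.bleach_prob > 0:
            length = int(rng.geometric(config.bleach_prob))
        else:
            length = config.max_frames
        length = min(max(length, 2), config.max_frames)
        start_frame = int(rng.integers(0, max(config.max_frames - length, 0) + 1))
        xy = _simulate_one(model, length, dt, config.geometry, rng)
        if config.localization_sigma > 0:
            xy = xy + rng.normal(0.0, config.localization_sigma, size=xy.shape)
        tracks.append(
            Track(
                id=f"t{i:05d}",
                frames=np.arange(start_frame, start_frame + length),
                xy=xy,
            )
        )
    return TrackSet(
        tracks,
        frame_interval=dt,
        pixel_size=config.pixel_size,
        cell_id=config.cell_id,
        stage=config.stage,
    )


# ---------------------------------------------------------------------------
# stage presets
# ---------------------------------------------------------------------------

# Mixture fixtures per developmental stage.  D in um^2/s.  The directed
# components of one simulated cell share a drift axis drawn from the cell's
# seed, which is what elongates the cell's pooled motion profile.
_FAST_D = 0.05

def _preset_mixture(stage: str, drift_dir: np.ndarray) -> list[tuple[MotionModel, float]]:
    if stage == "OPC":
        return [
            (MotionModel("brownian", D=0.001), 0.50),
            (MotionModel("brownian", D=0.004), 0.28),
            (MotionModel("brownian", D=0.012), 0.15),
            (MotionModel("brownian", D=_FAST_D), 0.07),
        ]
    if stage == "eOL":
        return [
            (MotionModel("brownian", D=0.004), 0.35),
            (MotionModel("brownian", D=0.008), 0.35),
            (MotionModel("directed", D=0.003, drift=tuple(0.24 * drift_dir)), 0.30),
        ]
    if stage == "mOL":
        return [
            (MotionModel("confined", D=0.005, corral_radius=0.05), 0.60),
            (MotionModel("directed", D=0.0015, drift=tuple(2.0 * drift_dir)), 0.28),
            (MotionModel("brownian", D=_FAST_D), 0.12),
        ]
    raise ConfigError(f"unknown stage {stage!r}; expected one of {STAGES}")


def stage_preset(stage: str, n_tracks: int = 1300, seed: int = 0) -> SimulationConfig:
    """Simulation config for one cell at a developmental stage.

    OPC: isotropic Brownian mixture including a small fast fraction in a
    narrow rectangular process.  eOL: fast fraction removed, a directed
    component raising net displacement (mildly reduced confinement), small
    disc.  mOL: strongly confined majority plus a directed fraction and a
    re-introduced fast fraction, large disc.
    """
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; expected one of {STAGES}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, STAGES.index(stage)]))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    drift_dir = np.array([np.cos(theta), np.sin(theta)])
    geometry = {
        "OPC": Geometry("process", width=2.0, length=10.0),
        "eOL": Geometry("bubble", radius=2.0),
        "mOL": Geometry("sheet", radius=8.0),
    }[stage]
    return SimulationConfig(
        mixture=_preset_mixture(stage, drift_dir),
        geometry=geometry,
        n_tracks=n_tracks,
        seed=seed,
        stage=stage,
    )


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

def _render_spot(img: np.ndarray, x_px: float, y_px: float, psf: PSFModel) -> None:
    """Add one Gaussian spot in-place (local window, +-4 sigma)."""
    h, w = img.shape
    half = int(math.ceil(4.0 * psf.sigma_px))
    cx, cy = int(round(x_px)), int(round(y_px))
    x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    g = psf.amplitude * np.exp(
        -((xs - x_px) ** 2 + (ys - y_px) ** 2) / (2.0 * psf.sigma_px**2)
    )
    img[y0:y1, x0:x1] += g


def render_movie(
    trackset: TrackSet,
    psf: PSFModel,
    shape: tuple[int, int],
    seed: int = 0,
    noise: bool = True,
) -> FrameStack:
    """Render a TrackSet into a synthetic camera movie.

    Each localization becomes a 2D Gaussian of sd ``psf.sigma_px`` on a flat
    background; Poisson shot noise is applied to signal+background and
    Gaussian read noise added, clipped to the 16-bit range.  ``noise=False``
    yields the noiseless expectation image (useful for ground-truth tests).
    """
    h, w = shape
    px = trackset.pixel_size
    for t in trackset:
        xpx, ypx = t.xy[:, 0] / px, t.xy[:, 1] / px
        if np.any((xpx < 0) | (xpx > w - 1) | (ypx < 0) | (ypx > h - 1)):
            raise ValidationError(f"track {t.id!r} has points outside the image")

    n_frames = 1 + max((int(t.frames.max()) for t in trackset), default=0)
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, h, w), dtype=np.uint16)
    by_frame: dict[int, list[tuple[float, float]]] = {}
    for t in trackset:
        for f, (x, y) in zip(t.frames, t.xy):
            by_frame.setdefault(int(f), []).append((x / px, y / px))

    for fi in range(n_frames):
        img = np.full((h, w), float(psf.background))
        for x_px, y_px in by_frame.get(fi, ()):
            _render_spot(img, x_px, y_px, psf)
        if noise:
            img = rng.poisson(img).astype(float)
            if psf.read_noise_sd > 0:
                img = img + rng.normal(0.0, psf.read_noise_sd, size=img.shape)
        frames[fi] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return FrameStack(frames, pixel_size=px, frame_interval=trackset.frame_interval)


def make_stationary_stack(
    n_particles: int,
    sigma_nm: float,
    n_frames: int = 20,
    psf: PSFModel | None = None,
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 0.1,
    seed: int = 0,
    noise: bool = True,
) -> tuple[FrameStack, np.ndarray]:
    """Movie of stationary emitters for localization-precision estimation.

    True positions are fixed; the apparent position of each particle is
    jittered per frame by Normal(0, sigma_nm) per axis before rendering,
    mimicking the apparent wobble of immobilized beads.  Returns the stack
    and the true positions (um, shape (n_particles, 2)).
    """
    if n_particles < 1:
        raise ConfigError("n_particles must be >= 1")
    psf = psf or PSFModel()
    rng = np.random.default_rng(seed)
    h, w = shape
    margin_px = 8
    min_sep_px = 6.0 * psf.sigma_px  # calibration beads are chosen isolated
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_particles:
        p = rng.uniform(
            [margin_px, margin_px], [w - 1 - margin_px, h - 1 - margin_px]
        )
        if all(np.hypot(*(p - q)) >= min_sep_px for q in placed):
            placed.append(p)
        attempts += 1
        if attempts > 1000 * n_particles:
            raise ConfigError("cannot place particles at the required sparsity")
    truth_px = np.asarray(placed)
    truth_um = truth_px * pixel_size
    sigma_um = sigma_nm / 1000.0
    tracks = []
    for i, (x, y) in enumerate(truth_um):
        jitter = (
            rng.normal(0.0, sigma_um, size=(n_frames, 2)) if sigma_um > 0 else np.zeros((n_frames, 2))
        )
        tracks.append(
            Track(id=f"p{i:04d}", frames=np.arange(n_frames), xy=np.array([x, y]) + jitter)
        )
    ts = TrackSet(tracks, frame_interval=0.03, pixel_size=pixel_size)
    stack = render_movie(ts, psf, shape, seed=seed + 1, noise=noise)
    return stack, truth_um
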