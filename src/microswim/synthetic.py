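"""Ground-truthed synthetic scenes of swimming, sedimenting and adherent cells.

The generator emulates the population structure the analysis pipelines
assume in free-swimming motility recordings of microalgae:

* **swimmers** — ballistic cells moving at a roughly constant individual
  speed whose heading diffuses by a per-frame Gaussian perturbation;
  headings can be isotropic, fixed, or concentrated around a preferred
  direction (von Mises), emulating phototactic alignment.
* **sedimenters** — non-motile cells sinking at a uniform speed straight
  down (heading 180°, no heading diffusion).
* **adherent** — stationary cells stuck to the chamber surface.

An optional uniform bulk drift is added to every particle, emulating
fluid motion the pipelines must correct for. Cells are rendered as
anti-aliased bright disks on a darker noisy background and quantised to
8-bit, which is what the segmentation and optical-flow stages see from a
real monochrome camera.

Positions wrap toroidally at the frame borders so the population density
stays constant, mimicking cells entering and leaving the field of view;
wrap events are marked in the ground truth so trajectory statistics can
be computed on the continuous (unwrapped) paths.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .angles import DOWN_DEG, vector_from_heading
from .optics import CalibrationState
from .sequence import FrameSequence

__all__ = [
    "ParticlePopulation",
    "SceneConfig",
    "GroundTruth",
    "simulate_tracks",
    "render_frames",
    "write_fixture",
    "load_fixture",
]

_KINDS = ("swimmer", "sedimenter", "adherent")


@dataclass
class ParticlePopulation:
    """One homogeneous group of particles in a scene.

    ``heading_mode`` is ``"isotropic"``, ``("fixed", theta_deg)`` or
    ``("biased", theta_deg, kappa)`` (von Mises concentration ``kappa``).
    Sedimenters are forced to a fixed straight-down heading with no
    heading diffusion; adherent cells are forced to zero speed.
    """

    kind: str
    count: int
    speed_um_s: float = 0.0
    speed_sd_um_s: float = 0.0
    heading_mode: str | tuple = "isotropic"
    turn_sd_deg_per_frame: float = 0.0
    radius_um: float = 4.0
    intensity: float = 0.6

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.speed_sd_um_s < 0 or self.turn_sd_deg_per_frame < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")
        if self.kind == "adherent":
            self.speed_um_s = 0.0
            self.speed_sd_um_s = 0.0
        if self.kind == "sedimenter":
            self.heading_mode = ("fixed", DOWN_DEG)
            self.turn_sd_deg_per_frame = 0.0


@dataclass
class SceneConfig:
    """Full description of a synthetic recording, including the RNG seed."""

    populations: list[ParticlePopulation]
    n_frames: int
    calibration: CalibrationState
    drift_um_per_frame: tuple[float, float] = (0.0, 0.0)
    background_level: float = 0.2
    noise_sd: float = 0.02
    seed: int = 0
    #: optional per-frame multiplier applied to every particle's own speed
    #: (not to drift); used to impose stimulus-coupled behaviour such as a
    #: photoshock swimming pause. Length must equal ``n_frames``.
    speed_factor_per_frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.speed_factor_per_frame is not None:
            self.speed_factor_per_frame = np.asarray(
                self.speed_factor_per_frame, dtype=float
            )
            if self.speed_factor_per_frame.shape != (self.n_frames,):
                raise ValueError("speed_factor_per_frame must have length n_frames")

    @property
    def n_particles(self) -> int:
        return sum(p.count for p in self.populations)

    def to_dict(self) -> dict:
        d = {
            "populations": [
                {
                    "kind": p.kind,
                    "count": p.count,
                    "speed_um_s": p.speed_um_s,
                    "speed_sd_um_s": p.speed_sd_um_s,
                    "heading_mode": list(p.heading_mode)
                    if isinstance(p.heading_mode, tuple)
                    else p.heading_mode,
                    "turn_sd_deg_per_frame": p.turn_sd_deg_per_frame,
                    "radius_um": p.radius_um,
                    "intensity": p.intensity,
                }
                for p in self.populations
            ],
            "n_frames": self.n_frames,
            "calibration": {
                "um_per_px": self.calibration.um_per_px,
                "frame_rate": self.calibration.frame_rate,
                "frame_width_px": self.calibration.frame_width_px,
                "frame_height_px": self.calibration.frame_height_px,
            },
            "drift_um_per_frame": list(self.drift_um_per_frame),
            "background_level": self.background_level,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        if self.speed_factor_per_frame is not None:
            d["speed_factor_per_frame"] = self.speed_factor_per_frame.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        known = {
            "populations", "n_frames", "calibration", "drift_um_per_frame",
            "background_level", "noise_sd", "seed", "speed_factor_per_frame",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scene config keys: {sorted(unknown)}")
        pops = [
            ParticlePopulation(
                kind=p["kind"],
                count=p["count"],
                speed_um_s=p.get("speed_um_s", 0.0),
                speed_sd_um_s=p.get("speed_sd_um_s", 0.0),
                heading_mode=tuple(p["heading_mode"])
                if isinstance(p.get("heading_mode"), list)
                else p.get("heading_mode", "isotropic"),
                turn_sd_deg_per_frame=p.get("turn_sd_deg_per_frame", 0.0),
                radius_um=p.get("radius_um", 4.0),
                intensity=p.get("intensity", 0.6),
            )
            for p in d["populations"]
        ]
        cal = CalibrationState(**d["calibration"])
        return cls(
            populations=pops,
            n_frames=d["n_frames"],
            calibration=cal,
            drift_um_per_frame=tuple(d.get("drift_um_per_frame", (0.0, 0.0))),
            background_level=d.get("background_level", 0.2),
            noise_sd=d.get("noise_sd", 0.02),
            seed=d.get("seed", 0),
            speed_factor_per_frame=d.get("speed_factor_per_frame"),
        )


@dataclass
class GroundTruth:
    """Per-particle, per-frame truth for a simulated scene.

    ``positions_um`` are the wrapped (rendered) positions; ``unwrapped_um``
    the continuous paths before boundary handling. ``speeds_um_s`` is each
    particle's own instantaneous swimming/sinking speed (drift excluded).
    ``wrapped[i, f]`` marks a toroidal wrap between frames ``f-1`` and ``f``.
    """

    kinds: np.ndarray          # (n,) str
    positions_um: np.ndarray   # (n, F, 2) wrapped
    unwrapped_um: np.ndarray   # (n, F, 2)
    speeds_um_s: np.ndarray    # (n, F)
    headings_deg: np.ndarray   # (n, F)
    wrapped: np.ndarray        # (n, F) bool
    drift_um_per_frame: np.ndarray  # (2,)
    radii_um: np.ndarray       # (n,)
    intensities: np.ndarray    # (n,)

    @property
    def n_particles(self) -> int:
        return self.positions_um.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions_um.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (one row per particle per frame)."""
        n, f = self.n_particles, self.n_frames
        pid = np.repeat(np.arange(n), f)
        frm = np.tile(np.arange(f), n)
        return pd.DataFrame(
            {
                "particle_id": pid,
                "kind": np.repeat(self.kinds, f),
                "frame": frm,
                "x_um": self.positions_um[:, :, 0].ravel(),
                "y_um": self.positions_um[:, :, 1].ravel(),
                "speed_um_s": self.speeds_um_s.ravel(),
                "heading_deg": self.headings_deg.ravel(),
                "wrapped": self.wrapped.ravel(),
            }
        )


def simulate_tracks(config: SceneConfig) -> GroundTruth:
    """Simulate particle motion for a scene; deterministic given the seed.

    Swimmers move at an individual constant base speed along a heading
    perturbed each frame by a Gaussian of sd ``turn_sd_deg_per_frame``;
    sedimenters move straight down at constant speed; adherent cells are
    static. Drift is added to every particle. Randomness never depends on
    the drift vector, so adding drift shifts displacements exactly.
    """
    rng = np.random.default_rng(config.seed)
    cal = config.calibration
    w_um, h_um = cal.fov_width_um, cal.fov_height_um
    n = config.n_particles
    n_frames = config.n_frames
    dt = 1.0 / cal.frame_rate
    drift = np.asarray(config.drift_um_per_frame, dtype=float)
    factor = (
        config.speed_factor_per_frame
        if config.speed_factor_per_frame is not None
        else np.ones(n_frames)
    )

    kinds = np.empty(n, dtype=object)
    radii = np.empty(n)
    intensities = np.empty(n)
    base_speed = np.empty(n)
    heading0 = np.empty(n)
    turn_sd = np.empty(n)

    i = 0
    for pop in config.populations:
        sl = slice(i, i + pop.count)
        kinds[sl] = pop.kind
        radii[sl] = pop.radius_um
        intensities[sl] = pop.intensity
        base_speed[sl] = np.clip(
            rng.normal(pop.speed_um_s, pop.speed_sd_um_s, pop.count), 0.0, None
        )
        if pop.heading_mode == "isotropic":
            heading0[sl] = rng.uniform(0.0, 360.0, pop.count)
        elif pop.heading_mode[0] == "fixed":
            heading0[sl] = pop.heading_mode[1]
        elif pop.heading_mode[0] == "biased":
            theta, kappa = pop.heading_mode[1], pop.heading_mode[2]
            heading0[sl] = np.degrees(
                rng.vonmises(np.radians(theta), kappa, pop.count)
            ) % 360.0
        else:
            raise ValueError(f"unknown heading_mode {pop.heading_mode!r}")
        turn_sd[sl] = pop.turn_sd_deg_per_frame
        i += pop.count

    positions = np.empty((n, n_frames, 2))
    unwrapped = np.empty((n, n_frames, 2))
    speeds = np.empty((n, n_frames))
    headings = np.empty((n, n_frames))
    wrapped = np.zeros((n, n_frames), dtype=bool)

    pos = np.column_stack([rng.uniform(0, w_um, n), rng.uniform(0, h_um, n)])
    upos = pos.copy()
    heading = heading0.copy()
    # pre-draw heading perturbations so they are independent of drift
    turns = rng.normal(0.0, 1.0, (n, n_frames)) * turn_sd[:, None]

    for f in range(n_frames):
        if f > 0:
            heading = (heading + turns[:, f]) % 360.0
            v = base_speed * factor[f - 1]
            dx, dy = vector_from_heading(heading, v * dt)
            step = np.column_stack([dx, dy]) + drift
            upos = upos + step
            pos = pos + step
            wrapped[:, f] = (
                (pos[:, 0] < 0) | (pos[:, 0] >= w_um)
                | (pos[:, 1] < 0) | (pos[:, 1] >= h_um)
            )
            pos[:, 0] %= w_um
            pos[:, 1] %= h_um
        positions[:, f] = pos
        unwrapped[:, f] = upos
        speeds[:, f] = base_speed * factor[f]
        headings[:, f] = heading

    # adherent cells have no heading; record NaN to avoid accidental use
    headings[kinds == "adherent"] = np.nan
    return GroundTruth(
        kinds=kinds,
        positions_um=positions,
        unwrapped_um=unwrapped,
        speeds_um_s=speeds,
        headings_deg=headings,
        wrapped=wrapped,
        drift_um_per_frame=drift,
        radii_um=radii,
        intensities=intensities,
    )


def _add_disk(frame: np.ndarray, cx: float, cy: float, r: float, amp: float) -> None:
    """Additively draw an anti-aliased disk, clipped to the frame."""
    h, w = frame.shape
    x0, x1 = int(np.floor(cx - r - 1)), int(np.ceil(cx + r + 2))
    y0, y1 = int(np.floor(cy - r - 1)), int(np.ceil(cy + r + 2))
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    frame[y0:y1, x0:x1] += amp * np.clip(r + 0.5 - d, 0.0, 1.0)


def render_frames(truth: GroundTruth, config: SceneConfig) -> FrameSequence:
    """Render the ground truth as 8-bit grayscale frames.

    Each particle becomes an anti-aliased bright disk on the background;
    disks crossing a border are drawn again at the wrapped position so
    toroidal scenes look seamless. Gaussian pixel noise of sd
    ``noise_sd`` is added, frames are clipped to [0, 1] and quantised.
    """
    cal = config.calibration
    w, h = cal.frame_width_px, cal.frame_height_px
    radii_px = truth.radii_um / cal.um_per_px if truth.n_particles else np.empty(0)
    if truth.n_particles and np.any(radii_px < 1.0):
        warnings.warn(
            "some particles are smaller than 1 px at this calibration; "
            "sub-pixel cells are unreliable to segment",
            stacklevel=2,
        )
    # noise drawn from a stream separate from the motion stream so that
    # truth and rendering are independently reproducible
    noise_rng = np.random.default_rng([config.seed, 0x5EED])
    frames = np.empty((config.n_frames, h, w), dtype=np.uint8)
    for f in range(config.n_frames):
        img = np.full((h, w), config.background_level, dtype=float)
        for i in range(truth.n_particles):
            x_um, y_um = truth.positions_um[i, f]
            cx, cy = x_um / cal.um_per_px, y_um / cal.um_per_px
            r = radii_px[i]
            amp = truth.intensities[i]
            for ox in (0.0, -w, w):
                for oy in (0.0, -h, h):
                    if -r - 1 <= cx + ox <= w + r + 1 and -r - 1 <= cy + oy <= h + r + 1:
                        _add_disk(img, cx + ox, cy + oy, r, amp)
        if config.noise_sd > 0:
            img += noise_rng.normal(0.0, config.noise_sd, (h, w))
        frames[f] = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    return FrameSequence(frames=frames, calibration=cal)


def simulate_scene(config: SceneConfig) -> tuple[GroundTruth, FrameSequence]:
    """Convenience: simulate motion and render it in one call."""
    truth = simulate_tracks(config)
    return truth, render_frames(truth, config)


def write_fixture(
    frames: FrameSequence, truth: GroundTruth, directory: str | Path,
    config: SceneConfig | None = None,
) -> Path:
    """Write a scene to disk: numbered PNGs, truth.csv, scene.json echo.

    Layout: ``frames/000001.png …``, ``truth.csv`` (particle_id, kind,
    frame, x_um, y_um, speed_um_s, heading_deg, wrapped), ``scene.json``.
    """
    directory = Path(directory)
    frame_dir = directory / "frames"
    try:
        frame_dir.mkdir(parents=True, exist_ok=True)
        for i in range(len(frames)):
            iio.imwrite(frame_dir / f"{i + 1:06d}.png", frames.frames[i])
        truth.to_frame().to_csv(directory / "truth.csv", index=False)
        if config is not None:
            (directory / "scene.json").write_text(
                json.dumps(config.to_dict(), indent=1) + "\n"
            )
    except OSError as exc:
        raise OSError(f"failed to write fixture under {directory}: {exc}") from exc
    return directory


def load_fixture(directory: str | Path) -> tuple[FrameSequence, pd.DataFrame, SceneConfig]:
    """Read back a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    config = SceneConfig.from_dict(json.loads((directory / "scene.json").read_text()))
    paths = sorted((directory / "frames").glob("*.png"))
    frames = np.stack([iio.imread(p) for p in paths])
    truth = pd.read_csv(directory / "truth.csv")
    return FrameSequence(frames=frames, calibration=config.calibration), truth, config


def truth_to_tracks(truth: GroundTruth, calibration: CalibrationState):
    """Build one idealised track per particle from the continuous paths.

    Uses the unwrapped positions, so trajectory statistics are free of
    boundary-wrap artefacts; intended for validating classifiers against
    known population labels. Returns ``list[Track]`` (see tracking module).
    """
    from .tracking import Detection, Track

    tracks = []
    for i in range(truth.n_particles):
        pts = [
            Detection(
                frame_index=f,
                centroid=(
                    truth.unwrapped_um[i, f, 0] / calibration.um_per_px,
                    truth.unwrapped_um[i, f, 1] / calibration.um_per_px,
                ),
                area_px=np.pi * (truth.radii_um[i] / calibration.um_per_px) ** 2,
            )
            for f in range(truth.n_frames)
        ]
        tracks.append(Track(track_id=i, points=pts))
    return tracks
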