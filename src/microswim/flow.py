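"""Top-down, population-level motility from dense optical flow.

Pipeline per consecutive frame pair: dense displacement field → noise
thresholding → cell-region extraction (Canny edges + area filter) →
per-region vector averaging → bulk-drift correction → mean speed in
µm/s. Frame pairs are independent, which makes this path robust at high
cell density and sensitive to short-term speed changes, at the cost of
not tracking individual identities.

Drift (sedimentation or bulk fluid motion) is estimated either by
consensus — the largest group of region vectors sharing direction and
magnitude within tolerances, presumed to be non-motile cells carried by
the flow — or from a dark pre-exposure segment during which no directed
swimming is assumed. Consensus refuses (returns no drift) when nearly
all vectors agree, since strong collective swimming (phototaxis) is then
indistinguishable from drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.morphology import closing, disk
from skimage.measure import label, regionprops
from skimage.registration import optical_flow_ilk

from .angles import angle_difference_deg, circular_mean_deg, heading_from_vector
from .optics import px_per_frame_to_um_per_s
from .sequence import FrameSequence

__all__ = [
    "FlowParams",
    "FlowField",
    "MotionRegion",
    "DriftEstimate",
    "dense_flow",
    "threshold_flow",
    "extract_motion_regions",
    "estimate_drift_consensus",
    "estimate_drift_dark",
    "apply_drift_correction",
    "frame_pair_speeds",
]


@dataclass(frozen=True)
class FlowParams:
    """Tunables of the top-down pipeline.

    The dense-flow estimator is a pyramidal iterative Lucas–Kanade
    scheme; ``flow_radius`` is the half-width of its local window.
    ``min_magnitude_px`` removes the sub-noise-floor vectors; the
    defaults sit above the noise observed on identical-frame pairs.
    Region area bounds default to (0.25x, 4x) the expected cell area
    computed from ``cell_radius_px``.
    """

    flow_radius: int = 7
    flow_num_warp: int = 3
    flow_gaussian: bool = False
    min_magnitude_px: float = 0.5
    canny_sigma: float = 1.5
    cell_radius_px: float = 5.0
    area_bounds_px: tuple[float, float] | None = None
    angle_tol_deg: float = 7.5
    mag_tol_frac: float = 0.2
    min_support_frac: float = 0.2
    max_support_frac: float = 0.8
    exclude_drift_group: bool = True

    def effective_area_bounds(self) -> tuple[float, float]:
        if self.area_bounds_px is not None:
            return self.area_bounds_px
        expected = np.pi * self.cell_radius_px**2
        return (0.25 * expected, 4.0 * expected)


@dataclass
class FlowField:
    """Per-pixel displacement between one frame pair, in px/frame."""

    dx: np.ndarray
    dy: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx and dy must share shape")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)

    @property
    def angle_deg(self) -> np.ndarray:
        return heading_from_vector(self.dx, self.dy)


@dataclass
class MotionRegion:
    """A connected cell-sized region with its averaged motion vector.

    The mean magnitude is the norm of the mean vector — a cell is
    treated as a rigid translating body, so internally opposing vector
    noise cancels rather than inflating the magnitude.
    """

    mask: np.ndarray          # boolean, full-frame
    area_px: int
    mean_vector: tuple[float, float]

    @property
    def mean_magnitude_px(self) -> float:
        return float(np.hypot(*self.mean_vector))

    @property
    def mean_angle_deg(self) -> float:
        return float(heading_from_vector(*self.mean_vector))


@dataclass
class DriftEstimate:
    """A single bulk-motion displacement vector and its provenance."""

    vector: tuple[float, float]
    support: int
    mode: str  # consensus | dark_calibrated | none
    member_indices: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mode not in ("consensus", "dark_calibrated", "none"):
            raise ValueError(f"unknown drift mode {self.mode!r}")
        if self.mode == "none":
            self.vector = (0.0, 0.0)
            self.support = 0
            self.member_indices = ()


def dense_flow(
    frame_a: np.ndarray, frame_b: np.ndarray, params: FlowParams = FlowParams()
) -> FlowField:
    """Dense displacement field from frame_a to frame_b (px/frame)."""
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError(
            f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}"
        )
    v, u = optical_flow_ilk(
        frame_a,
        frame_b,
        radius=params.flow_radius,
        num_warp=params.flow_num_warp,
        gaussian=params.flow_gaussian,
    )
    return FlowField(dx=u, dy=v)


def threshold_flow(fieldf: FlowField, min_magnitude_px: float) -> FlowField:
    """Zero out vectors below the magnitude threshold; idempotent."""
    if min_magnitude_px < 0:
        raise ValueError("min_magnitude_px must be non-negative")
    keep = fieldf.magnitude >= min_magnitude_px
    return FlowField(
        dx=np.where(keep, fieldf.dx, 0.0),
        dy=np.where(keep, fieldf.dy, 0.0),
        frame_index=fieldf.frame_index,
    )


def extract_motion_regions(
    fieldf: FlowField, frame: np.ndarray, params: FlowParams = FlowParams()
) -> list[MotionRegion]:
    """Cell-sized regions from Canny edges, each with its mean flow vector.

    Edges are detected on the image frame, morphologically closed and
    filled into connected components; components with area outside the
    bounds are discarded (debris and aggregates). The mean vector of a
    region is the arithmetic mean of the member-pixel vectors that
    survived thresholding (zeroed noise pixels do not dilute the cell's
    displacement); a region whose vectors were all suppressed gets mean
    vector (0, 0).
    """
    frame = np.asarray(frame, dtype=float)
    lo, hi = params.effective_area_bounds()
    edges = canny(frame, sigma=params.canny_sigma)
    closed = closing(edges, disk(2))
    filled = ndi.binary_fill_holes(closed)
    labels = label(filled)
    regions: list[MotionRegion] = []
    for prop in regionprops(labels):
        if not (lo <= prop.area <= hi):
            continue
        mask = labels == prop.label
        dxs, dys = fieldf.dx[mask], fieldf.dy[mask]
        moving = (dxs != 0) | (dys != 0)
        if moving.any():
            vec = (float(dxs[moving].mean()), float(dys[moving].mean()))
        else:
            vec = (0.0, 0.0)
        regions.append(MotionRegion(mask=mask, area_px=int(prop.area), mean_vector=vec))
    return regions


def _consensus_group(
    vectors: np.ndarray, angle_tol_deg: float, mag_tol_frac: float
) -> np.ndarray:
    """Indices of the largest self-consistent vector group.

    Grown from each vector as a seed and refined to a fixed point of:
    member iff within ``angle_tol_deg`` of the group's circular-mean
    direction and within ``mag_tol_frac`` relative magnitude of the
    group median. Deterministic; ties go to the earliest seed.
    """
    n = len(vectors)
    mags = np.hypot(vectors[:, 0], vectors[:, 1])
    angs = heading_from_vector(vectors[:, 0], vectors[:, 1])
    best = np.array([], dtype=int)
    for seed in range(n):
        if mags[seed] == 0:
            continue
        members = np.array([seed])
        for _ in range(20):
            ref_ang = circular_mean_deg(angs[members])
            ref_mag = float(np.median(mags[members]))
            ok = (
                (angle_difference_deg(angs, ref_ang) <= angle_tol_deg)
                & (np.abs(mags - ref_mag) <= mag_tol_frac * ref_mag)
                & (mags > 0)
            )
            new = np.flatnonzero(ok)
            if np.array_equal(new, members) or len(new) == 0:
                members = new if len(new) else members
                break
            members = new
        if len(members) > len(best):
            best = members
    return best


def estimate_drift_consensus(
    vectors,
    angle_tol_deg: float = 7.5,
    mag_tol_frac: float = 0.2,
    min_support_frac: float = 0.2,
) -> DriftEstimate:
    """Drift as the mean of the largest direction/magnitude-consistent group.

    Vectors (presumed one per detected region) whose direction lies
    within ``angle_tol_deg`` of the group's circular-mean direction and
    whose magnitude is within ``mag_tol_frac`` of the group median form
    the drift group; its arithmetic mean is the drift. Returns mode
    ``none`` when the best group holds fewer than ``min_support_frac``
    of all vectors (no coherent bulk motion).
    """
    vectors = np.asarray(vectors, dtype=float).reshape(-1, 2)
    if len(vectors) == 0:
        return DriftEstimate(vector=(0.0, 0.0), support=0, mode="none")
    group = _consensus_group(vectors, angle_tol_deg, mag_tol_frac)
    if len(group) < max(min_support_frac * len(vectors), 1):
        return DriftEstimate(vector=(0.0, 0.0), support=0, mode="none")
    mean = vectors[group].mean(axis=0)
    return DriftEstimate(
        vector=(float(mean[0]), float(mean[1])),
        support=int(len(group)),
        mode="consensus",
        member_indices=tuple(int(i) for i in group),
    )


def estimate_drift_dark(
    dark_frames: FrameSequence, params: FlowParams = FlowParams()
) -> DriftEstimate:
    """Drift from a dark pre-exposure segment, for phototaxis conditions.

    Runs the full top-down pass over the segment and averages *all*
    region vectors without any consensus restriction — in darkness no
    collectively directed swimming is assumed, so individual motility
    cancels and the mean is the bulk drift. The estimate is intended to
    be stored and applied across the whole experiment.
    """
    if len(dark_frames) < 2:
        raise ValueError("dark segment needs at least 2 frames")
    collected: list[tuple[float, float]] = []
    for i in range(len(dark_frames) - 1):
        fieldf = dense_flow(dark_frames.as_float(i), dark_frames.as_float(i + 1), params)
        fieldf = threshold_flow(fieldf, params.min_magnitude_px)
        regions = extract_motion_regions(fieldf, dark_frames.as_float(i), params)
        collected.extend(r.mean_vector for r in regions)
    if not collected:
        import warnings

        warnings.warn("no regions detected in dark segment; drift unknown", stacklevel=2)
        return DriftEstimate(vector=(0.0, 0.0), support=0, mode="none")
    arr = np.asarray(collected)
    mean = arr.mean(axis=0)
    return DriftEstimate(
        vector=(float(mean[0]), float(mean[1])),
        support=len(collected),
        mode="dark_calibrated",
    )


def apply_drift_correction(
    regions: list[MotionRegion], drift: DriftEstimate
) -> list[MotionRegion]:
    """Subtract the drift vector from every region's mean vector."""
    if drift.mode == "none":
        return list(regions)
    dx, dy = drift.vector
    return [
        replace(r, mean_vector=(r.mean_vector[0] - dx, r.mean_vector[1] - dy))
        for r in regions
    ]


def frame_pair_speeds(
    sequence: FrameSequence,
    params: FlowParams = FlowParams(),
    drift_policy: str = "consensus",
    dark_drift: DriftEstimate | None = None,
) -> pd.DataFrame:
    """Per-frame-pair mean population speed in µm/s.

    ``drift_policy`` is ``"consensus"`` (per-pair consensus vector, the
    drift group excluded from the speed average by default),
    ``"dark"`` (subtract a stored dark-segment estimate) or ``"none"``.
    With consensus, correction is refused for a pair when the drift
    group holds more than ``params.max_support_frac`` of the vectors —
    near-unanimous motion is indistinguishable from collective swimming
    and must not be cancelled.

    Returns a DataFrame with columns frame_index, time_s,
    mean_speed_um_s (NaN when no regions), n_regions, drift_dx_px,
    drift_dy_px. Frame pairs are processed independently.
    """
    if drift_policy not in ("consensus", "dark", "none"):
        raise ValueError(f"unknown drift_policy {drift_policy!r}")
    if drift_policy == "dark" and dark_drift is None:
        raise ValueError("drift_policy 'dark' requires a dark_drift estimate")
    if len(sequence) < 2:
        raise ValueError("need at least 2 frames")
    cal = sequence.calibration
    rows = []
    for i in range(len(sequence) - 1):
        fa, fb = sequence.as_float(i), sequence.as_float(i + 1)
        fieldf = dense_flow(fa, fb, params)
        fieldf.frame_index = i
        fieldf = threshold_flow(fieldf, params.min_magnitude_px)
        regions = extract_motion_regions(fieldf, fa, params)
        drift = DriftEstimate(vector=(0.0, 0.0), support=0, mode="none")
        speed_regions = regions
        if regions:
            if drift_policy == "consensus":
                cand = estimate_drift_consensus(
                    [r.mean_vector for r in regions],
                    params.angle_tol_deg,
                    params.mag_tol_frac,
                    params.min_support_frac,
                )
                if (
                    cand.mode == "consensus"
                    and cand.support <= params.max_support_frac * len(regions)
                ):
                    drift = cand
                    corrected = apply_drift_correction(regions, drift)
                    if params.exclude_drift_group:
                        member = set(drift.member_indices)
                        speed_regions = [
                            r for j, r in enumerate(corrected) if j not in member
                        ]
                    else:
                        speed_regions = corrected
            elif drift_policy == "dark":
                drift = dark_drift
                speed_regions = apply_drift_correction(regions, drift)
        if speed_regions:
            mean_mag = float(
                np.mean([r.mean_magnitude_px for r in speed_regions])
            )
            speed = px_per_frame_to_um_per_s(mean_mag, cal)
        else:
            speed = np.nan
        rows.append(
            {
                "frame_index": i,
                "time_s": i / cal.frame_rate,
                "mean_speed_um_s": speed,
                "n_regions": len(regions),
                "drift_dx_px": drift.vector[0],
                "drift_dy_px": drift.vector[1],
            }
        )
    return pd.DataFrame(rows)
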