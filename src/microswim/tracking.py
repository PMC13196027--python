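"""Bottom-up single-cell segmentation and identity-preserving tracking.

The reverse of the top-down path: cells are first isolated per frame
(adaptive threshold → Canny contours → connected components →
percentile area filter), then their centroids are linked across frames
into continuous trajectories using constant-velocity motion prediction
and globally optimal one-to-one assignment under a gating radius. This
yields per-cell speeds, headings and path shapes, at the cost of more
parameter tuning and sensitivity to crowding (identity swaps when
silhouettes merge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from skimage.feature import canny
from skimage.filters import threshold_local
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk

from .angles import heading_from_vector
from .optics import CalibrationState

__all__ = [
    "SegmentationParams",
    "LinkParams",
    "Detection",
    "Track",
    "segment_frame",
    "detect_cells",
    "filter_by_area_percentile",
    "link_detections",
    "track_table",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Adaptive-threshold and contour-detection tunables.

    ``block_size`` (odd) is the local-mean window of the adaptive
    threshold; ``offset`` is subtracted from the local mean, so a
    negative offset demands pixels brighter than their surroundings by
    |offset| — suited to bright cells on a darker background. Set
    ``invert=True`` for dark cells on a bright background. ``canny_on``
    selects whether contours are traced on the binary mask (default;
    closes ragged components) or on the raw frame.
    """

    block_size: int = 51
    offset: float = -0.08
    invert: bool = False
    canny_sigma: float = 1.0
    canny_on: str = "mask"  # mask | raw


@dataclass(frozen=True)
class LinkParams:
    """Tracker tunables.

    ``gate_px`` is the maximum prediction-to-detection distance for a
    match (a sensible value is ~3x the expected per-frame displacement);
    ``init_hits`` consecutive matches confirm a tentative track;
    ``max_skip`` missed frames terminate a track.
    """

    gate_px: float = 15.0
    init_hits: int = 2
    max_skip: int = 3


@dataclass(frozen=True)
class Detection:
    """One segmented cell in one frame: subpixel centroid plus area."""

    frame_index: int
    centroid: tuple[float, float]  # (x, y) px
    area_px: float

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.area_px <= 0:
            raise ValueError("area_px must be positive")


@dataclass
class Track:
    """One cell's identity: ordered detections with derived kinematics."""

    track_id: int
    points: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [p.frame_index for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("points must have strictly increasing frame_index")

    def __len__(self) -> int:
        return len(self.points)

    def step_speeds_um_s(self, calibration: CalibrationState) -> np.ndarray:
        """Per-step speeds, µm/s; frame gaps divide by the elapsed time."""
        if len(self.points) < 2:
            return np.empty(0)
        xy = np.array([p.centroid for p in self.points])
        f = np.array([p.frame_index for p in self.points], dtype=float)
        d_px = np.hypot(*np.diff(xy, axis=0).T)
        dt_s = np.diff(f) / calibration.frame_rate
        return d_px * calibration.um_per_px / dt_s

    def step_headings_deg(self) -> np.ndarray:
        """Per-step headings, degrees (0° = up, clockwise)."""
        if len(self.points) < 2:
            return np.empty(0)
        xy = np.array([p.centroid for p in self.points])
        dxy = np.diff(xy, axis=0)
        return heading_from_vector(dxy[:, 0], dxy[:, 1])

    def mean_speed_um_s(self, calibration: CalibrationState) -> float:
        s = self.step_speeds_um_s(calibration)
        return float(s.mean()) if s.size else float("nan")

    def net_displacement_um(self, calibration: CalibrationState) -> float:
        if len(self.points) < 2:
            return 0.0
        x0, y0 = self.points[0].centroid
        x1, y1 = self.points[-1].centroid
        return float(np.hypot(x1 - x0, y1 - y0) * calibration.um_per_px)

    def duration_s(self, calibration: CalibrationState) -> float:
        if len(self.points) < 2:
            return 0.0
        return (
            self.points[-1].frame_index - self.points[0].frame_index
        ) / calibration.frame_rate


def segment_frame(
    frame: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> np.ndarray:
    """Binary mask isolating cells via local-mean adaptive thresholding."""
    frame = np.asarray(frame, dtype=float)
    if params.invert:
        frame = frame.max() - frame
    thresh = threshold_local(frame, params.block_size, offset=params.offset)
    return frame > thresh


def detect_cells(
    mask: np.ndarray,
    frame: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    frame_index: int = 0,
) -> list[Detection]:
    """Detections from a segmentation mask: contour → component → centroid.

    Contours are traced with Canny (on the mask by default, closing
    ragged component outlines; on the raw frame with ``canny_on="raw"``),
    morphologically closed, filled and labelled. Centroids are
    intensity-weighted over each component for subpixel precision.
    """
    frame = np.asarray(frame, dtype=float)
    source = mask.astype(float) if params.canny_on == "mask" else frame
    edges = canny(source, sigma=params.canny_sigma)
    closed = closing(edges, disk(1))
    filled = ndi.binary_fill_holes(closed)
    if params.canny_on == "mask":
        filled |= mask  # contours can only widen the mask, not lose cells
    labels = label(filled)
    h, w = frame.shape
    out = []
    for prop in regionprops(labels, intensity_image=frame):
        cy, cx = prop.centroid_weighted
        cx = min(max(cx, 0.0), w - 1.0)
        cy = min(max(cy, 0.0), h - 1.0)
        out.append(
            Detection(
                frame_index=frame_index, centroid=(float(cx), float(cy)),
                area_px=float(prop.area),
            )
        )
    return out


def filter_by_area_percentile(
    detections: list[Detection],
    low_frac: float = 0.10,
    high_frac: float = 0.10,
) -> list[Detection]:
    """Drop the smallest and largest objects by pooled area quantiles.

    Pools the areas of all detections over the whole video, computes the
    ``low_frac`` and ``1 - high_frac`` empirical quantiles (linear
    interpolation between order statistics) and retains detections with
    ``q_low < area <= q_high`` — removing debris below and aggregates
    above. With fewer than 10 detections the filter is disabled (the
    quantiles would be meaningless) and a warning is emitted.
    """
    if low_frac < 0 or high_frac < 0 or low_frac + high_frac >= 1:
        raise ValueError("need 0 <= low_frac + high_frac < 1")
    if low_frac == 0 and high_frac == 0:
        return list(detections)
    if len(detections) < 10:
        warnings.warn(
            "fewer than 10 detections; area-percentile filter disabled",
            stacklevel=2,
        )
        return list(detections)
    areas = np.array([d.area_px for d in detections])
    q_low, q_high = np.quantile(areas, [low_frac, 1.0 - high_frac])
    if q_low == q_high:  # degenerate distribution: keep everything
        return [d for d in detections if d.area_px == q_low] or list(detections)
    return [d for d in detections if q_low < d.area_px <= q_high]


class _LiveTrack:
    __slots__ = ("track_id", "points", "velocity", "misses", "hits")

    def __init__(self, track_id: int, det: Detection):
        self.track_id = track_id
        self.points = [det]
        self.velocity = np.zeros(2)
        self.misses = 0
        self.hits = 1

    def predict(self) -> np.ndarray:
        last = np.asarray(self.points[-1].centroid)
        # coast through missed frames with the last velocity estimate
        return last + self.velocity * (self.misses + 1)

    def update(self, det: Detection) -> None:
        prev = np.asarray(self.points[-1].centroid)
        gap = det.frame_index - self.points[-1].frame_index
        self.velocity = (np.asarray(det.centroid) - prev) / gap
        self.points.append(det)
        self.misses = 0
        self.hits += 1


def link_detections(
    detections: list[Detection],
    params: LinkParams = LinkParams(),
) -> list[Track]:
    """Link per-frame detections into identity-preserving tracks.

    Frame by frame, each live track predicts its next position under a
    constant-velocity model; predicted positions are matched to the
    frame's detections by globally minimal total Euclidean cost, with
    pairs farther than ``gate_px`` forbidden. Unmatched detections seed
    tentative tracks (reported once they reach ``init_hits`` points);
    tracks are terminated after ``max_skip`` consecutive missed frames,
    so brief occlusions do not break identities.

    Detection order within a frame does not affect the result (up to
    exact cost ties, which are broken deterministically).
    """
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame_index, []).append(d)
    if not by_frame:
        return []

    next_id = 0
    live: list[_LiveTrack] = []
    finished: list[_LiveTrack] = []

    for f in range(min(by_frame), max(by_frame) + 1):
        dets = by_frame.get(f, [])
        live.sort(key=lambda t: t.track_id)
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        if live and dets:
            preds = np.array([t.predict() for t in live])
            pts = np.array([d.centroid for d in dets])
            cost = np.hypot(
                preds[:, 0][:, None] - pts[:, 0][None, :],
                preds[:, 1][:, None] - pts[:, 1][None, :],
            )
            big = params.gate_px * 1e6 + 1.0
            gated = np.where(cost <= params.gate_px, cost, big)
            rows, cols = linear_sum_assignment(gated)
            for r, c in zip(rows, cols):
                if cost[r, c] <= params.gate_px:
                    live[r].update(dets[c])
                    matched_tracks.add(r)
                    matched_dets.add(c)
        survivors = []
        for idx, t in enumerate(live):
            if idx in matched_tracks:
                survivors.append(t)
            else:
                t.misses += 1
                if t.misses > params.max_skip:
                    finished.append(t)
                else:
                    survivors.append(t)
        live = survivors
        for c, det in enumerate(dets):
            if c not in matched_dets:
                live.append(_LiveTrack(next_id, det))
                next_id += 1
    finished.extend(live)

    finished.sort(key=lambda t: t.track_id)
    return [
        Track(track_id=t.track_id, points=t.points)
        for t in finished
        if t.hits >= params.init_hits
    ]


def track_table(tracks: list[Track], calibration: CalibrationState) -> pd.DataFrame:
    """Long-format trajectory table, one row per track point.

    Columns: track_id, frame, t_s, x_px, y_px, x_um, y_um,
    step_speed_um_s, heading_deg (NaN on each track's first point).
    """
    cols = [
        "track_id", "frame", "t_s", "x_px", "y_px", "x_um", "y_um",
        "step_speed_um_s", "heading_deg",
    ]
    rows = []
    for tr in tracks:
        speeds = tr.step_speeds_um_s(calibration)
        headings = tr.step_headings_deg()
        for i, p in enumerate(tr.points):
            x, y = p.centroid
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": p.frame_index,
                    "t_s": p.frame_index / calibration.frame_rate,
                    "x_px": x,
                    "y_px": y,
                    "x_um": x * calibration.um_per_px,
                    "y_um": y * calibration.um_per_px,
                    "step_speed_um_s": speeds[i - 1] if i > 0 else np.nan,
                    "heading_deg": headings[i - 1] if i > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=cols)


def tracks_to_jsonl(tracks: list[Track]) -> str:
    """Serialise tracks as JSON-lines, one track per line."""
    import json

    lines = []
    for tr in tracks:
        lines.append(
            json.dumps(
                {
                    "track_id": tr.track_id,
                    "frames": [p.frame_index for p in tr.points],
                    "x_px": [p.centroid[0] for p in tr.points],
                    "y_px": [p.centroid[1] for p in tr.points],
                    "area_px": [p.area_px for p in tr.points],
                },
                separators=(",", ":"),
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def tracks_from_jsonl(text: str) -> list[Track]:
    """Inverse of :func:`tracks_to_jsonl`; round-trips losslessly."""
    import json

    tracks = []
    for line in text.splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        pts = [
            Detection(frame_index=f, centroid=(x, y), area_px=a)
            for f, x, y, a in zip(d["frames"], d["x_px"], d["y_px"], d["area_px"])
        ]
        tracks.append(Track(track_id=d["track_id"], points=pts))
    return tracks
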