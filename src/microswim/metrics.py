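"""Biological readouts: speed statistics, motile-fraction classification,
orientation distributions and photoshock response quantification.

Two complementary motile/non-motile criteria are provided, matching the
two observation geometries of a motility microscope:

* **speed-based** (vertical configuration, imaging the chamber top
  surface): adherent cells have near-zero speed, so a simple speed
  threshold separates swimmers from stuck cells. The resulting fraction
  is comparative, not absolute — slow swimmers near the surface are
  indistinguishable from adherent cells.
* **trajectory-angle-based** (horizontal configuration, imaging the
  water column): non-motile cells sediment at a uniform speed straight
  down, while swimmers show a broad diversity of headings and speeds.
  Labelling as non-motile only those tracks that head straight down at
  the modal sedimentation speed yields an absolute motility percentage.

Orientation is summarised with circular statistics (polar histogram,
circular mean, resultant length) for phototaxis experiments, and the
photoshock response — a transient swimming stop triggered by a sudden
intensity increase — is quantified from the top-down speed series
around each stimulus pulse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import (
    DOWN_DEG,
    angle_difference_deg,
    circular_mean_deg,
    resultant_length,
)
from .optics import CalibrationState
from .tracking import Track

__all__ = [
    "MotilityReport",
    "OrientationHistogram",
    "PhotoshockResult",
    "PhotoshockParams",
    "classify_by_speed",
    "classify_by_trajectory_angle",
    "orientation_histogram",
    "plot_orientation",
    "photoshock_response",
    "speed_summary",
]


@dataclass
class MotilityReport:
    """Per-track labels and the derived motile fraction."""

    table: pd.DataFrame  # track_id, mean_speed_um_s, mean_heading_deg, label
    motile_fraction: float
    classification_mode: str  # speed_based | trajectory_based
    absolute: bool
    parameters: dict

    @property
    def n_tracks(self) -> int:
        return len(self.table)


@dataclass
class OrientationHistogram:
    """Binned heading distribution with circular summary statistics."""

    bin_edges_deg: np.ndarray
    counts: np.ndarray
    n_total: int
    circular_mean_deg: float
    resultant_length: float

    @property
    def relative_frequency(self) -> np.ndarray:
        if self.n_total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n_total


@dataclass
class PhotoshockResult:
    """Response of the population speed to one stimulus pulse."""

    pulse_onset_s: float
    baseline_speed_um_s: float
    min_speed_um_s: float
    response_duration_s: float
    responded: bool


@dataclass(frozen=True)
class PhotoshockParams:
    """Windows and relative thresholds of the photoshock detector.

    ``baseline`` is the mean speed over ``pre_window_s`` before pulse
    onset; a response requires the speed to fall below
    ``drop_frac x baseline`` within ``react_window_s`` of onset; the
    response ends when the speed first returns above
    ``recover_frac x baseline`` sustained for ``hold_frames`` samples.
    All thresholds are relative, so the detector is invariant to
    rescaling the speed series.
    """

    pre_window_s: float = 5.0
    react_window_s: float = 1.0
    drop_frac: float = 0.5
    recover_frac: float = 0.7
    hold_frames: int = 5


def _track_stats(
    tracks: list[Track], calibration: CalibrationState, min_points: int
) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        if len(tr) < min_points:
            continue
        speeds = tr.step_speeds_um_s(calibration)
        headings = tr.step_headings_deg()
        rows.append(
            {
                "track_id": tr.track_id,
                "n_points": len(tr),
                "mean_speed_um_s": float(speeds.mean()),
                "mean_heading_deg": circular_mean_deg(headings),
            }
        )
    return pd.DataFrame(
        rows, columns=["track_id", "n_points", "mean_speed_um_s", "mean_heading_deg"]
    )


def classify_by_speed(
    tracks: list[Track],
    calibration: CalibrationState,
    speed_threshold_um_s: float = 5.0,
    min_points: int = 2,
) -> MotilityReport:
    """Label tracks motile iff mean speed exceeds the threshold.

    Suited to the vertical configuration, where the non-motile class is
    adherent (near-zero-speed) cells. The default threshold of 5 µm/s
    sits well above centroid-noise apparent speed at typical
    calibrations and frame rates. The reported fraction is comparative
    (``absolute=False``): it does not distinguish slow swimmers from
    stuck cells.
    """
    stats = _track_stats(tracks, calibration, min_points)
    if stats.empty:
        warnings.warn("no tracks to classify", stacklevel=2)
        return MotilityReport(
            table=stats.assign(label=pd.Series(dtype=object)),
            motile_fraction=float("nan"),
            classification_mode="speed_based",
            absolute=False,
            parameters={"speed_threshold_um_s": speed_threshold_um_s},
        )
    stats = stats.assign(
        label=np.where(
            stats["mean_speed_um_s"] > speed_threshold_um_s, "motile", "non_motile"
        )
    )
    return MotilityReport(
        table=stats,
        motile_fraction=float((stats["label"] == "motile").mean()),
        classification_mode="speed_based",
        absolute=False,
        parameters={"speed_threshold_um_s": speed_threshold_um_s},
    )


def _modal_speed(speeds: np.ndarray, n_bins: int = 20) -> float:
    """Histogram mode of a speed sample (bin-centre of the fullest bin)."""
    if speeds.size == 1:
        return float(speeds[0])
    counts, edges = np.histogram(speeds, bins=n_bins)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def classify_by_trajectory_angle(
    tracks: list[Track],
    calibration: CalibrationState,
    down_tol_deg: float = 15.0,
    sed_speed_tol_frac: float = 0.25,
    min_points: int = 2,
) -> MotilityReport:
    """Label tracks by the sedimentation criterion (horizontal geometry).

    The modal sedimentation speed is estimated from tracks heading
    within ``down_tol_deg`` of straight down; a track is non-motile iff
    its mean heading is within that cone *and* its mean speed is within
    ``sed_speed_tol_frac`` of the modal sedimentation speed. Everything
    else — any heading outside the cone, or a down-going track at a
    clearly different speed — is an active swimmer. The fraction is an
    absolute motility percentage. If no track heads downward the speed
    criterion cannot be anchored; classification falls back to the
    angle criterion alone with a warning.
    """
    stats = _track_stats(tracks, calibration, min_points)
    if stats.empty:
        warnings.warn("no tracks to classify", stacklevel=2)
        return MotilityReport(
            table=stats.assign(label=pd.Series(dtype=object)),
            motile_fraction=float("nan"),
            classification_mode="trajectory_based",
            absolute=True,
            parameters={
                "down_tol_deg": down_tol_deg,
                "sed_speed_tol_frac": sed_speed_tol_frac,
            },
        )
    downward = (
        angle_difference_deg(stats["mean_heading_deg"].to_numpy(), DOWN_DEG)
        <= down_tol_deg
    )
    params = {
        "down_tol_deg": down_tol_deg,
        "sed_speed_tol_frac": sed_speed_tol_frac,
        "modal_sed_speed_um_s": None,
    }
    if not downward.any():
        warnings.warn(
            "no downward tracks; sedimentation speed undefined, "
            "falling back to angle-only classification",
            stacklevel=2,
        )
        non_motile = downward  # all False
    else:
        sed_speed = _modal_speed(stats.loc[downward, "mean_speed_um_s"].to_numpy())
        params["modal_sed_speed_um_s"] = sed_speed
        speed_ok = (
            np.abs(stats["mean_speed_um_s"].to_numpy() - sed_speed)
            <= sed_speed_tol_frac * sed_speed
        )
        non_motile = downward & speed_ok
    stats = stats.assign(label=np.where(non_motile, "non_motile", "motile"))
    return MotilityReport(
        table=stats,
        motile_fraction=float((stats["label"] == "motile").mean()),
        classification_mode="trajectory_based",
        absolute=True,
        parameters=params,
    )


def orientation_histogram(
    tracks_or_headings,
    n_bins: int = 16,
    calibration: CalibrationState | None = None,
    min_points: int = 2,
) -> OrientationHistogram:
    """Polar histogram of swimming directions with circular statistics.

    Accepts either per-track objects (each contributes its circular-mean
    heading; ``calibration`` required) or a plain array of headings in
    degrees. The caller is expected to pass motile entries only —
    sedimenting cells would otherwise imprint a spurious downward mode.
    Circular mean and resultant length are computed from the raw
    (unbinned) headings.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    if len(tracks_or_headings) and isinstance(tracks_or_headings[0], Track):
        if calibration is None:
            raise ValueError("calibration required when passing tracks")
        stats = _track_stats(tracks_or_headings, calibration, min_points)
        headings = stats["mean_heading_deg"].dropna().to_numpy()
    else:
        headings = np.asarray(tracks_or_headings, dtype=float) % 360.0
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(headings, bins=edges)
    if headings.size == 0:
        warnings.warn("no headings; circular mean undefined", stacklevel=2)
        mean = float("nan")
        r = float("nan")
    else:
        mean = circular_mean_deg(headings)
        r = resultant_length(headings)
    return OrientationHistogram(
        bin_edges_deg=edges,
        counts=counts,
        n_total=int(headings.size),
        circular_mean_deg=mean,
        resultant_length=r,
    )


def plot_orientation(
    hist: OrientationHistogram, path, title: str | None = None
) -> None:
    """Render a polar bar plot of an orientation histogram to a file.

    Bars show relative frequency per bin; the plot is oriented with 0°
    at the top and angles increasing clockwise, matching the package
    heading convention (light source at the top of the frame).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = np.radians(0.5 * (hist.bin_edges_deg[:-1] + hist.bin_edges_deg[1:]))
    width = np.radians(np.diff(hist.bin_edges_deg))
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.bar(centers, hist.relative_frequency, width=width, alpha=0.8,
           edgecolor="black", linewidth=0.5)
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def photoshock_response(
    speed_series: pd.DataFrame,
    pulse_onsets_s,
    params: PhotoshockParams = PhotoshockParams(),
) -> list[PhotoshockResult]:
    """Quantify the transient swimming stop after each stimulus pulse.

    ``speed_series`` needs columns ``time_s`` and ``mean_speed_um_s``
    (the top-down per-frame-pair output); missing values are ignored.
    Per pulse: baseline = mean speed over the pre-window; ``responded``
    iff the minimum speed within the reaction window falls below
    ``drop_frac x baseline``; the response duration runs from onset to
    the first time the speed holds above ``recover_frac x baseline``
    for ``hold_frames`` consecutive samples. Raises if consecutive
    pulses are closer than the pre-window (analysis windows overlap).
    """
    onsets = sorted(float(t) for t in pulse_onsets_s)
    for a, b in zip(onsets, onsets[1:]):
        if b - a < params.pre_window_s:
            raise ValueError(
                f"pulses at {a} s and {b} s are closer than the "
                f"{params.pre_window_s} s analysis window"
            )
    t = speed_series["time_s"].to_numpy(dtype=float)
    v = speed_series["mean_speed_um_s"].to_numpy(dtype=float)
    ok = np.isfinite(v)
    t, v = t[ok], v[ok]
    results = []
    for k, onset in enumerate(onsets):
        pre = (t >= onset - params.pre_window_s) & (t < onset)
        if not pre.any():
            raise ValueError(f"no samples in the pre-window of the pulse at {onset} s")
        baseline = float(v[pre].mean())
        window_end = onsets[k + 1] if k + 1 < len(onsets) else t[-1] + 1.0
        react = (t >= onset) & (t <= onset + params.react_window_s)
        min_speed = float(v[react].min()) if react.any() else baseline
        responded = min_speed < params.drop_frac * baseline
        duration = 0.0
        if responded:
            post_idx = np.flatnonzero((t >= onset) & (t < window_end))
            above = v[post_idx] >= params.recover_frac * baseline
            duration = float(t[post_idx[-1]] - onset) if post_idx.size else 0.0
            run = 0
            for j, a in enumerate(above):
                run = run + 1 if a else 0
                if run >= params.hold_frames:
                    start = post_idx[j - params.hold_frames + 1]
                    duration = float(t[start] - onset)
                    break
        results.append(
            PhotoshockResult(
                pulse_onset_s=onset,
                baseline_speed_um_s=baseline,
                min_speed_um_s=min_speed,
                response_duration_s=duration,
                responded=responded,
            )
        )
    return results


def speed_summary(replicate_means) -> tuple[float, float]:
    """Mean and sample SD over replicate mean speeds.

    A replicate is one recording's mean speed; with a single replicate
    the SD is undefined and reported as NaN.
    """
    x = np.asarray(list(replicate_means), dtype=float)
    if x.size == 0:
        raise ValueError("need at least one replicate")
    if x.size == 1:
        return float(x[0]), float("nan")
    return float(x.mean()), float(x.std(ddof=1))
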