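"""Frame readers, analysis orchestration and result writers.

The operational shell around the analysis core: read a recording (an
image directory or a container video), run the selected pipeline with a
fully echoed configuration, and leave a machine-readable result bundle
(CSV/JSON + config echo + per-stage log) sufficient to reproduce the
run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import flow as flow_mod
from . import metrics as metrics_mod
from . import tracking as track_mod
from .light import StimulusSchedule
from .optics import CalibrationState
from .sequence import FrameSequence

logger = logging.getLogger("microswim")

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class AnalysisConfig:
    """Everything one run needs; every parameter has a default except
    the calibration, which has no universal value."""

    mode: str  # topdown | bottomup
    calibration: CalibrationState
    flow: flow_mod.FlowParams = field(default_factory=flow_mod.FlowParams)
    segmentation: track_mod.SegmentationParams = field(
        default_factory=track_mod.SegmentationParams
    )
    link: track_mod.LinkParams = field(default_factory=track_mod.LinkParams)
    photoshock: metrics_mod.PhotoshockParams = field(
        default_factory=metrics_mod.PhotoshockParams
    )
    drift_policy: str = "consensus"
    area_filter_low_frac: float = 0.10
    area_filter_high_frac: float = 0.10
    speed_threshold_um_s: float = 5.0
    orientation_bins: int = 16
    stimulus_schedule_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("topdown", "bottomup"):
            raise ValueError(f"mode must be 'topdown' or 'bottomup', got {self.mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["calibration"] = dataclasses.asdict(self.calibration)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d["calibration"] = CalibrationState(**d["calibration"])
        for key, klass in (
            ("flow", flow_mod.FlowParams),
            ("segmentation", track_mod.SegmentationParams),
            ("link", track_mod.LinkParams),
            ("photoshock", metrics_mod.PhotoshockParams),
        ):
            if key in d and isinstance(d[key], dict):
                block = dict(d[key])
                if key == "flow" and isinstance(block.get("area_bounds_px"), list):
                    block["area_bounds_px"] = tuple(block["area_bounds_px"])
                d[key] = klass(**block)
        return cls(**d)


def read_frames(path: str | Path, calibration: CalibrationState) -> FrameSequence:
    """Load a recording as a grayscale frame sequence.

    ``path`` is either a directory of numbered PNG/TIFF frames (read in
    lexicographic order) or a container video file readable by imageio.
    Colour input is converted to luminance (ITU-R 601 weights). The
    frame rate always comes from the calibration.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames found in {path}")
        frames = []
        shape = None
        for p in files:
            try:
                img = iio.imread(p)
            except Exception as exc:
                raise OSError(f"unreadable frame {p}: {exc}") from exc
            img = _to_gray(img)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"frame {p.name} has shape {img.shape}, expected {shape}"
                )
            frames.append(img)
        return FrameSequence(frames=np.stack(frames), calibration=calibration)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        data = iio.imread(path)
    except Exception as exc:
        raise OSError(f"cannot read video {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4:
        data = np.stack([_to_gray(fr) for fr in data])
    return FrameSequence(frames=data, calibration=calibration)


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        rgb = img[..., :3].astype(float)
        gray = rgb @ np.array([0.299, 0.587, 0.114])
        return np.round(gray).astype(img.dtype)
    raise ValueError(f"unsupported frame shape {img.shape}")


def run_analysis(
    config: AnalysisConfig, input_path: str | Path, out_dir: str | Path
) -> dict:
    """Run one pipeline end to end and write the result bundle.

    Top-down mode writes ``speed_series.csv``; bottom-up mode writes
    ``tracks.csv``, ``tracks.jsonl`` and ``motility_report.csv`` plus an
    orientation histogram (``orientation.csv``). When a stimulus
    schedule is configured, photoshock results are written as
    ``photoshock.csv``. The effective configuration is echoed to
    ``config.json``. Returns a summary dict of the main quantities.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("parameters: %s", json.dumps(config.to_dict(), sort_keys=True))
    (out_dir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    sequence = read_frames(input_path, config.calibration)
    logger.info("loaded %d frames of %s", len(sequence), sequence.frames.shape[1:])

    schedule = None
    if config.stimulus_schedule_path:
        schedule = StimulusSchedule.from_json(
            Path(config.stimulus_schedule_path).read_text()
        )

    summary: dict = {"mode": config.mode, "n_frames": len(sequence)}
    try:
        if config.mode == "topdown":
            series = flow_mod.frame_pair_speeds(
                sequence, config.flow, drift_policy=config.drift_policy
            )
            series.to_csv(out_dir / "speed_series.csv", index=False)
            valid = series["mean_speed_um_s"].dropna()
            summary["mean_speed_um_s"] = float(valid.mean()) if len(valid) else None
            summary["n_frame_pairs"] = len(series)
            logger.info(
                "topdown: %d pairs, mean speed %s µm/s",
                len(series), summary["mean_speed_um_s"],
            )
            if schedule is not None:
                results = metrics_mod.photoshock_response(
                    series, schedule.pulse_onsets_s, config.photoshock
                )
                pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
                    out_dir / "photoshock.csv", index=False
                )
                summary["photoshock_n_responded"] = sum(r.responded for r in results)
        else:
            detections: list[track_mod.Detection] = []
            for i in range(len(sequence)):
                frame = sequence.as_float(i)
                mask = track_mod.segment_frame(frame, config.segmentation)
                detections.extend(
                    track_mod.detect_cells(mask, frame, config.segmentation, i)
                )
            n_raw = len(detections)
            detections = track_mod.filter_by_area_percentile(
                detections, config.area_filter_low_frac, config.area_filter_high_frac
            )
            logger.info(
                "bottomup: %d detections, %d after area filter", n_raw, len(detections)
            )
            tracks = track_mod.link_detections(detections, config.link)
            logger.info("bottomup: %d confirmed tracks", len(tracks))
            table = track_mod.track_table(tracks, config.calibration)
            table.to_csv(out_dir / "tracks.csv", index=False)
            (out_dir / "tracks.jsonl").write_text(
                track_mod.tracks_to_jsonl(tracks)
            )
            report = metrics_mod.classify_by_speed(
                tracks, config.calibration, config.speed_threshold_um_s
            )
            report.table.to_csv(out_dir / "motility_report.csv", index=False)
            motile = [
                t for t in tracks
                if t.track_id
                in set(report.table.loc[report.table.label == "motile", "track_id"])
            ]
            hist = metrics_mod.orientation_histogram(
                motile, config.orientation_bins, config.calibration
            )
            pd.DataFrame(
                {
                    "bin_start_deg": hist.bin_edges_deg[:-1],
                    "bin_end_deg": hist.bin_edges_deg[1:],
                    "count": hist.counts,
                    "relative_frequency": hist.relative_frequency,
                }
            ).to_csv(out_dir / "orientation.csv", index=False)
            if hist.n_total:
                metrics_mod.plot_orientation(
                    hist, out_dir / "orientation.png",
                    title="motile swimming directions",
                )
            summary.update(
                n_detections=len(detections),
                n_tracks=len(tracks),
                motile_fraction=report.motile_fraction,
                mean_speed_um_s=float(report.table["mean_speed_um_s"].mean())
                if len(report.table)
                else None,
            )
    except Exception as exc:
        raise RuntimeError(f"analysis failed in {config.mode} stage: {exc}") from exc
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    return summary
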