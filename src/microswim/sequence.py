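"""Frame-sequence container shared by the analysis pipelines."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import CalibrationState


@dataclass
class FrameSequence:
    """Ordered grayscale frames plus the calibration that interprets them.

    ``frames`` is a (n_frames, height, width) array. Integer dtypes
    (8/10/16-bit) are kept as stored; :meth:`as_float` yields frames
    normalised to [0, 1] for analysis.
    """

    frames: np.ndarray
    calibration: CalibrationState

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, h, w) array, got shape {self.frames.shape}"
            )
        h, w = self.frames.shape[1:]
        if (w, h) != (self.calibration.frame_width_px, self.calibration.frame_height_px):
            raise ValueError(
                f"frame shape {w}x{h} px does not match calibration "
                f"{self.calibration.frame_width_px}x{self.calibration.frame_height_px}"
            )

    def __len__(self) -> int:
        return self.frames.shape[0]

    def as_float(self, index: int) -> np.ndarray:
        """Frame ``index`` as float64 in [0, 1]."""
        frame = self.frames[index]
        if np.issubdtype(frame.dtype, np.integer):
            info = np.iinfo(frame.dtype)
            return frame.astype(np.float64) / info.max
        return np.clip(frame.astype(np.float64), 0.0, 1.0)

    @property
    def duration_s(self) -> float:
        return len(self) / self.calibration.frame_rate
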