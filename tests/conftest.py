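"""Shared synthetic-scene fixtures (generated at test time, no stored data)."""

from __future__ import annotations

import pytest

from microswim import (
    CalibrationState,
    ParticlePopulation,
    SceneConfig,
    simulate_scene,
)


@pytest.fixture(scope="session")
def cal_small() -> CalibrationState:
    """Medium-magnification calibration on a small test frame."""
    return CalibrationState(
        um_per_px=0.86, frame_rate=30.0, frame_width_px=208, frame_height_px=160
    )


@pytest.fixture(scope="session")
def swimmer_scene(cal_small):
    """12 ballistic swimmers at 100 µm/s, 40 frames, no drift."""
    config = SceneConfig(
        populations=[
            ParticlePopulation(
                "swimmer", 12, speed_um_s=100.0, speed_sd_um_s=5.0,
                turn_sd_deg_per_frame=4.0, radius_um=5.0,
            )
        ],
        n_frames=40,
        calibration=cal_small,
        seed=42,
    )
    truth, frames = simulate_scene(config)
    return config, truth, frames


@pytest.fixture(scope="session")
def static_scene(cal_small):
    """10 adherent cells, nothing moves."""
    config = SceneConfig(
        populations=[ParticlePopulation("adherent", 10, radius_um=5.0)],
        n_frames=10,
        calibration=cal_small,
        seed=7,
    )
    truth, frames = simulate_scene(config)
    return config, truth, frames


@pytest.fixture(scope="session")
def drift_scene(cal_small):
    """Mostly non-motile scene with a uniform bulk drift of 2 px/frame in x."""
    config = SceneConfig(
        populations=[
            ParticlePopulation(
                "swimmer", 6, speed_um_s=100.0, speed_sd_um_s=5.0,
                turn_sd_deg_per_frame=4.0, radius_um=5.0,
            ),
            ParticlePopulation("adherent", 10, radius_um=5.0),
        ],
        n_frames=25,
        calibration=cal_small,
        drift_um_per_frame=(2 * 0.86, 0.0),
        seed=13,
    )
    truth, frames = simulate_scene(config)
    return config, truth, frames
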