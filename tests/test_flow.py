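"""Top-down pipeline: dense flow, thresholding, regions, drift, speeds."""

import itertools

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as ndshift

from microswim import (
    DriftEstimate,
    FlowField,
    FlowParams,
    apply_drift_correction,
    dense_flow,
    estimate_drift_consensus,
    estimate_drift_dark,
    extract_motion_regions,
    frame_pair_speeds,
    threshold_flow,
)
from microswim.angles import angle_difference_deg, circular_mean_deg, heading_from_vector
from microswim.flow import MotionRegion

PARAMS = FlowParams(cell_radius_px=5 / 0.86)


def _textured(seed=0, shape=(120, 160)):
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.normal(0.5, 0.15, shape), 2).clip(0, 1)


def test_identical_frames_give_near_zero_flow():
    img = _textured()
    field = dense_flow(img, img)
    assert field.magnitude.max() < 0.05


def test_known_rigid_shift_is_recovered():
    img = _textured(1)
    shifted = ndshift(img, (0, 3), order=3, mode="wrap")
    field = dense_flow(img, shifted)
    assert abs(np.median(field.dx) - 3.0) < 0.25
    assert abs(np.median(field.dy)) < 0.25


def test_moving_disk_mean_vector(swimmer_scene):
    config, truth, frames = swimmer_scene
    field = dense_flow(frames.as_float(0), frames.as_float(1))
    cal = config.calibration
    # per-particle true displacement in px
    disp = np.diff(truth.unwrapped_um[:, :2], axis=1)[:, 0] / cal.um_per_px
    yy, xx = np.mgrid[0 : frames.frames.shape[1], 0 : frames.frames.shape[2]]
    errs = []
    for i in range(truth.n_particles):
        if truth.wrapped[i, 1]:
            continue
        cx, cy = truth.positions_um[i, 0] / cal.um_per_px
        mask = np.hypot(xx - cx, yy - cy) <= 5 / cal.um_per_px
        est = np.array([field.dx[mask].mean(), field.dy[mask].mean()])
        errs.append(np.hypot(*(est - disp[i])))
    assert np.median(errs) < 0.5


def test_flow_rejects_shape_mismatch():
    with pytest.raises(ValueError):
        dense_flow(np.zeros((10, 10)), np.zeros((10, 12)))


def test_threshold_flow_zero_is_identity():
    field = FlowField(dx=np.array([[0.2, 2.0]]), dy=np.array([[0.0, 0.0]]))
    out = threshold_flow(field, 0.0)
    assert np.array_equal(out.dx, field.dx)


def test_threshold_flow_above_max_zeroes_everything():
    field = FlowField(dx=np.array([[0.2, 2.0]]), dy=np.array([[0.1, 1.0]]))
    out = threshold_flow(field, 10.0)
    assert not out.dx.any() and not out.dy.any()


def test_threshold_flow_keeps_only_large_vectors_and_is_idempotent():
    field = FlowField(dx=np.array([[0.2, 2.0]]), dy=np.array([[0.0, 0.0]]))
    out = threshold_flow(field, 0.5)
    assert out.dx.tolist() == [[0.0, 2.0]]
    again = threshold_flow(out, 0.5)
    assert np.array_equal(out.dx, again.dx) and np.array_equal(out.dy, again.dy)


def test_flow_field_magnitude_and_angle_conventions():
    field = FlowField(dx=np.array([[3.0]]), dy=np.array([[-4.0]]))
    assert field.magnitude[0, 0] == pytest.approx(5.0)
    # up-right displacement: heading between 0 and 90 degrees
    assert 0 < field.angle_deg[0, 0] < 90


def test_extract_regions_blank_frame_is_empty():
    frame = np.full((100, 100), 0.2)
    field = FlowField(dx=np.zeros((100, 100)), dy=np.zeros((100, 100)))
    assert extract_motion_regions(field, frame, PARAMS) == []


def test_extract_regions_counts_well_separated_disks():
    centers = [(40, 40), (120, 40), (40, 120), (160, 120), (100, 80)]
    frame = np.full((160, 208), 0.2)
    yy, xx = np.mgrid[0:160, 0:208]
    for cx, cy in centers:
        frame += 0.6 * np.clip(5.8 + 0.5 - np.hypot(xx - cx, yy - cy), 0, 1)
    field = FlowField(dx=np.zeros(frame.shape), dy=np.zeros(frame.shape))
    regions = extract_motion_regions(field, frame, PARAMS)
    assert len(regions) == len(centers)


def test_extract_regions_area_filter_drops_out_of_bounds():
    frame = np.full((120, 120), 0.2)
    yy, xx = np.mgrid[0:120, 0:120]
    frame += 0.6 * np.clip(6.0 - np.hypot(xx - 30, yy - 30), 0, 1)  # area ~100 px
    frame += 0.6 * np.clip(1.5 - np.hypot(xx - 90, yy - 90), 0, 1)  # tiny debris
    field = FlowField(dx=np.zeros(frame.shape), dy=np.zeros(frame.shape))
    regions = extract_motion_regions(
        field, frame, FlowParams(area_bounds_px=(40, 500))
    )
    assert len(regions) == 1
    assert 40 <= regions[0].area_px <= 500


def _exhaustive_consensus(vectors, angle_tol, mag_tol):
    """Oracle: largest self-consistent subset by full enumeration."""
    vectors = np.asarray(vectors, dtype=float)
    n = len(vectors)
    mags = np.hypot(vectors[:, 0], vectors[:, 1])
    angs = heading_from_vector(vectors[:, 0], vectors[:, 1])
    best = ()
    for r in range(n, 0, -1):
        for subset in itertools.combinations(range(n), r):
            idx = np.array(subset)
            if (mags[idx] == 0).any():
                continue
            ref_ang = circular_mean_deg(angs[idx])
            ref_mag = np.median(mags[idx])
            if (angle_difference_deg(angs[idx], ref_ang) <= angle_tol).all() and (
                np.abs(mags[idx] - ref_mag) <= mag_tol * ref_mag
            ).all():
                best = subset
                break
        if best:
            break
    return best


def test_consensus_finds_majority_group_like_exhaustive_oracle():
    vectors = [(1.0, 0.0)] * 10 + [(0.0, 3.0)] * 3
    est = estimate_drift_consensus(vectors, 7.5, 0.2)
    assert est.mode == "consensus"
    assert est.support == 10
    assert est.vector == pytest.approx((1.0, 0.0))
    oracle = _exhaustive_consensus(vectors, 7.5, 0.2)
    assert len(oracle) == est.support
    assert set(oracle) == set(est.member_indices)


def test_consensus_on_noisy_clusters_matches_oracle():
    rng = np.random.default_rng(0)
    base = np.array([2.0, 0.5])
    cluster = base + rng.normal(0, 0.03, (7, 2))
    outliers = rng.normal(0, 2.0, (4, 2))
    vectors = np.vstack([cluster, outliers])
    est = estimate_drift_consensus(vectors, 7.5, 0.2)
    oracle = _exhaustive_consensus(vectors, 7.5, 0.2)
    assert est.support == len(oracle)
    assert set(est.member_indices) == set(oracle)


def test_consensus_identical_vectors_full_support():
    est = estimate_drift_consensus([(0.5, -1.0)] * 6)
    assert est.support == 6
    assert est.vector == pytest.approx((0.5, -1.0))


def test_consensus_dissimilar_vectors_refuse():
    vectors = [(1.0, 0.0), (0.0, 1.0), (-1.0, -1.0)]
    est = estimate_drift_consensus(vectors, 7.5, 0.2, min_support_frac=0.4)
    assert est.mode == "none"
    assert est.vector == (0.0, 0.0) and est.support == 0


def test_consensus_empty_input_refuses():
    assert estimate_drift_consensus([]).mode == "none"


def test_dark_drift_recovers_uniform_translation(cal_small):
    # dark pre-exposure segment: non-motile cells carried by pure drift
    from microswim import ParticlePopulation, SceneConfig, simulate_scene

    config = SceneConfig(
        populations=[ParticlePopulation("adherent", 12, radius_um=5.0)],
        n_frames=12, calibration=cal_small,
        drift_um_per_frame=(2 * 0.86, 0.0), seed=17,
    )
    _, frames = simulate_scene(config)
    est = estimate_drift_dark(frames, PARAMS)
    assert est.mode == "dark_calibrated"
    assert est.vector[0] == pytest.approx(2.0, abs=0.2)
    assert abs(est.vector[1]) < 0.2


def test_dark_drift_isotropic_swimmers_mostly_cancel(cal_small):
    # many isotropic swimmers: mean vector far below their mean speed
    from microswim import ParticlePopulation, SceneConfig, simulate_scene

    config = SceneConfig(
        populations=[
            ParticlePopulation("swimmer", 40, speed_um_s=100.0, speed_sd_um_s=5.0,
                               turn_sd_deg_per_frame=15.0, radius_um=5.0)
        ],
        n_frames=12, calibration=cal_small, seed=19,
    )
    _, frames = simulate_scene(config)
    est = estimate_drift_dark(frames, PARAMS)
    mean_speed_px = 100.0 / 30.0 / 0.86  # ~3.9 px/frame
    assert np.hypot(*est.vector) < mean_speed_px / 3


def test_dark_drift_static_scene_is_zero(static_scene):
    config, truth, frames = static_scene
    est = estimate_drift_dark(frames, PARAMS)
    # static cells produce no above-threshold vectors: either no drift
    # signal at all, or a numerically zero vector
    assert np.hypot(*est.vector) < 0.1


def test_drift_correction_is_involutive():
    regions = [
        MotionRegion(mask=np.ones((2, 2), bool), area_px=4, mean_vector=(1.5, -0.5)),
        MotionRegion(mask=np.ones((2, 2), bool), area_px=4, mean_vector=(0.0, 2.0)),
    ]
    d = DriftEstimate(vector=(0.7, -0.2), support=5, mode="consensus")
    minus_d = DriftEstimate(vector=(-0.7, 0.2), support=5, mode="consensus")
    out = apply_drift_correction(apply_drift_correction(regions, d), minus_d)
    for before, after in zip(regions, out):
        assert after.mean_vector == pytest.approx(before.mean_vector)


def test_drift_correction_mode_none_is_identity():
    regions = [
        MotionRegion(mask=np.ones((2, 2), bool), area_px=4, mean_vector=(1.0, 1.0))
    ]
    out = apply_drift_correction(
        regions, DriftEstimate(vector=(0.0, 0.0), support=0, mode="none")
    )
    assert out[0].mean_vector == regions[0].mean_vector


def test_static_scene_speed_series_is_zero_or_missing(static_scene):
    config, truth, frames = static_scene
    series = frame_pair_speeds(frames, PARAMS)
    valid = series["mean_speed_um_s"].dropna()
    assert (valid < 5.0).all()


def test_speed_series_recovers_swimmer_speed(swimmer_scene):
    config, truth, frames = swimmer_scene
    series = frame_pair_speeds(frames, PARAMS, drift_policy="none")
    assert series["mean_speed_um_s"].mean() == pytest.approx(100.0, rel=0.15)


def test_consensus_correction_recovers_speed_under_drift(drift_scene):
    config, truth, frames = drift_scene
    series = frame_pair_speeds(frames, PARAMS)
    assert series["mean_speed_um_s"].mean() == pytest.approx(100.0, rel=0.20)
    assert series["drift_dx_px"].mean() == pytest.approx(2.0, abs=0.3)
    assert series["drift_dy_px"].mean() == pytest.approx(0.0, abs=0.3)


def test_aligned_swimmers_refuse_consensus_correction(cal_small):
    # 100% collectively moving cells: consensus must not cancel the signal
    from microswim import ParticlePopulation, SceneConfig, simulate_scene

    config = SceneConfig(
        populations=[
            ParticlePopulation(
                "swimmer", 12, speed_um_s=100.0, speed_sd_um_s=3.0,
                heading_mode=("fixed", 90.0), radius_um=5.0,
            )
        ],
        n_frames=10,
        calibration=cal_small,
        seed=21,
    )
    _, frames = simulate_scene(config)
    series = frame_pair_speeds(frames, PARAMS)
    assert (series["drift_dx_px"] == 0).all() and (series["drift_dy_px"] == 0).all()
    assert series["mean_speed_um_s"].mean() == pytest.approx(100.0, rel=0.15)


def test_speed_series_scales_with_calibration(swimmer_scene):
    from microswim import CalibrationState, FrameSequence

    config, truth, frames = swimmer_scene
    sub = FrameSequence(frames=frames.frames[:6], calibration=config.calibration)
    base = frame_pair_speeds(sub, PARAMS, drift_policy="none")
    cal2 = CalibrationState(
        2 * config.calibration.um_per_px,
        config.calibration.frame_rate,
        config.calibration.frame_width_px,
        config.calibration.frame_height_px,
    )
    doubled = frame_pair_speeds(
        FrameSequence(frames=frames.frames[:6], calibration=cal2),
        PARAMS, drift_policy="none",
    )
    assert doubled["mean_speed_um_s"].mean() == pytest.approx(
        2 * base["mean_speed_um_s"].mean()
    )
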