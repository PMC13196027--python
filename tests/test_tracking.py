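"""Bottom-up pipeline: segmentation, detection, area filter, linking."""

import itertools

import numpy as np
import pytest

from microswim import (
    CalibrationState,
    Detection,
    LinkParams,
    SegmentationParams,
    Track,
    detect_cells,
    filter_by_area_percentile,
    link_detections,
    segment_frame,
    track_table,
)
from microswim.tracking import tracks_from_jsonl, tracks_to_jsonl


def _disk_frame(centers, radius=5.8, shape=(160, 208), background=0.2, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    frame = np.full(shape, background)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cx, cy in centers:
        frame += 0.6 * np.clip(radius + 0.5 - np.hypot(xx - cx, yy - cy), 0, 1)
    if noise:
        frame += rng.normal(0, noise, shape)
    return frame.clip(0, 1)


def test_uniform_frame_gives_empty_mask():
    mask = segment_frame(np.full((80, 80), 0.4))
    assert not mask.any()


def test_mask_overlaps_rendered_disk():
    frame = _disk_frame([(100, 80)], noise=0.02)
    mask = segment_frame(frame)
    yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
    truth = np.hypot(xx - 100, yy - 80) <= 5.8
    iou = (mask & truth).sum() / (mask | truth).sum()
    assert iou > 0.6


def test_polarity_flag_recovers_dark_cells_on_bright_background():
    frame = _disk_frame([(100, 80)], noise=0.0)
    inverted = frame.max() - frame
    mask = segment_frame(frame)
    mask_inv = segment_frame(inverted, SegmentationParams(invert=True))
    assert np.array_equal(mask, mask_inv)


def test_detect_cells_empty_mask():
    frame = np.full((60, 60), 0.2)
    assert detect_cells(np.zeros((60, 60), bool), frame) == []


@pytest.mark.parametrize("canny_on", ["mask", "raw"])
def test_detect_cells_counts_and_centroids(canny_on):
    centers = [(40.3, 30.7), (120.2, 100.4), (170.6, 40.1)]
    frame = _disk_frame(centers, noise=0.02)
    params = SegmentationParams(canny_on=canny_on)
    mask = segment_frame(frame, params)
    dets = detect_cells(mask, frame, params)
    dets = [d for d in dets if d.area_px > 20]  # drop noise specks
    assert len(dets) == 3
    for cx, cy in centers:
        err = min(np.hypot(d.centroid[0] - cx, d.centroid[1] - cy) for d in dets)
        assert err < 0.5


def _oracle_percentile_filter(areas, low, high):
    """Order-statistics oracle for the pooled quantile rule."""
    s = np.sort(np.asarray(areas, float))
    n = len(s)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    q_low, q_high = q(low), q(1 - high)
    return [a for a in areas if q_low < a <= q_high]


def test_area_percentile_filter_matches_order_statistics_oracle():
    areas = list(range(1, 11))
    dets = [Detection(frame_index=0, centroid=(float(a), 1.0), area_px=float(a))
            for a in areas]
    kept = filter_by_area_percentile(dets, 0.10, 0.10)
    assert sorted(d.area_px for d in kept) == [2, 3, 4, 5, 6, 7, 8, 9]
    assert sorted(d.area_px for d in kept) == sorted(
        _oracle_percentile_filter(areas, 0.10, 0.10)
    )


def test_area_percentile_filter_random_samples_match_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        areas = rng.uniform(5, 400, rng.integers(10, 60))
        dets = [Detection(frame_index=0, centroid=(0.0, 0.0), area_px=float(a))
                for a in areas]
        kept = filter_by_area_percentile(dets, 0.10, 0.10)
        oracle = _oracle_percentile_filter(areas, 0.10, 0.10)
        assert sorted(d.area_px for d in kept) == sorted(oracle)
        assert len(kept) <= 0.8 * len(areas) + 2


def test_area_filter_zero_fractions_is_identity():
    dets = [Detection(frame_index=0, centroid=(0.0, 0.0), area_px=float(a))
            for a in [1, 2, 3]]
    assert filter_by_area_percentile(dets, 0.0, 0.0) == dets


def test_area_filter_equal_areas_all_retained():
    dets = [Detection(frame_index=0, centroid=(0.0, 0.0), area_px=42.0)
            for _ in range(12)]
    assert len(filter_by_area_percentile(dets, 0.10, 0.10)) == 12


def test_area_filter_disabled_below_ten_detections():
    dets = [Detection(frame_index=0, centroid=(0.0, 0.0), area_px=float(a))
            for a in [1, 100]]
    with pytest.warns(UserWarning, match="disabled"):
        kept = filter_by_area_percentile(dets)
    assert len(kept) == 2


def test_single_detection_per_frame_yields_single_track():
    dets = [Detection(frame_index=f, centroid=(10.0 + f, 20.0), area_px=30.0)
            for f in range(8)]
    tracks = link_detections(dets, LinkParams(gate_px=5))
    assert len(tracks) == 1
    assert len(tracks[0]) == 8


def test_gap_longer_than_max_skip_splits_track():
    dets = [Detection(frame_index=f, centroid=(10.0, 20.0), area_px=30.0)
            for f in list(range(5)) + list(range(9, 14))]
    tracks = link_detections(dets, LinkParams(gate_px=5, max_skip=3))
    assert len(tracks) == 2


def test_gap_within_max_skip_keeps_identity():
    dets = [Detection(frame_index=f, centroid=(10.0 + 2 * f, 20.0), area_px=30.0)
            for f in [0, 1, 2, 5, 6]]
    tracks = link_detections(dets, LinkParams(gate_px=8, max_skip=3))
    assert len(tracks) == 1
    assert [p.frame_index for p in tracks[0].points] == [0, 1, 2, 5, 6]


def _brute_force_link(per_frame, gate):
    """Oracle: per-frame exhaustive minimum-cost assignment, same lifecycle."""
    live = []  # list of [id, points, velocity, misses]
    finished = []
    next_id = 0
    frames = sorted(per_frame)
    for f in range(frames[0], frames[-1] + 1):
        dets = per_frame.get(f, [])
        best, best_cost = None, np.inf
        k = min(len(live), len(dets))
        for tr_subset in itertools.permutations(range(len(live)), k):
            for det_subset in itertools.combinations(range(len(dets)), k):
                cost, ok = 0.0, True
                for ti, di in zip(tr_subset, det_subset):
                    tid, pts, vel, misses = live[ti]
                    pred = np.asarray(pts[-1][1]) + vel * (misses + 1)
                    c = np.hypot(*(pred - np.asarray(dets[di])))
                    if c > gate:
                        ok = False
                        break
                    cost += c
                if ok and cost < best_cost:
                    best_cost, best = cost, list(zip(tr_subset, det_subset))
        # also consider leaving some unmatched: with well-separated particles
        # the full matching above is optimal whenever feasible
        matched_t, matched_d = set(), set()
        if best is not None:
            for ti, di in best:
                tid, pts, vel, misses = live[ti]
                prev = np.asarray(pts[-1][1])
                gap = f - pts[-1][0]
                live[ti][2] = (np.asarray(dets[di]) - prev) / gap
                pts.append((f, dets[di]))
                live[ti][3] = 0
                matched_t.add(ti)
                matched_d.add(di)
        keep = []
        for i, t in enumerate(live):
            if i not in matched_t:
                t[3] += 1
                if t[3] > 3:
                    finished.append(t)
                    continue
            keep.append(t)
        live = keep
        for di, d in enumerate(dets):
            if di not in matched_d:
                live.append([next_id, [(f, d)], np.zeros(2), 0])
                next_id += 1
    finished.extend(live)
    return [
        frozenset((f, tuple(np.round(p, 6))) for f, p in t[1])
        for t in finished
        if len(t[1]) >= 2
    ]


@pytest.mark.parametrize("seed", range(25))
def test_linking_matches_exhaustive_assignment_oracle(seed):
    """Well-separated particles: linker output equals brute-force min-cost
    linking and reproduces the true particle partition with no swaps."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 6))
    grid = [(200.0 + 300 * i, 200.0 + 300 * j) for i in range(3) for j in range(2)]
    starts = [grid[k] for k in rng.choice(len(grid), n, replace=False)]
    vels = rng.uniform(-3, 3, (n, 2))
    n_frames = 15
    per_frame = {}
    truth_sets = []
    for i in range(n):
        pts = []
        for f in range(n_frames):
            p = (starts[i][0] + vels[i][0] * f, starts[i][1] + vels[i][1] * f)
            per_frame.setdefault(f, []).append(p)
            pts.append((f, tuple(np.round(p, 6))))
        truth_sets.append(frozenset(pts))
    dets = [
        Detection(frame_index=f, centroid=p, area_px=30.0)
        for f, plist in per_frame.items()
        for p in plist
    ]
    tracks = link_detections(dets, LinkParams(gate_px=15, max_skip=3))
    got = {
        frozenset((p.frame_index, tuple(np.round(p.centroid, 6))) for p in t.points)
        for t in tracks
    }
    oracle = set(_brute_force_link(per_frame, gate=15))
    assert got == oracle
    assert got == set(truth_sets)  # zero identity swaps


def test_linking_is_invariant_to_detection_order_within_frame():
    rng = np.random.default_rng(11)
    dets = []
    for f in range(10):
        pts = [(50.0 + 2 * f, 50.0), (150.0 - 2 * f, 150.0), (250.0, 50.0 + 3 * f)]
        for p in pts:
            dets.append(Detection(frame_index=f, centroid=p, area_px=30.0))
    shuffled = dets.copy()
    rng.shuffle(shuffled)
    a = link_detections(dets, LinkParams(gate_px=10))
    b = link_detections(shuffled, LinkParams(gate_px=10))
    key = lambda tr: frozenset(
        (p.frame_index, p.centroid) for p in tr.points
    )
    assert {key(t) for t in a} == {key(t) for t in b}


def test_track_table_step_speed_arithmetic():
    cal = CalibrationState(1.0, 30.0, 400, 400)
    tr = Track(
        track_id=0,
        points=[
            Detection(frame_index=0, centroid=(0.0, 0.0), area_px=10.0),
            Detection(frame_index=1, centroid=(3.0, 4.0), area_px=10.0),
        ],
    )
    table = track_table([tr], cal)
    assert len(table) == 2
    assert np.isnan(table.step_speed_um_s.iloc[0])
    assert table.step_speed_um_s.iloc[1] == pytest.approx(150.0)


def test_track_table_empty_is_header_only():
    cal = CalibrationState(1.0, 30.0, 400, 400)
    table = track_table([], cal)
    assert len(table) == 0
    assert "step_speed_um_s" in table.columns


def test_track_table_row_count_is_total_points(swimmer_scene):
    config, truth, frames = swimmer_scene
    dets = []
    for i in range(10):
        f = frames.as_float(i)
        dets.extend(detect_cells(segment_frame(f), f, frame_index=i))
    dets = filter_by_area_percentile(dets)
    tracks = link_detections(dets, LinkParams(gate_px=12))
    table = track_table(tracks, config.calibration)
    assert len(table) == sum(len(t) for t in tracks)


def test_end_to_end_exact_recovery_when_well_separated():
    """Spacing > 2x gate and no boundary wraps: track count equals the
    true particle count and the mean speed is recovered within 10%."""
    from microswim import ParticlePopulation, SceneConfig, simulate_scene

    cal = CalibrationState(0.86, 30.0, 320, 240)
    config = SceneConfig(
        populations=[
            ParticlePopulation("swimmer", 5, speed_um_s=100, speed_sd_um_s=5,
                               turn_sd_deg_per_frame=4, radius_um=5.0)
        ],
        n_frames=20, calibration=cal, seed=46,
    )
    truth, frames = simulate_scene(config)
    assert not truth.wrapped.any()  # scene chosen free of boundary wraps
    dets = []
    for i in range(len(frames)):
        f = frames.as_float(i)
        dets.extend(detect_cells(segment_frame(f), f, frame_index=i))
    dets = filter_by_area_percentile(dets)
    tracks = link_detections(dets, LinkParams(gate_px=12))
    assert len(tracks) == truth.n_particles
    speeds = np.concatenate([t.step_speeds_um_s(cal) for t in tracks])
    assert np.mean(speeds) == pytest.approx(100.0, rel=0.10)


def test_end_to_end_speed_recovery_at_density(swimmer_scene):
    """Denser wrapping scene: fragments appear but speed stays accurate."""
    config, truth, frames = swimmer_scene
    cal = config.calibration
    dets = []
    for i in range(len(frames)):
        f = frames.as_float(i)
        dets.extend(detect_cells(segment_frame(f), f, frame_index=i))
    dets = filter_by_area_percentile(dets)
    tracks = link_detections(dets, LinkParams(gate_px=12))
    assert len(tracks) >= truth.n_particles
    speeds = np.concatenate([t.step_speeds_um_s(cal) for t in tracks if len(t) >= 3])
    assert np.mean(speeds) == pytest.approx(100.0, rel=0.10)


def test_tracks_jsonl_round_trip():
    tracks = [
        Track(
            track_id=3,
            points=[
                Detection(frame_index=0, centroid=(1.5, 2.5), area_px=20.0),
                Detection(frame_index=2, centroid=(3.5, 4.5), area_px=21.0),
            ],
        )
    ]
    text = tracks_to_jsonl(tracks)
    back = tracks_from_jsonl(text)
    assert back[0].track_id == 3
    assert [p.centroid for p in back[0].points] == [(1.5, 2.5), (3.5, 4.5)]
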