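"""Per-cell and per-step motility metrics: closed forms, counting oracles,
and geometric invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from motility3d.io import TrackSet
from motility3d.metrics import (
    MetricParams,
    angle_histogram,
    cell_speed,
    compute_all,
    confinement,
    displacement_speed,
    fraction_below,
    meandering_ratio,
    msd_slope,
    persistence_from_speeds,
    persistence_table,
    speed_angle_profile,
    step_distances,
    step_table,
    turning_angles,
    volume_rate,
)

from conftest import make_track, random_walk_track


# ---------------------------------------------------------------- distances & speeds


def test_step_distances_closed_forms():
    tr = make_track([[0, 0, 0], [3, 4, 0], [3, 4, 0], [4, 5, 1]])
    np.testing.assert_allclose(step_distances(tr), [5.0, 0.0, np.sqrt(3)])


def test_cell_speed_examples(straight_track, out_and_back_track):
    assert cell_speed(straight_track) == pytest.approx(6.0)  # 18 µm / 3 min
    assert cell_speed(out_and_back_track) == pytest.approx(6.0)
    assert cell_speed(make_track(np.zeros((4, 3)))) == 0.0


def test_displacement_speed_examples(straight_track, out_and_back_track, l_track):
    assert displacement_speed(straight_track) == pytest.approx(6.0)
    assert displacement_speed(out_and_back_track) == pytest.approx(0.0)
    assert displacement_speed(l_track) == pytest.approx(9 * np.sqrt(2) / 3)


def test_meandering_ratio_examples(straight_track, out_and_back_track, l_track):
    assert meandering_ratio(straight_track) == pytest.approx(1.0)
    assert meandering_ratio(out_and_back_track) == pytest.approx(0.0)
    assert meandering_ratio(l_track) == pytest.approx(np.sqrt(2) / 2)
    assert np.isnan(meandering_ratio(make_track(np.zeros((3, 3)))))


def test_meander_speed_displacement_identity():
    """meandering_ratio x cell_speed == displacement_speed (algebraic identity)."""
    rng = np.random.default_rng(0)
    for i in range(50):
        tr = random_walk_track(rng, n_points=int(rng.integers(3, 25)))
        assert meandering_ratio(tr) * cell_speed(tr) == pytest.approx(
            displacement_speed(tr), rel=1e-12, abs=1e-12
        )


# ---------------------------------------------------------------- turning angles


@pytest.mark.parametrize(
    "second_leg,expected",
    [([0, 9, 0], 90.0), ([-9, 0, 0], 180.0), ([9, 0, 0], 0.0)],
)
def test_turning_angle_geometry(second_leg, expected):
    tr = make_track([[0, 0, 0], [9, 0, 0], [9 + second_leg[0], second_leg[1], second_leg[2]]])
    df = turning_angles(tr)
    assert df["angle_deg"].iloc[0] == pytest.approx(expected, abs=1e-9)


def test_turning_angle_slow_steps_flagged_excluded():
    tr = make_track([[0, 0, 0], [0.5, 0, 0], [0.5, 1.0, 0]], dt=90.0)  # ~0.5 µm/min
    df = turning_angles(tr, min_speed=1.0)
    assert not df["included"].iloc[0]
    df2 = turning_angles(tr, min_speed=0.0)
    assert df2["included"].iloc[0]


def test_turning_angle_zero_step_skipped():
    tr = make_track([[0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0]])
    df = turning_angles(tr)
    assert len(df) == 1  # only the fully defined triple
    assert df.attrs["n_zero_steps"] == 1


def test_angle_histogram_sums_to_one_and_places_mass():
    tr = make_track([[0, 0, 0], [9, 0, 0], [9, 9, 0], [0, 9, 0]])  # two 90° turns
    steps = step_table(TrackSet([tr]))
    h = angle_histogram(steps, bin_width=9.0)
    assert h["frequency"].sum() == pytest.approx(1.0)
    assert h.loc[h["bin_lo_deg"] == 90.0, "frequency"].iloc[0] == pytest.approx(1.0)


def test_angle_histogram_empty_errors():
    tr = make_track([[0, 0, 0], [0.1, 0, 0], [0.1, 0.1, 0]])  # all below min speed
    steps = step_table(TrackSet([tr]))
    with pytest.raises(ValueError):
        angle_histogram(steps)


def test_isotropic_walk_angles_follow_sine_law():
    """Isotropic 3D headings give turning angles with density sin(θ)/2."""
    rng = np.random.default_rng(42)
    tracks = [
        random_walk_track(rng, n_points=200, step_scale=9.0, cell_id=f"c{i}")
        for i in range(60)
    ]
    steps = step_table(TrackSet(tracks), min_speed=0.0)
    h = angle_histogram(steps, bin_width=9.0)
    lo, hi = np.radians(h["bin_lo_deg"]), np.radians(h["bin_hi_deg"])
    expected = (np.cos(lo) - np.cos(hi)) / 2.0
    np.testing.assert_allclose(h["frequency"], expected, atol=0.012)


def test_fraction_below_per_cell():
    tr45 = make_track([[0, 0, 0], [9, 0, 0], [9 + 9 / np.sqrt(2), 9 / np.sqrt(2), 0]],
                      cell_id="sharp")
    tr135 = make_track([[0, 0, 0], [9, 0, 0], [9 - 9 / np.sqrt(2), 9 / np.sqrt(2), 0]],
                       cell_id="blunt")
    steps = step_table(TrackSet([tr45, tr135]))
    out = fraction_below(steps, threshold=90.0).set_index("cell_id")["fraction"]
    assert out["sharp"] == 1.0
    assert out["blunt"] == 0.0


def test_speed_angle_profile_constant_speed():
    tr = make_track([[0, 0, 0], [9, 0, 0], [9, 9, 0], [18, 9, 0]])
    prof = speed_angle_profile(step_table(TrackSet([tr])), bin_width=9.0)
    occupied = prof[prof["count"] > 0]
    np.testing.assert_allclose(occupied["mean_speed"], 6.0)
    np.testing.assert_allclose(occupied["sd_speed"], 0.0)
    np.testing.assert_allclose(occupied["sd_over_8"], 0.0)


def test_speed_angle_profile_detects_fast_straight_slow_turny():
    """Fast persistent + slow reversing populations give a decreasing
    speed-vs-angle trend."""
    rng = np.random.default_rng(3)
    from motility3d.simulate import WalkerSpec, generate_track

    fast = WalkerSpec("persistent", speed_mean=9.0, speed_sd=0.5, kappa=8.0, n_steps=30)
    slow = WalkerSpec("back_and_forth", speed_mean=2.5, speed_sd=0.5, kappa=8.0,
                      reversal_prob=0.8, n_steps=30)
    tracks = [generate_track(fast, f"f{i}", "f", "x", rng) for i in range(40)]
    tracks += [generate_track(slow, f"s{i}", "f", "x", rng) for i in range(40)]
    prof = speed_angle_profile(step_table(TrackSet(tracks)), bin_width=9.0)
    first = prof[prof["bin_lo_deg"] < 45]["mean_speed"].mean()
    last = prof[prof["bin_lo_deg"] >= 135]["mean_speed"].mean()
    assert first > last


# ---------------------------------------------------------------- persistence


def test_persistence_counting_oracle():
    """Direct counting on a hand-built speed sequence.

    Speeds alternate between bin 0 and bin 5, except for one repeated bin-0
    pair, so counts can be tallied by hand.
    """
    speeds = np.array([0.5, 0.4, 5.5, 0.5, 5.5, 0.5])
    # pairs: (0.5,0.4) (0.4,5.5) (5.5,0.5) (0.5,5.5) (5.5,0.5)  -> m = 5
    pt = persistence_from_speeds(speeds, max_bin=12.0)
    row0 = pt.table.iloc[0]
    assert pt.m == 5
    assert row0["m_b"] == 3 and row0["m_a"] == 3 and row0["m_ab"] == 1
    assert row0["ratio"] == pytest.approx(5 * 1 / 9)
    row5 = pt.table.iloc[5]
    assert row5["m_b"] == 2 and row5["m_a"] == 2 and row5["m_ab"] == 0
    assert row5["ratio"] == 0.0


def test_persistence_independent_speeds_ratio_one():
    rng = np.random.default_rng(11)
    speeds = rng.uniform(0, 10, size=100_000)
    pt = persistence_from_speeds(speeds, max_bin=12.0)
    occupied = pt.table.dropna(subset=["ratio"])
    occupied = occupied[occupied["m_b"] > 100]
    np.testing.assert_allclose(occupied["ratio"], 1.0, atol=0.1)


def test_persistence_autocorrelated_speeds_ratio_above_one():
    rng = np.random.default_rng(12)
    n = 20_000
    s = np.empty(n)
    s[0] = 5.0
    for i in range(1, n):  # AR(1), strongly autocorrelated
        s[i] = np.clip(5.0 + 0.97 * (s[i - 1] - 5.0) + rng.normal(0, 0.4), 0, 11.9)
    pt = persistence_from_speeds(s, max_bin=12.0)
    occupied = pt.table.dropna(subset=["ratio"])
    occupied = occupied[occupied["m_b"] > 50]
    assert (occupied["ratio"] > 1.5).all()


def test_persistence_constant_speed_single_bin():
    pt = persistence_from_speeds(np.full(10, 3.5), max_bin=12.0)
    row = pt.table.iloc[3]
    assert row["ratio"] == pytest.approx(1.0)
    assert pt.table["ratio"].count() == 1  # all other bins undefined


def test_persistence_trackset_requires_pairs(straight_track):
    with pytest.raises(ValueError):
        persistence_table(TrackSet([make_track([[0, 0, 0], [1, 0, 0]])]))
    pt = persistence_table(TrackSet([straight_track]))
    assert pt.m == 1


# ---------------------------------------------------------------- MSD slope


def test_msd_slope_ballistic_exactly_two():
    tr = make_track(np.arange(8)[:, None] * [9.0, 0, 0])
    assert msd_slope(tr) == pytest.approx(2.0, abs=1e-12)


def test_msd_slope_respects_time_cap():
    # straight for 10.5 min then frozen; the frozen tail must not dilute the slope
    xyz = np.vstack([np.arange(8)[:, None] * [9.0, 0, 0], np.full((5, 3), [63.0, 0, 0])])
    tr = make_track(xyz)
    assert msd_slope(tr, max_elapsed_min=10.5) == pytest.approx(2.0, abs=1e-12)
    assert msd_slope(tr, max_elapsed_min=30.0) < 2.0


def test_msd_slope_zero_displacement_point_excluded():
    tr = make_track([[0, 0, 0], [9, 0, 0], [0, 0, 0], [9, 9, 0], [0, 9, 0]])
    # the return-to-origin point at k=2 must be dropped, not crash
    assert np.isfinite(msd_slope(tr))


def test_msd_slope_undefined_below_three_points():
    assert np.isnan(msd_slope(make_track([[0, 0, 0], [1, 0, 0]])))


def test_msd_slope_rigid_motion_invariance():
    rng = np.random.default_rng(5)
    tr = random_walk_track(rng, n_points=8)
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    moved = make_track(tr.xyz @ rot.T + np.array([100.0, -50.0, 3.0]))
    assert msd_slope(moved) == pytest.approx(msd_slope(tr), rel=1e-9)


def test_brownian_ensemble_median_slope_near_one():
    rng = np.random.default_rng(2024)
    slopes = [
        msd_slope(random_walk_track(rng, n_points=15, step_scale=5.0, cell_id=f"c{i}"))
        for i in range(500)
    ]
    assert abs(np.nanmedian(slopes) - 1.0) < 0.15


# ---------------------------------------------------------------- confinement


def test_confinement_stationary_cell():
    tr = make_track(np.zeros((11, 3)), dt=90.0)  # 10 steps of 90 s
    ratio, ctime = confinement(tr)
    assert ratio == pytest.approx(1.0)
    # censored exit times: mean over anchors of (T - t_i), in minutes
    T = tr.t[-1]
    expected = np.mean(T - tr.t) / 60.0
    assert ctime == pytest.approx(expected)


def test_confinement_fast_straight_mover_zero():
    tr = make_track(np.arange(10)[:, None] * [9.0, 0, 0], dt=90.0)
    ratio, ctime = confinement(tr)
    assert ratio == 0.0
    assert ctime == pytest.approx(90.0 / 60.0 * (9 / 10) + 0.0 / 10, rel=1e-9)


def test_confinement_short_dwell_not_counted():
    # 90 s within the ball then out: dwell 90 s < 150 s -> not confined
    tr = make_track([[0, 0, 0], [2, 0, 0], [9, 0, 0], [18, 0, 0]], dt=90.0)
    ratio, _ = confinement(tr, radius=5.0, min_dwell_s=150.0)
    assert ratio == 0.0


def test_confinement_long_dwell_counts_whole_dwell():
    # stays within 5 µm of the first point for 180 s (> 150 s) then leaves
    tr = make_track([[0, 0, 0], [2, 0, 0], [4, 0, 0], [14, 0, 0]], dt=90.0)
    ratio, _ = confinement(tr, radius=5.0, min_dwell_s=150.0)
    assert ratio == pytest.approx(180.0 / 270.0)


# ---------------------------------------------------------------- patrolled volume


def brute_force_volume(tr, voxel, reach, domain):
    """Exhaustive scan of every voxel centre against the sampled polyline."""
    lo, hi = tr.xyz.min(axis=0), tr.xyz.max(axis=0)
    shift = domain / 2 - (lo + hi) / 2
    pts = [tr.xyz[0] + shift]
    for a, b in zip(tr.xyz[:-1] + shift, tr.xyz[1:] + shift):
        seg = b - a
        length = np.linalg.norm(seg)
        n = max(1, int(np.ceil(length / (voxel / 2))))
        pts.extend(a + (k / n) * seg for k in range(1, n + 1))
    pts = np.asarray(pts)
    n_vox = int(round(domain / voxel))
    centres = (np.arange(n_vox) + 0.5) * voxel
    gx, gy, gz = np.meshgrid(centres, centres, centres, indexing="ij")
    grid = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    d2 = ((grid[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    hit = (d2 < reach**2).any(axis=1)
    return hit.sum() * voxel**3


def voxel_count(rate, duration_s, voxel=2.5):
    return round(rate * duration_s / voxel**3)


def test_volume_stationary_position_is_reach_ball():
    tr = make_track([[0, 0, 0], [0, 0, 0.0]], t=[0.0, 90.0])
    v = volume_rate(tr, voxel=2.5, reach=5.0, domain=50.0)
    assert voxel_count(v, 90.0) == round(brute_force_volume(tr, 2.5, 5.0, 50.0) / 2.5**3)
    assert v * 90.0 == pytest.approx(4 / 3 * np.pi * 5**3, rel=0.25)  # voxelized ball


def test_volume_straight_segment_matches_brute_force():
    tr = make_track([[0, 0, 0], [30.0, 0, 0]], t=[0.0, 90.0])
    v = volume_rate(tr, voxel=2.5, reach=5.0, domain=50.0)
    assert voxel_count(v, 90.0) == round(brute_force_volume(tr, 2.5, 5.0, 50.0) / 2.5**3)


def test_volume_random_tracks_match_brute_force():
    rng = np.random.default_rng(9)
    for i in range(10):
        tr = random_walk_track(rng, n_points=int(rng.integers(2, 6)), step_scale=4.0)
        rate = volume_rate(tr, voxel=2.5, reach=5.0, domain=50.0)
        expected = round(brute_force_volume(tr, 2.5, 5.0, 50.0) / 2.5**3)
        assert voxel_count(rate, tr.duration_s) == expected


def test_volume_rate_halves_with_doubled_duration():
    xyz = [[0, 0, 0], [9, 0, 0], [18, 0, 0]]
    r1 = volume_rate(make_track(xyz, dt=90.0))
    r2 = volume_rate(make_track(xyz, dt=180.0))
    assert r2 == pytest.approx(r1 / 2)


def test_volume_rate_errors():
    big = make_track([[0, 0, 0], [500.0, 0, 0]])
    with pytest.raises(ValueError, match="exceeds"):
        volume_rate(big, domain=400.0)


# ---------------------------------------------------------------- invariances & assembly


def test_metrics_invariant_under_rigid_motion():
    rng = np.random.default_rng(21)
    tr = random_walk_track(rng, n_points=12)
    rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
    moved = make_track(tr.xyz @ rot.T + 50.0)
    for f in (cell_speed, displacement_speed, meandering_ratio):
        assert f(moved) == pytest.approx(f(tr), rel=1e-9)
    np.testing.assert_allclose(
        turning_angles(moved)["angle_deg"], turning_angles(tr)["angle_deg"], atol=1e-8
    )
    assert confinement(moved)[0] == pytest.approx(confinement(tr)[0])


def test_compute_all_matches_individual_operations(small_trackset):
    metrics, steps = compute_all(small_trackset)
    assert len(metrics) == 3
    tr = small_trackset.tracks[0]
    row = metrics.set_index(["frame_id", "cell_id"]).loc[(tr.frame_id, tr.cell_id)]
    assert row["cell_speed"] == pytest.approx(cell_speed(tr))
    assert row["meandering_ratio"] == pytest.approx(meandering_ratio(tr))
    assert row["volume_rate"] == pytest.approx(volume_rate(tr))


def test_compute_all_marks_undefined_not_zero():
    ts = TrackSet([make_track([[0, 0, 0], [9, 0, 0]])])
    metrics, _ = compute_all(ts)
    assert np.isnan(metrics["msd_slope"].iloc[0])
    assert metrics["cell_speed"].iloc[0] == pytest.approx(6.0)
    assert metrics.attrs["n_msd_undefined"] == 1


def test_compute_all_deterministic(small_trackset):
    m1, s1 = compute_all(small_trackset)
    m2, s2 = compute_all(small_trackset)
    assert m1.equals(m2) and s1.equals(s2)
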