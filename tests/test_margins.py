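"""Cutting-plane isolation, zone classification, summaries, alerts, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navmargin.behavior import evaluate_plane_analytic, ideal_pose
from navmargin.grids import DistanceField
from navmargin.margins import (
    MarginPlaneMap,
    PlaneSamplingSpec,
    PointerPose,
    ZoneRule,
    classify_point,
    classify_points,
    evaluate_alert,
    evaluate_plane,
    isolate_area,
    render_colormap,
    summarize_plane,
)

ZONE_EXAMPLES = [
    (-0.5, 7.0, "R"),
    (1.5, 7.0, "O3"),
    (3.0, 7.5, "G"),
    (3.0, -0.2, "Y1"),
    (2.0, 7.0, "O3"),  # d_ica = 2 is still orange (adequate is > 2)
    (3.0, 5.0, "G"),  # 5-10 band is closed
    (3.0, 10.0, "G"),
    (1.0, -1.0, "O1"),
    (1.0, 3.0, "O2"),
    (1.0, 12.0, "O4"),
    (3.0, 3.0, "Y2"),
    (3.0, 11.0, "B"),
]


@pytest.mark.parametrize("d_ica, d_tumor, expected", ZONE_EXAMPLES)
def test_zone_classification_examples(d_ica, d_tumor, expected):
    assert classify_point(d_ica, d_tumor) == expected


def test_nan_distance_rejected():
    with pytest.raises(ValueError, match="finite"):
        classify_point(np.nan, 1.0)


@settings(max_examples=300, derandomize=True)
@given(
    d_ica=st.one_of(st.floats(-20, 20), st.sampled_from([0.0, 2.0, -0.0])),
    d_tumor=st.one_of(st.floats(-20, 20), st.sampled_from([0.0, 5.0, 10.0])),
)
def test_zone_partition_total_and_exclusive(d_ica, d_tumor):
    """Every finite distance pair maps to exactly one of the nine codes."""
    code = classify_point(d_ica, d_tumor)
    rule = ZoneRule()
    conditions = {
        "R": d_ica <= 0,
        "O1": 0 < d_ica <= rule.ica_danger and d_tumor <= 0,
        "O2": 0 < d_ica <= rule.ica_danger and 0 < d_tumor < rule.tumor_near,
        "O3": 0 < d_ica <= rule.ica_danger and rule.tumor_near <= d_tumor <= rule.tumor_far,
        "O4": 0 < d_ica <= rule.ica_danger and d_tumor > rule.tumor_far,
        "Y1": d_ica > rule.ica_danger and d_tumor <= 0,
        "Y2": d_ica > rule.ica_danger and 0 < d_tumor < rule.tumor_near,
        "G": d_ica > rule.ica_danger and rule.tumor_near <= d_tumor <= rule.tumor_far,
        "B": d_ica > rule.ica_danger and d_tumor > rule.tumor_far,
    }
    fired = [c for c, ok in conditions.items() if ok]
    assert fired == [code]


def test_isolated_area_default_lattice():
    pose = PointerPose(tip=[0, 0, 0], shaft_axis=[1, 0, 0])
    grid = isolate_area(pose)
    assert grid.shape == (61, 23, 3)
    # coplanarity
    rel = grid.reshape(-1, 3) - pose.tip
    assert np.allclose(rel @ pose.plane_normal, 0.0, atol=1e-9)
    # extent
    assert np.isclose(np.linalg.norm(grid[-1, 11] - grid[0, 11]), 30.0)
    assert np.isclose(np.linalg.norm(grid[0, -1] - grid[0, 0]), 11.0)


def test_isolated_area_degenerate_spec():
    spec = PlaneSamplingSpec(length=2.0, half_width=2.0, step=2.0)
    grid = isolate_area(PointerPose(tip=[0, 0, 0], shaft_axis=[0, 1, 0]), spec)
    assert grid.shape == (2, 3, 3)


def test_roll_mirror_symmetry():
    p0 = PointerPose(tip=[1, 2, 3], shaft_axis=[1, 0, 0], roll=0.0)
    p180 = PointerPose(tip=[1, 2, 3], shaft_axis=[1, 0, 0], roll=180.0)
    g0 = isolate_area(p0)
    g180 = isolate_area(p180)
    assert np.allclose(g0, g180[:, ::-1], atol=1e-9)


def _ball_field(radius=6.0, spacing=1.0, n=41, center=(0.0, 0.0, 0.0)):
    ax = (np.arange(n) - n // 2) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    d = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2) - radius
    return DistanceField(spacing=spacing, origin=np.array([ax[0]] * 3), values=d)


def test_evaluate_plane_zones_and_flags():
    """A plane sliced through an analytic ball field picks up R points and
    the damaged flag; a remote plane is all B."""
    ica = _ball_field(radius=3.0)
    tumor = _ball_field(radius=3.0, center=(0.0, 0.0, -15.0))
    spec = PlaneSamplingSpec(length=10, half_width=2, step=0.5)
    through = PointerPose(tip=[-5, 0, 0], shaft_axis=[1, 0, 0])
    pm = evaluate_plane(through, tumor, ica, spec)
    assert np.sum(pm.zone == "R") >= 1
    assert summarize_plane(pm).ica_damaged

    far = PointerPose(tip=[-15, -15, 14], shaft_axis=[1, 0, 0], roll=0.0)
    spec2 = PlaneSamplingSpec(length=8, half_width=2, step=1.0)
    pm2 = evaluate_plane(far, tumor, ica, spec2)
    assert np.all(pm2.zone == "B")


def test_evaluate_plane_out_of_bounds_names_point():
    f = _ball_field()
    pose = PointerPose(tip=[18, 0, 0], shaft_axis=[1, 0, 0])
    with pytest.raises(ValueError, match="outside"):
        evaluate_plane(pose, f, f)


def test_plane_distances_match_brute_force(s2_model, s2_masks, s2_fields):
    """Interpolated plane distances agree with a brute-force search over
    boundary voxel centers of the mask, within one voxel."""
    from scipy import ndimage

    tumor_field, _ = s2_fields
    mask = s2_masks["tumor"].voxels
    boundary = mask & ~ndimage.binary_erosion(mask)
    surf_pts = tumor_field.index_to_world(np.argwhere(boundary))

    pose = ideal_pose(s2_model, "superior")
    grid = isolate_area(pose).reshape(-1, 3)
    rng = np.random.default_rng(5)
    pts = grid[rng.choice(len(grid), 50, replace=False)]
    d_field = tumor_field.sample(pts)
    for p, dv in zip(pts, d_field):
        brute = np.min(np.linalg.norm(surf_pts - p, axis=1))
        assert abs(abs(dv) - brute) <= 0.8 * np.sqrt(3)


def test_plane_distance_lipschitz(s2_model):
    """Distances along the sampled lattice vary no faster than the
    point spacing (1-Lipschitz plus interpolation slack)."""
    pose = ideal_pose(s2_model, "inferior")
    pm = evaluate_plane_analytic(pose, s2_model)
    step = PlaneSamplingSpec().step
    for d in (pm.d_tumor, pm.d_ica):
        assert np.max(np.abs(np.diff(d, axis=0))) <= step + 1e-6
        assert np.max(np.abs(np.diff(d, axis=1))) <= step + 1e-6


def _map_from(d_pairs):
    d_ica = np.array([[p[0] for p in d_pairs]])
    d_tumor = np.array([[p[1] for p in d_pairs]])
    grid = np.zeros(d_ica.shape + (3,))
    return MarginPlaneMap(
        grid=grid, d_tumor=d_tumor, d_ica=d_ica, zone=classify_points(d_ica, d_tumor)
    )


def test_summary_hand_counted():
    """4-point map {R, G, G, Y1}: fractions 0.25/0.5/0.25 and both the
    damaged and intratumoral flags set."""
    pm = _map_from([(-1.0, 7.0), (5.0, 7.0), (5.0, 8.0), (4.0, -1.0)])
    s = summarize_plane(pm)
    assert s.fractions["R"] == 0.25
    assert s.fractions["G"] == 0.5
    assert s.fractions["Y1"] == 0.25
    assert sum(s.fractions.values()) == pytest.approx(1.0, abs=1e-9)
    assert s.ica_damaged and s.intratumoral
    assert not s.adequate_margin


def test_summary_danger_zone_flag():
    pm = _map_from([(1.0, 7.0), (5.0, 7.0), (6.0, 7.0)])
    s = summarize_plane(pm)
    assert s.danger_zone and not s.ica_damaged and not s.ica_adequate


def test_summary_all_green():
    pm = _map_from([(5.0, 7.0)] * 6)
    s = summarize_plane(pm)
    assert s.fractions["G"] == 1.0
    assert s.adequate_margin and s.ica_adequate


def test_summary_flag_exclusivity(s2_model):
    pose = ideal_pose(s2_model, "superior")
    s = summarize_plane(evaluate_plane_analytic(pose, s2_model))
    assert [s.ica_damaged, s.danger_zone, s.ica_adequate].count(True) == 1
    assert s.intratumoral == (not s.adequate_margin)


def test_alert_states_and_boundaries():
    f = _ball_field(radius=3.0)
    assert evaluate_alert([0, 0, 0], f) == "breach"
    assert evaluate_alert([0, 0, 4.2], f) == "proximity"
    assert evaluate_alert([0, 0, 5.2], f) == "clear"
    with pytest.raises(ValueError, match="outside"):
        evaluate_alert([100, 0, 0], f)


def test_alert_breach_iff_red_at_tip():
    f = _ball_field(radius=3.0)
    rng = np.random.default_rng(8)
    tips = rng.uniform(-10, 10, (200, 3))
    for tip in tips:
        d = f.sample(tip)[0]
        breach = evaluate_alert(tip, f) == "breach"
        assert breach == (classify_point(d, 50.0) == "R")


def test_colormap_render_deterministic(tmp_path, s2_model):
    pose = ideal_pose(s2_model, "superior")
    pm = evaluate_plane_analytic(pose, s2_model)
    p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
    render_colormap(pm, p1)
    render_colormap(pm, p2)
    b1, b2 = p1.read_bytes(), p2.read_bytes()
    assert len(b1) > 1000
    assert b1 == b2
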