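"""Segmentation, surface extraction, signed distance, alert cloud."""

import numpy as np
import pytest

from navmargin.grids import LabelMask, Volume
from navmargin.imaging import (
    build_alert_cloud,
    extract_surface,
    mean_surface_offset,
    segment_by_threshold,
    signed_distance,
)
from navmargin.phantoms import VolumeSpec

from conftest import sphere_mask


def _midpoint_threshold():
    inten = VolumeSpec().intensities
    return 0.5 * (inten["bone"] + inten["tumor"])


def test_threshold_recovers_ground_truth(s2_masks, s2_volume):
    """On the noiseless volume, the bone/tumor midpoint threshold recovers
    exactly the tumor-union-ICA voxel set."""
    seg = segment_by_threshold(s2_volume, _midpoint_threshold(), refine_radius=0.0)
    truth = s2_masks["tumor"].voxels | s2_masks["ica"].voxels
    assert np.array_equal(seg.voxels, truth)


def test_threshold_above_maximum_errors(s2_volume):
    with pytest.raises(ValueError, match="threshold"):
        segment_by_threshold(s2_volume, float(s2_volume.data.max()) + 1.0)


def test_noisy_segmentation_dice(s2_model, s2_masks, small_spec):
    """Gaussian noise at 10% of the bone-tumor contrast still yields
    Dice >= 0.95 against ground truth after morphological refinement."""
    from dataclasses import replace
    from navmargin.phantoms import synthesize_volume

    contrast = VolumeSpec().intensities["tumor"] - VolumeSpec().intensities["bone"]
    spec = replace(small_spec, noise_sd=0.1 * contrast)
    vol = synthesize_volume(s2_model, spec, rng=3)
    seg = segment_by_threshold(vol, _midpoint_threshold(), refine_radius=1.6)
    truth = s2_masks["tumor"].voxels | s2_masks["ica"].voxels
    inter = np.sum(seg.voxels & truth)
    dice = 2 * inter / (np.sum(seg.voxels) + np.sum(truth))
    assert dice >= 0.95


def test_segmentation_idempotent(s2_masks):
    """Re-synthesizing a segmented mask and segmenting again is a no-op."""
    mask = s2_masks["tumor"]
    vol = Volume(
        spacing=mask.spacing,
        origin=mask.origin,
        data=np.where(mask.voxels, 800.0, 0.0).astype(np.float32),
    )
    seg = segment_by_threshold(vol, 400.0, refine_radius=0.0)
    assert np.array_equal(seg.voxels, mask.voxels)


def test_surface_volume_of_sphere():
    """Marching-cubes mesh volume within 5% of the analytic sphere volume."""
    mask = sphere_mask(10.0)
    mesh = extract_surface(mask)
    assert mesh.is_watertight
    assert mesh.volume == pytest.approx(4.0 / 3.0 * np.pi * 10.0**3, rel=0.05)


def test_surface_single_voxel():
    vox = np.zeros((5, 5, 5), dtype=bool)
    vox[2, 2, 2] = True
    mesh = extract_surface(LabelMask(spacing=1.0, origin=np.zeros(3), voxels=vox))
    assert mesh.is_watertight
    assert mesh.volume > 0


def test_surface_of_ica_mask_watertight(s2_masks):
    mesh = extract_surface(s2_masks["ica"])
    assert mesh.is_watertight
    assert mesh.volume > 0


def test_surface_empty_mask_errors():
    empty = LabelMask(spacing=1.0, origin=np.zeros(3), voxels=np.zeros((4, 4, 4), bool))
    with pytest.raises(ValueError, match="empty"):
        extract_surface(empty)


def test_signed_distance_sphere_center():
    """d at the sphere center is -radius within half a voxel."""
    mask = sphere_mask(5.0)
    field = signed_distance(mask)
    center = np.unravel_index(np.argmin(np.abs(field.values)), field.values.shape)
    d_center = field.sample(np.zeros(3))[0]
    assert d_center == pytest.approx(-5.0, abs=0.4 + 1e-9)


def test_signed_distance_sign_matches_mask(s2_masks):
    field = signed_distance(s2_masks["ica"])
    assert np.all(field.values[s2_masks["ica"].voxels] < 0)
    assert np.all(field.values[~s2_masks["ica"].voxels] > 0)


def test_signed_distance_radius_recovery():
    """Voxelized spheres of radius 3-15 mm recover the radius within a voxel."""
    for r in (3.0, 7.0, 11.0, 15.0):
        field = signed_distance(sphere_mask(r))
        assert -field.sample(np.zeros(3))[0] == pytest.approx(r, abs=0.8)


def test_signed_distance_degenerate_masks():
    empty = np.zeros((4, 4, 4), bool)
    for vox in (empty, ~empty):
        with pytest.raises(ValueError, match="surface"):
            signed_distance(LabelMask(spacing=1.0, origin=np.zeros(3), voxels=vox))


def _cylinder_mask(radius=2.5, spacing=0.8, n=(40, 40, 60)):
    axs = [(np.arange(k) - k / 2 + 0.5) * spacing for k in n]
    X, Y, Z = np.meshgrid(*axs, indexing="ij")
    return LabelMask(
        spacing=spacing,
        origin=np.array([a[0] for a in axs]),
        voxels=X**2 + Y**2 <= radius**2,
    )


def test_alert_cloud_offset_on_cylinder():
    """The 2-mm alert surface around a 2.5-mm cylinder sits 2 mm from the
    vessel surface (within half a voxel); outer radius ~4.5 mm."""
    cyl = _cylinder_mask()
    cloud = build_alert_cloud(cyl, margin=2.0)
    inner = extract_surface(cyl)
    offset = mean_surface_offset(inner, cloud.surface_mesh)
    assert offset == pytest.approx(2.0, abs=0.4)
    radial = np.linalg.norm(np.asarray(cloud.surface_mesh.vertices)[:, :2], axis=1)
    interior = np.abs(np.asarray(cloud.surface_mesh.vertices)[:, 2]) < 15.0
    assert np.median(radial[interior]) == pytest.approx(4.5, abs=0.4)


def test_alert_cloud_voxels_within_margin():
    """Every cloud-voxel center lies strictly outside the vessel and within
    margin + half a voxel of it."""
    mask = sphere_mask(4.0)
    cloud = build_alert_cloud(mask, margin=2.0)
    field = signed_distance(mask)
    d = field.values[cloud.mask.voxels]
    assert np.all(d > 0)
    assert np.all(d <= 2.0 + 0.4 + 1e-9)


def test_alert_cloud_margin_validation():
    mask = sphere_mask(4.0)
    with pytest.raises(ValueError, match="margin"):
        build_alert_cloud(mask, margin=0.0)
    with pytest.warns(UserWarning, match="disconnected"):
        build_alert_cloud(mask, margin=0.5)
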