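"""Image-processing arm: rescaling, registration, resampling, detection,
applied-displacement measurement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import tiny_config
from osteodisc.phantom import deform_phantom, generate_phantom
from osteodisc.volume import (MarkerSet, RigidTransform, VoxelVolume,
                              detect_markers, detect_reference_markers, kabsch,
                              measure_applied_displacement, register_rigid,
                              resample_to, rescale_greyscale)


# ---------------------------------------------------------------------------
# rescale
# ---------------------------------------------------------------------------

def test_rescale_closed_form():
    """{10, 20, 30} maps to {0, 127.5, 255}; full-range data is unchanged."""
    v = VoxelVolume(np.array([10.0, 20.0, 30.0]).reshape(1, 1, 3), 1.0, 0.0)
    out = rescale_greyscale(v)
    assert np.allclose(out.values.ravel(), [0.0, 127.5, 255.0])
    w = VoxelVolume(np.array([0.0, 100.0, 255.0]).reshape(1, 1, 3), 1.0, 0.0)
    assert np.allclose(rescale_greyscale(w).values, w.values)


def test_rescale_bounds_and_order(tiny_phantom):
    out = rescale_greyscale(tiny_phantom["ct"])
    assert out.values.min() == pytest.approx(0.0)
    assert out.values.max() == pytest.approx(255.0)


def test_rescale_constant_volume_errors():
    v = VoxelVolume(np.full((3, 3, 3), 5.0), 1.0, 0.0)
    with pytest.raises(ValueError):
        rescale_greyscale(v)


# ---------------------------------------------------------------------------
# transforms and resampling
# ---------------------------------------------------------------------------

def test_rigid_transform_algebra():
    rng = np.random.default_rng(0)
    R = Rotation.random(random_state=1).as_matrix()
    t = RigidTransform(R, rng.normal(size=3), rng.normal(size=3))
    pts = rng.normal(size=(10, 3))
    assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)
    t2 = RigidTransform(Rotation.random(random_state=2).as_matrix(),
                        rng.normal(size=3))
    assert np.allclose(t.compose(t2).apply(pts), t.apply(t2.apply(pts)),
                       atol=1e-12)
    m = t.as_matrix()
    assert np.allclose(RigidTransform.from_matrix(m).apply(pts), t.apply(pts))
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]))    # improper rotation


def test_resample_identity_and_unit_shift():
    rng = np.random.default_rng(1)
    vol = VoxelVolume(rng.random((12, 11, 10)).astype(np.float32), 0.5, 0.0)
    same = resample_to(vol, vol, RigidTransform.identity())
    assert np.allclose(same.values, vol.values, atol=1e-6)
    # translating by exactly one voxel shifts indices by one
    shift = RigidTransform(np.eye(3), np.array([0.5, 0.0, 0.0]))
    out = resample_to(vol, vol, shift)
    assert np.allclose(out.values[1:], vol.values[:-1], atol=1e-5)


def test_resample_output_grid_matches_reference(tiny_phantom):
    mr, ct = tiny_phantom["mr"], tiny_phantom["ct"]
    out = resample_to(mr, ct, RigidTransform.identity())
    assert out.shape == ct.shape
    assert np.allclose(out.spacing, ct.spacing)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def test_register_identity_when_moving_equals_fixed(tiny_phantom):
    ct = tiny_phantom["ct"]
    t = register_rigid(ct, ct)
    assert np.allclose(t.rotation, np.eye(3), atol=5e-4)
    assert np.allclose(t.translation, 0.0, atol=0.05)


def test_register_recovers_planted_perturbation(tiny_phantom):
    """Caudal-bone registration inverts the planted rigid motion to within
    half a voxel RMS at the marker positions."""
    truth = tiny_phantom["truth"]
    vol = deform_phantom(truth, 1, rigid_only=True)
    t = register_rigid(vol, tiny_phantom["ct"])
    planted = truth.rigid_per_step[1]
    pts = truth.markers_per_step[0][["x", "y", "z"]].to_numpy()
    rms = np.sqrt(np.mean(np.sum((t.apply(planted.apply(pts)) - pts) ** 2,
                                 axis=1)))
    assert rms < 0.5 * tiny_phantom["config"].voxel_spacing


def test_kabsch_exact_on_three_markers():
    """Pinpoint-style closed-form alignment is exact for noise-free points."""
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(3, 3)) * 10
    R = Rotation.from_euler("xyz", [4, -3, 7], degrees=True).as_matrix()
    moved = pts @ R.T + np.array([1.0, -2.0, 0.5])
    t = kabsch(moved, pts)
    assert t.residual < 1e-9
    assert np.allclose(t.apply(moved), pts, atol=1e-9)


def test_pinpoint_registration_mr_to_ct(tiny_phantom):
    """MR-to-CT registration via the reference markers lands the MR frame on
    the CT frame (identity here) and detects 6 endcap markers."""
    ct, mr = tiny_phantom["ct"], tiny_phantom["mr"]
    pins = detect_reference_markers(ct)
    assert len(pins) == 6
    t = register_rigid(mr, ct, roi="pinpoint_markers")
    pts = np.array([[5.0, 0.0, -8.0], [0.0, 5.0, 8.0], [1.0, 1.0, 0.0]])
    assert np.allclose(t.apply(pts), pts, atol=0.25)


# ---------------------------------------------------------------------------
# marker detection
# ---------------------------------------------------------------------------

def test_detect_markers_count_and_accuracy(tiny_phantom):
    cfg = tiny_phantom["config"]
    ms = detect_markers(rescale_greyscale(tiny_phantom["ct"]), cfg.n_markers)
    assert len(ms) == 40
    gt = tiny_phantom["truth"].markers_per_step[0]
    m = ms.table.merge(gt, on="id", suffixes=("_d", "_t"))
    assert len(m) == 40                      # line/level identification agrees
    trans = np.hypot(m.x_d - m.x_t, m.y_d - m.y_t)
    axial = np.abs(m.z_d - m.z_t)
    # voxel-size-scaled analogues of the reference-resolution bounds
    assert trans.max() < 1.1 * cfg.voxel_spacing
    assert axial.max() < 4.0 * cfg.voxel_spacing
    assert (m.zone_d == m.zone_t).all()


def test_detect_markers_invariant_to_intensity_scaling(tiny_phantom):
    """Detection after rescaling is unaffected by global intensity scaling."""
    ct = tiny_phantom["ct"]
    scaled = VoxelVolume(ct.values * 3.7 + 11.0, ct.spacing, ct.origin)
    a = detect_markers(rescale_greyscale(ct), 40).table
    b = detect_markers(rescale_greyscale(scaled), 40).table
    assert np.allclose(a[["x", "y", "z"]], b[["x", "y", "z"]], atol=1e-3)


def test_detect_markers_wrong_count_raises(tiny_phantom):
    with pytest.raises(ValueError, match="expected 39|markers"):
        detect_markers(rescale_greyscale(tiny_phantom["ct"]), 39)


def test_marker_zone_labels_stable_across_steps(tiny_phantom):
    """Zone is carried by marker id, not re-derived from deformed positions."""
    truth = tiny_phantom["truth"]
    vol = deform_phantom(truth, 1)
    t = register_rigid(vol, tiny_phantom["ct"])
    reg = resample_to(vol, tiny_phantom["ct"], t)
    ms1 = detect_markers(rescale_greyscale(reg), 40)
    gt1 = truth.markers_per_step[1]
    m = ms1.table.merge(gt1, on="id", suffixes=("_d", "_t"))
    assert (m.zone_d == m.zone_t).all()
    # and the registered-frame centroids track the deformed ground truth
    err = np.hypot(m.x_d - m.x_t, m.y_d - m.y_t)
    assert err.max() < 1.2 * tiny_phantom["config"].voxel_spacing


# ---------------------------------------------------------------------------
# applied displacement
# ---------------------------------------------------------------------------

def test_displacement_zero_for_identical_volumes(tiny_phantom):
    ct = tiny_phantom["ct"]
    assert measure_applied_displacement(ct, ct) == pytest.approx(0.0, abs=1e-9)


def test_displacement_recovers_planted_platen_motion(tiny_phantom):
    """Measured endcap inner-surface distance change matches the planted
    displacement within about one voxel, and grows across cumulative steps."""
    cfg, truth = tiny_phantom["config"], tiny_phantom["truth"]
    ct = tiny_phantom["ct"]
    measured = []
    for step in (1, 2):
        vol = deform_phantom(truth, step)
        t = register_rigid(vol, ct)
        reg = resample_to(vol, ct, t)
        measured.append(measure_applied_displacement(ct, reg))
    planted = truth.applied_displacement_per_step[:2]
    assert np.all(np.abs(np.array(measured) - planted)
                  <= 1.5 * cfg.voxel_spacing)
    assert measured[1] > measured[0]
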