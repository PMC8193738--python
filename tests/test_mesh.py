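"""Model building: nucleus variants, meshing, materials, fibres, BCs."""

import numpy as np
import pytest

from conftest import solver_config
from osteodisc.mesh import (SpecimenModel, build_bcs, build_nucleus,
                            build_specimen_model, disc_geometry,
                            map_markers_to_nodes, mesh_specimen, write_inp,
                            write_vtu)
from osteodisc.phantom import generate_labels
from osteodisc.volume import VoxelVolume


def box_labels(code=5, shape=(10, 10, 20), spacing=0.5):
    lab = np.zeros(shape, dtype=np.int8)
    lab[1:-1, 1:-1, 1:-1] = code
    return VoxelVolume(lab, spacing, 0.0)


# ---------------------------------------------------------------------------
# nucleus variants
# ---------------------------------------------------------------------------

def test_std_cyl_diameter_ratio(coarse_model):
    """std_cyl nucleus diameter is exactly half the mean annulus diameter."""
    labels = coarse_model["labels"]
    lab = build_nucleus("std_cyl", labels)
    geom = disc_geometry(labels)
    idx = np.argwhere(lab.values == 4)
    pts = lab.index_to_world(idx)
    r = np.hypot(pts[:, 0] - geom["center"][0], pts[:, 1] - geom["center"][1])
    # voxelized cylinder: max radius within half a voxel of the target
    assert abs(r.max() - 0.5 * geom["mean_radius"]) < np.max(lab.spacing)


def test_fit_cyl_volume_matches_mask(coarse_model):
    """fit_cyl nucleus volume matches the MR mask volume within 1%."""
    labels = coarse_model["labels"]
    truth_mask = coarse_model["config"]
    # synthetic NP mask: offset sphere of known volume inside the disc
    geom = disc_geometry(labels)
    idx = np.argwhere(np.isin(labels.values, (3, 4)))
    pts = labels.index_to_world(idx)
    mask = np.zeros(labels.shape, dtype=np.uint8)
    inside = np.linalg.norm(pts - (geom["center"] + [0.4, 0, 0]), axis=1) < 1.8
    mask[tuple(idx[inside].T)] = 1
    np_mask = VoxelVolume(mask, labels.spacing, labels.origin)
    v_mask = mask.sum() * np.prod(labels.spacing)

    lab = build_nucleus("fit_cyl", labels, np_mask)
    v_np = (lab.values == 4).sum() * np.prod(labels.spacing)
    # the fitted radius reproduces the mask volume analytically; the meshed
    # (voxelized) region reproduces it within discretization
    r_fit = np.sqrt(v_mask / (np.pi * geom["height"]))
    v_analytic = np.pi * r_fit ** 2 * geom["height"]
    assert abs(v_analytic - v_mask) / v_mask < 1e-9
    assert abs(v_np - v_mask) / v_mask < 0.10        # voxelization error

    lab_mr = build_nucleus("mr", labels, np_mask)
    v_mr = (lab_mr.values == 4).sum() * np.prod(labels.spacing)
    assert abs(v_mr - v_mask) / v_mask < 0.02


def test_nucleus_requires_mask_and_knows_types(coarse_model):
    with pytest.raises(ValueError, match="mask"):
        build_nucleus("fit_cyl", coarse_model["labels"])
    with pytest.raises(ValueError, match="unknown"):
        build_nucleus("sphere", coarse_model["labels"])


def test_std_cyl_larger_than_fit_cyl_for_small_np(coarse_model):
    """With a measured NP below (0.5)^2 of the disc area, the standard
    cylinder is the larger nucleus (consistent with the MR volumes being
    smaller than the standardised one)."""
    labels = coarse_model["labels"]
    np_mask = VoxelVolume((labels.values == 4).astype(np.uint8),
                          labels.spacing, labels.origin)
    v_std = (build_nucleus("std_cyl", labels).values == 4).sum()
    v_fit = (build_nucleus("fit_cyl", labels, np_mask).values == 4).sum()
    assert v_std > v_fit


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

def test_mesh_positive_volumes_and_quality():
    mesh = mesh_specimen(box_labels(), target_edge=1.0)
    assert np.all(mesh.volumes() > 0)
    assert mesh.scaled_jacobians().min() > 0.05
    # conforming: every interior face is shared by exactly two tets
    bf = mesh.boundary_faces()
    assert len(bf) > 0


def test_mesh_edge_statistics_at_reference_scale():
    """At the reference setting the median edge falls in the 0.5-1.0 mm
    band used for the full-resolution models."""
    mesh = mesh_specimen(box_labels(spacing=0.4), target_edge=0.7)
    med = np.median(mesh.edge_lengths())
    assert 0.5 <= med <= 1.0


def test_mesh_desk_scale_element_count(coarse_model):
    """Coarse desk-scale meshing keeps the model under 10^4 elements."""
    mesh = coarse_model["model"].mesh
    assert mesh.n_elems < 10_000
    # overall disc volume approximates the label mask; the split between the
    # thin NP and the AF carries first-order boundary error at desk scale,
    # which must shrink under refinement
    labels = coarse_model["labels"]
    voxel = np.prod(labels.spacing)
    v_disc_lab = np.isin(labels.values, (3, 4)).sum() * voxel

    def np_err(edge):
        m = mesh_specimen(labels, target_edge=edge)
        v_disc = m.volumes()[np.isin(m.region, (3, 4))].sum()
        v_np = m.volumes()[m.region == 4].sum()
        v_np_lab = (labels.values == 4).sum() * voxel
        return abs(v_disc - v_disc_lab) / v_disc_lab, \
            abs(v_np - v_np_lab) / v_np_lab

    d_coarse, n_coarse = np_err(1.8)
    d_fine, n_fine = np_err(0.9)
    assert d_coarse < 0.10 and d_fine < 0.05
    assert n_fine < n_coarse            # NP volume error converges


def test_bone_moduli_pooling_and_bounds(coarse_model):
    """Greyscale mapping: uniform bone -> uniform E; defaults stay within
    the reported 3.6-842 MPa range."""
    from osteodisc.mesh import assign_bone_moduli
    from osteodisc.phantom import generate_phantom
    from osteodisc.volume import rescale_greyscale

    cfg = solver_config(seed=13)
    ct, _, truth = generate_phantom(cfg, with_mr=False)
    mesh = mesh_specimen(truth.labels, target_edge=1.8)
    assign_bone_moduli(mesh, rescale_greyscale(ct))
    bone = np.isin(mesh.region, (1, 2))
    E = mesh.bone_E[bone]
    assert np.all(np.isfinite(E))
    assert np.all((E >= 3.6) & (E <= 842.0 + 1e-9))


def test_bone_moduli_two_valued_oracle():
    """A two-valued CT yields a bimodal per-element E histogram whose modes
    are the mapped intensities and whose mode fractions match the volume
    split."""
    from osteodisc.mesh import assign_bone_moduli

    lab = np.zeros((14, 14, 26), dtype=np.int8)
    lab[1:13, 1:13, 1:25] = 1
    labels = VoxelVolume(lab, 0.5, 0.0)
    ct = np.full(lab.shape, 100.0, dtype=np.float32)
    ct[:, :, 13:] = 200.0
    ctv = VoxelVolume(ct, 0.5, 0.0)
    mesh = mesh_specimen(labels, target_edge=1.0)
    assign_bone_moduli(mesh, ctv)
    E = mesh.bone_E[np.isin(mesh.region, (1, 2))]
    a = 842.0 / 255.0
    lo, hi = 100 * a, 200 * a
    f_lo = np.mean(np.abs(E - lo) < 1.0)
    f_hi = np.mean(np.abs(E - hi) < 1.0)
    assert f_lo + f_hi > 0.8                  # interface elements blend
    assert abs(f_lo - f_hi) < 0.15            # ~half/half split
    assert np.all((E >= lo - 1e-6) & (E <= hi + 1e-6))


def test_fibre_angles_and_symmetry(coarse_model):
    """AF fibre pairs sit at 20 +/- 0.1 degrees from the transverse plane,
    mirror-symmetric, and orthogonal to the radial direction."""
    mesh = coarse_model["model"].mesh
    af = mesh.region == 3
    f = mesh.fibres[af]
    ang = np.rad2deg(np.arcsin(np.abs(f[..., 2])))
    assert np.all(np.abs(ang - 20.0) < 0.1)
    assert np.allclose(f[:, 0, 2], -f[:, 1, 2], atol=1e-12)       # mirror
    cent = mesh.nodes[mesh.elems[af]].mean(axis=1)
    center = coarse_model["model"].disc_center
    e_r = cent - center
    e_r[:, 2] = 0
    e_r /= np.linalg.norm(e_r, axis=1, keepdims=True)
    assert np.abs(np.einsum("ei,ei->e", f[:, 0], e_r)).max() < 1e-9


def test_bcs_fix_faces(coarse_model):
    mesh = coarse_model["model"].mesh
    bcs = build_bcs(mesh, 0.8)
    vals = bcs["values"].reshape(-1, 3)
    n_bot = len(mesh.node_sets["endcap_bottom_face"])
    assert np.allclose(vals[:n_bot], 0.0)
    assert np.allclose(vals[n_bot:, :2], 0.0)
    assert np.allclose(vals[n_bot:, 2], -0.8)


def test_marker_node_map_close_to_surface(coarse_model):
    from osteodisc.phantom import generate_labels
    cfg = coarse_model["config"]
    _, geom = generate_labels(cfg)
    import pandas as pd

    markers = pd.DataFrame({
        "id": np.arange(len(geom["marker_theta"])),
        "x": geom["marker_r"] * np.cos(geom["marker_theta"]),
        "y": geom["marker_r"] * np.sin(geom["marker_theta"]),
        "z": geom["marker_z"]})
    mm = map_markers_to_nodes(coarse_model["model"].mesh, markers)
    # nearest surface node within roughly one mesh cell
    assert mm["distance"].max() < 2.0


def test_mesh_export_roundtrip(tmp_path, coarse_model):
    """VTU and INP exports are well-formed text files."""
    mesh = coarse_model["model"].mesh
    vtu = tmp_path / "m.vtu"
    inp = tmp_path / "m.inp"
    write_vtu(mesh, str(vtu), point_data={"u": np.zeros_like(mesh.nodes)})
    write_inp(mesh, str(inp), applied_displacement=0.5)
    txt = vtu.read_text()
    assert txt.count("<DataArray") >= 5 and "UnstructuredGrid" in txt
    assert f'NumberOfPoints="{mesh.n_nodes}"' in txt
    itxt = inp.read_text()
    assert "*ELEMENT, TYPE=C3D4" in itxt and "*BOUNDARY" in itxt
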