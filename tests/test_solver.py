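"""FE solver: closed-form checks, equilibrium, convergence, invariances."""

import numpy as np
import pandas as pd
import pytest

from conftest import solver_config
from osteodisc import materials as mat
from osteodisc.mesh import SpecimenModel, TetMesh, build_specimen_model, mesh_specimen
from osteodisc.phantom import generate_labels
from osteodisc.solver import (NonConvergenceError, _Assembler, forward_load_curve,
                              predict_bulge, solve_step)
from osteodisc.volume import VoxelVolume


def bar_model(nu=0.0):
    lab = np.zeros((13, 13, 29), dtype=np.int8)
    lab[1:12, 1:12, 1:14] = 5
    lab[1:12, 1:12, 14:28] = 6
    labels = VoxelVolume(lab, 0.5, 0.0)
    mesh = mesh_specimen(labels, target_edge=1.2)
    return SpecimenModel(labels, mesh), mat.MaterialParams(pmma_E=1035.0, pmma_nu=nu)


def test_zero_displacement_zero_solution(coarse_model, soft_materials):
    res = solve_step(coarse_model["model"], soft_materials, 0.0, substeps=1)
    assert np.allclose(res.u, 0.0)
    assert res.reaction_N == pytest.approx(0.0, abs=1e-9)


def test_bar_matches_linear_closed_form():
    """Homogeneous bar at small strain: reaction = E A d / L within 1%."""
    model, mats = bar_model(nu=0.0)
    z = model.mesh.nodes[:, 2]
    L = z.max() - z.min()
    A = model.mesh.volumes().sum() / L
    d = 1e-3 * L
    res = solve_step(model, mats, d, substeps=1)
    assert res.reaction_N == pytest.approx(1035.0 * A * d / L, rel=0.01)
    # linearity limit: doubling the displacement doubles the load within 1%
    res2 = solve_step(model, mats, 2 * d, substeps=1)
    assert res2.reaction_N == pytest.approx(2 * res.reaction_N, rel=0.01)


def test_single_element_reproduces_constitutive_stress():
    """A one-element patch under an affine displacement returns exactly the
    internal forces implied by the constitutive first PK stress."""
    nodes = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([4]))
    asm = _Assembler(mesh, mat.MaterialParams(np_K=50.0))
    F = np.array([[1.04, 0.02, 0.0], [0.0, 0.97, 0.01], [0.0, 0.0, 1.02]])
    u = nodes @ (F - np.eye(3)).T
    f = asm.internal_forces(u.ravel()).reshape(-1, 3)
    P = mat.first_piola(F, "mooney_rivlin", C10=0.07, C01=0.02, K=50.0)
    V = mesh.volumes()[0]
    f_exact = V * asm.G[0] @ P.T
    assert np.allclose(f, f_exact, atol=1e-12)


def test_global_equilibrium(coarse_model, soft_materials):
    """Internal forces sum to zero over all nodes (translation invariance)."""
    res = solve_step(coarse_model["model"], soft_materials, 0.6, substeps=2)
    asm = _Assembler(coarse_model["model"].mesh, soft_materials)
    f = asm.internal_forces(res.u.ravel()).reshape(-1, 3)
    assert np.abs(f.sum(axis=0)).max() < 1e-8 * max(res.reaction_N, 1.0)
    assert res.reaction_N > 0          # compression: positive axial reaction


def test_rigid_translation_is_force_free(coarse_model, soft_materials):
    asm = _Assembler(coarse_model["model"].mesh, soft_materials)
    u = np.tile([0.3, -0.2, 0.5], coarse_model["model"].mesh.n_nodes)
    assert np.abs(asm.internal_forces(u)).max() < 1e-9


def test_solution_invariant_under_node_renumbering(coarse_model, soft_materials):
    model = coarse_model["model"]
    mesh = model.mesh
    rng = np.random.default_rng(0)
    perm = rng.permutation(mesh.n_nodes)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(mesh.n_nodes)
    mesh2 = TetMesh(mesh.nodes[perm], inv[mesh.elems], mesh.region.copy(),
                    mesh.bone_E.copy(), mesh.fibres.copy(),
                    {k: inv[v] for k, v in mesh.node_sets.items()})
    model2 = SpecimenModel(model.labels, mesh2, None, model.disc_axis,
                           model.disc_center, model.nucleus_model)
    r1 = solve_step(model, soft_materials, 0.5, substeps=1)
    r2 = solve_step(model2, soft_materials, 0.5, substeps=1)
    assert r2.reaction_N == pytest.approx(r1.reaction_N, rel=1e-8)
    assert np.allclose(r2.u[inv], r1.u, atol=1e-8)


def test_mesh_refinement_cauchy_convergence():
    """Reaction force differences shrink under mesh refinement."""
    cfg = solver_config(seed=21)
    labels, _ = generate_labels(cfg)
    mats = mat.MaterialParams(af_K=300.0, np_K=150.0)
    reactions = []
    for edge in (3.0, 2.2, 1.6):
        model = build_specimen_model(labels, nucleus_model="std_cyl",
                                     target_edge=edge)
        reactions.append(solve_step(model, mats, 0.5, substeps=1).reaction_N)
    d1 = abs(reactions[1] - reactions[0])
    d2 = abs(reactions[2] - reactions[1])
    assert d2 < d1


def test_forward_curve_stiffening_and_bulge(coarse_model, soft_materials):
    """GOH annulus: convex (stiffening) load curve; axial compression of a
    nearly incompressible disc produces outward surface bulge."""
    model = coarse_model["model"]
    from osteodisc.mesh import map_markers_to_nodes
    from osteodisc.phantom import generate_labels

    _, geom = generate_labels(coarse_model["config"])
    markers = pd.DataFrame({
        "id": np.arange(len(geom["marker_theta"])),
        "zone": "A",
        "x": geom["marker_r"] * np.cos(geom["marker_theta"]),
        "y": geom["marker_r"] * np.sin(geom["marker_theta"]),
        "z": geom["marker_z"]})
    model.marker_nodes = map_markers_to_nodes(model.mesh, markers)
    rec = forward_load_curve(model, soft_materials, [0.5, 1.0, 1.5])
    F = rec["reaction_N"].to_numpy()
    d = rec["displacement_mm"].to_numpy()
    assert np.all(np.diff(F) > 0)
    slopes = np.diff(np.concatenate([[0.0], F])) / np.diff(np.concatenate([[0.0], d]))
    assert np.all(np.diff(slopes) > 0)
    bl = rec.attrs["bulge"][3]
    assert bl["bulge"].mean() > 0.05          # volume conservation pushes out
    # softer nucleus bulk -> lower reaction at the same displacement
    softer = mat.MaterialParams(af_K=soft_materials.af_K, np_K=100.0)
    rec2 = forward_load_curve(model, softer, [0.5])
    assert rec2["reaction_N"].iloc[0] < F[0]


def test_load_record_forward_mode_equals_solver(coarse_model, soft_materials):
    """The forward-FE mode of the synthetic load record is exactly the
    solver's reaction forces plus the preload."""
    from osteodisc.phantom import generate_load_record, generate_phantom

    cfg = coarse_model["config"]
    _, _, truth = generate_phantom(cfg, with_mr=False)
    rec = generate_load_record(cfg, truth, model=coarse_model["model"],
                               materials=soft_materials)
    fwd = forward_load_curve(coarse_model["model"], soft_materials,
                             list(truth.applied_displacement_per_step[:3]))
    assert np.allclose(rec["peak_load_N"].to_numpy()[1:] - cfg.preload_N,
                       fwd["reaction_N"].to_numpy(), rtol=1e-10)
    assert rec["peak_load_N"].iloc[0] == cfg.preload_N


def test_decreasing_displacements_rejected(coarse_model, soft_materials):
    with pytest.raises(ValueError):
        forward_load_curve(coarse_model["model"], soft_materials, [1.0, 0.5])


def test_zero_prediction_gives_zero_bulge(coarse_model):
    from osteodisc.solver import SolveResult
    model = coarse_model["model"]
    surf = model.mesh.node_sets["disc_surface_nodes"][:5]
    model = SpecimenModel(model.labels, model.mesh,
                          pd.DataFrame({"id": np.arange(5), "zone": "A",
                                        "node": surf, "distance": 0.0}))
    res = SolveResult(np.zeros((model.mesh.n_nodes, 3)), 0.0, 0.0)
    assert predict_bulge(res, model)["bulge"].eq(0).all()
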