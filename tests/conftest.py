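"""Shared fixtures: small phantoms and coarse FE models.

Unit tests run on reduced phantoms (2-3x the reference voxel size, small
specimens) so the suite stays fast; acceptance tests use the reference
82 um resolution.
"""

import numpy as np
import pytest

from osteodisc.materials import MaterialParams
from osteodisc.mesh import build_specimen_model
from osteodisc.phantom import PhantomConfig, generate_labels, generate_phantom


def tiny_config(**kw) -> PhantomConfig:
    """Small, coarse specimen for image-pipeline unit tests."""
    base = dict(voxel_spacing=0.2, disc_radius=5.0, disc_height=7.0,
                bone_height=3.0, endcap_height=3.0, seed=42)
    base.update(kw)
    return PhantomConfig(**base)


def solver_config(**kw) -> PhantomConfig:
    """Very coarse labels for FE tests (no imaging involved)."""
    base = dict(voxel_spacing=0.25, disc_radius=5.0, disc_height=5.0,
                bone_height=2.5, endcap_height=3.0, markers_per_line=3,
                step_displacements=(0.5, 0.5, 0.5, 0.5), seed=11)
    base.update(kw)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def tiny_phantom():
    cfg = tiny_config()
    ct, mr, truth = generate_phantom(cfg)
    return {"config": cfg, "ct": ct, "mr": mr, "truth": truth}


@pytest.fixture(scope="session")
def coarse_model():
    cfg = solver_config()
    labels, _ = generate_labels(cfg)
    model = build_specimen_model(labels, nucleus_model="std_cyl",
                                 target_edge=1.8)
    return {"config": cfg, "labels": labels, "model": model}


@pytest.fixture(scope="session")
def soft_materials():
    """Moderate bulk moduli: representative yet fast to converge."""
    return MaterialParams(af_K=800.0, np_K=300.0)
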