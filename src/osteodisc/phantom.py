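"""Synthetic osteodisc phantom generator.

Emulates the experimental arm on which the rest of the package operates: a
cylindrical bone-disc-bone specimen potted in PMMA endcaps, imaged at 82 um
isotropic CT-like resolution and at coarse MR-like resolution, carrying 40
glass fiducial markers (~1 mm) arranged on eight craniocaudal lines at
45-degree intervals, five markers per line.  Each phantom has

* a nucleus pulposus occupying a uniformly sampled 7-17% of the disc volume
  (visible only on the MR-like volume),
* four axial compression steps with increments drawn from N(0.89, 0.14^2) mm,
* a planted, analytically known surface-bulge field with anterior bias whose
  per-step across-cohort means default to the measured values 0.24 / 0.48 /
  0.67 / 0.84 mm,
* a monotone, convex (stiffening) load record rising from a 50 N preload to
  ~2 kN at the final step,
* a small random rigid perturbation of each deformed volume, to exercise the
  registration stage downstream.

The planted bulge field is radial, ``u_r(theta, z) = A(theta) sin(pi zeta)``
with ``zeta`` the relative height within the (compressed) disc and
``A(theta) = a (1 + beta sin(theta))`` (anterior = +y), so it vanishes at the
endplates and is controllable per zone.  All ground truth is analytic: marker
trajectories are exact, not discretized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from osteodisc.volume import RigidTransform, VoxelVolume, zone_from_azimuth

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "generate_labels",
    "generate_phantom",
    "deform_phantom",
    "generate_load_record",
    "LBL_BG", "LBL_BONE_CAUDAL", "LBL_BONE_CRANIAL", "LBL_AF", "LBL_NP",
    "LBL_ENDCAP_BOTTOM", "LBL_ENDCAP_TOP",
]

LBL_BG = 0
LBL_BONE_CAUDAL = 1
LBL_BONE_CRANIAL = 2
LBL_AF = 3
LBL_NP = 4
LBL_ENDCAP_BOTTOM = 5
LBL_ENDCAP_TOP = 6


def _default_ct_levels():
    # glass and reference markers are the brightest classes on CT
    return {"background": 20.0, "disc": 60.0, "endcap": 120.0,
            "bone": 175.0, "marker": 235.0, "pinpoint": 250.0}


def _default_mr_levels():
    # T2-like contrast: hydrated NP bright, AF intermediate, bone/PMMA dark
    return {"background": 10.0, "disc": 60.0, "np": 160.0, "endcap": 25.0,
            "bone": 40.0, "pinpoint": 220.0}


@dataclass
class PhantomConfig:
    """Stated world of the synthetic specimen.

    Lengths in mm.  The disc diameter (14 mm) is reduced relative to a full
    bovine caudal disc so that an 82 um volume stays desk-tractable; the
    marker layout, resolution, bone stock, platen-displacement distribution
    and nucleus volume fraction keep their reported values.
    """

    voxel_spacing: float = 0.082
    disc_radius: float = 7.0
    disc_height: float = 7.0
    bone_height: float = 15.0
    endcap_height: float = 4.0
    endcap_extra_radius: float = 1.0
    #: vertebral body radius = disc_radius - this margin (the disc overhangs
    #: the bone slightly, keeping surface beads clear of the bone blocks)
    bone_radius_margin: float = 0.3
    margin: float = 1.2            # transverse clearance beyond outermost feature
    np_volume_fraction: float | None = None   # None: sampled U(0.07, 0.17)
    np_center_offset: tuple = (0.0, 0.5)      # slight anterior offset
    n_marker_lines: int = 8
    markers_per_line: int = 5
    marker_diameter: float = 1.0
    pinpoint_diameter: float = 3.0
    n_steps: int = 4
    step_displacements: tuple | None = None   # None: increments ~ N(0.89, 0.14^2)
    step_mean: float = 0.89
    step_sd: float = 0.14
    #: across-cohort mean planted bulge per step (mm)
    bulge_step_means: tuple = (0.24, 0.48, 0.67, 0.84)
    #: specimen-to-specimen scatter as a fraction of the step mean
    bulge_specimen_sd_frac: float = 0.30
    #: anterior-posterior modulation A(theta) ~ (1 + beta sin theta)
    bulge_anterior_bias: float = 0.4
    #: (peak load at the final step in N, linear fraction of the ramp)
    load_curve_params: tuple = (2000.0, 0.4)
    preload_N: float = 50.0
    greyscale_levels: dict = field(default_factory=_default_ct_levels)
    noise_sd_fraction: float = 0.05           # of the bone intensity
    mr_spacing: tuple = (0.3, 0.3, 1.0)
    mr_levels: dict = field(default_factory=_default_mr_levels)
    mr_noise_sd: float = 5.0
    rigid_rot_deg: float = 1.0                # perturbation scale per step
    rigid_trans_mm: float = 0.3
    marker_jitter_deg: float = 2.0
    marker_jitter_z: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        for name in ("disc_radius", "disc_height", "bone_height", "endcap_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.np_volume_fraction is not None and not (0 < self.np_volume_fraction < 1):
            raise ValueError("np_volume_fraction must be in (0, 1)")
        if self.marker_diameter / self.voxel_spacing < 3:
            raise ValueError("marker diameter below 3 voxels is undetectable")

    @property
    def n_markers(self) -> int:
        return self.n_marker_lines * self.markers_per_line


@dataclass
class GroundTruth:
    """Analytic record of everything the phantom planted.

    ``markers_per_step[k]`` holds one row per marker with columns
    (id, line, level, zone, x, y, z, xv, yv, zv): (x, y, z) in the specimen
    (preloaded, registered) frame and (xv, yv, zv) in the frame of the k-th
    volume, i.e. including the planted rigid perturbation.  Step 0 is the
    preloaded state.
    """

    config: PhantomConfig
    markers_per_step: dict
    applied_displacement_per_step: np.ndarray  # cumulative, index k-1
    step_increments: np.ndarray
    np_label_volume: VoxelVolume | None
    labels: VoxelVolume | None
    field_params: dict
    rigid_per_step: dict
    np_volume_fraction: float
    peak_load_per_step: np.ndarray | None = None

    def bulge_truth(self, step: int) -> pd.DataFrame:
        """Planted transverse-plane marker displacement at a step (mm)."""
        m0 = self.markers_per_step[0]
        mk = self.markers_per_step[step]
        d = mk[["x", "y"]].to_numpy() - m0[["x", "y"]].to_numpy()
        out = m0[["id", "line", "level", "zone"]].copy()
        out["bulge"] = np.linalg.norm(d, axis=1)
        return out


# ---------------------------------------------------------------------------
# Geometry sampling
# ---------------------------------------------------------------------------

def _sample_geometry(config: PhantomConfig, rng: np.random.Generator) -> dict:
    c = config
    frac = c.np_volume_fraction
    if frac is None:
        frac = float(rng.uniform(0.07, 0.17))
    r_np = c.disc_radius * np.sqrt(frac)
    off = np.asarray(c.np_center_offset, dtype=float)
    if r_np + np.linalg.norm(off) >= c.disc_radius:
        raise ValueError("nucleus cylinder does not fit inside the annulus")

    if c.step_displacements is not None:
        inc = np.asarray(c.step_displacements, dtype=float)
        if len(inc) != c.n_steps:
            raise ValueError("step_displacements length must equal n_steps")
    else:
        inc = np.clip(rng.normal(c.step_mean, c.step_sd, size=c.n_steps), 0.2, None)
    cum = np.cumsum(inc)
    if cum[-1] >= c.disc_height:
        raise ValueError("cumulative compression exceeds disc height")

    # marker base layout (cylindrical coordinates on the disc surface)
    m, nl = c.markers_per_line, c.n_marker_lines
    lines = np.repeat(np.arange(nl), m)
    levels = np.tile(np.arange(m), nl)
    theta = lines * (2 * np.pi / nl) + np.deg2rad(
        rng.normal(0.0, c.marker_jitter_deg, size=nl * m))
    zfrac = (levels + 1) / (m + 1)
    z = (zfrac - 0.5) * c.disc_height + rng.normal(0.0, c.marker_jitter_z, size=nl * m)
    if m > 1:   # beads are rigid: jitter must not make them interpenetrate
        z = _declutter_lines(z, lines, c.marker_diameter)
    r = np.full(nl * m, c.disc_radius + 0.35 * c.marker_diameter)

    pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    if len(pts) > 1:
        from scipy.spatial.distance import pdist
        if pdist(pts).min() < c.marker_diameter:
            raise ValueError("overlapping markers in sampled layout")

    # specimen bulge factor and per-step radial amplitudes
    f = max(float(rng.normal(1.0, c.bulge_specimen_sd_frac)), 0.05)
    sbar = float(np.mean(np.sin(np.pi * (np.arange(m) + 1) / (m + 1)))) \
        if m > 0 else 1.0
    amps = np.asarray(c.bulge_step_means[:c.n_steps], dtype=float) * f / sbar

    # reference markers: three per endcap at 120 degrees (non-collinear),
    # half-embedded into the outer endcap face (clear of bone and glass beads)
    pin = []
    for zc, phase in ((-0.5 * c.disc_height - c.bone_height - c.endcap_height, 0.0),
                      (0.5 * c.disc_height + c.bone_height + c.endcap_height,
                       np.pi / 3)):
        for k in range(3):
            a = phase + k * 2 * np.pi / 3
            rr = 0.6 * c.disc_radius
            pin.append([rr * np.cos(a), rr * np.sin(a), zc])

    return {
        "np_fraction_sampled": frac, "np_radius": r_np, "np_center": off,
        "increments": inc, "cumulative": cum,
        "marker_lines": lines, "marker_levels": levels, "marker_theta": theta,
        "marker_r": r, "marker_z": z, "bulge_factor": f, "sbar": sbar,
        "amplitudes": amps, "beta": c.bulge_anterior_bias,
        "pinpoints": np.asarray(pin),
    }


def _marker_table(config: PhantomConfig, geom: dict, pos: np.ndarray,
                  pos_vol: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "id": geom["marker_lines"] * config.markers_per_line + geom["marker_levels"],
        "line": geom["marker_lines"], "level": geom["marker_levels"],
        "zone": zone_from_azimuth(geom["marker_theta"]),
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "xv": pos_vol[:, 0], "yv": pos_vol[:, 1], "zv": pos_vol[:, 2],
    })


def _marker_positions(config: PhantomConfig, geom: dict, D: float) -> np.ndarray:
    """Analytic marker positions under cumulative platen displacement D."""
    c = config
    h, hp = c.disc_height, c.disc_height - D
    zeta = (geom["marker_z"] + 0.5 * h) / h
    znew = -0.5 * h + zeta * hp
    amp = geom["amplitudes"][_step_of(geom, D)] if D > 0 else 0.0
    A = amp * (1 + geom["beta"] * np.sin(geom["marker_theta"]))
    rnew = geom["marker_r"] + A * np.sin(np.pi * zeta)
    if D > 0:   # rigid beads cannot interpenetrate: axially declutter lines
        znew = _declutter_lines(znew, geom["marker_lines"], c.marker_diameter)
    return np.stack([rnew * np.cos(geom["marker_theta"]),
                     rnew * np.sin(geom["marker_theta"]), znew], axis=1)


def _declutter_lines(z: np.ndarray, lines: np.ndarray, d_min: float) -> np.ndarray:
    """Enforce a minimum axial centre distance within each marker line.

    Compression squeezes same-line beads together; physically they stack in
    contact instead of interpenetrating.  Gaps below ``d_min`` are widened
    sequentially and the line is re-centred so its mean height is preserved.
    """
    z = z.copy()
    for ln in np.unique(lines):
        sel = np.flatnonzero(lines == ln)
        order = sel[np.argsort(z[sel])]
        zz = z[order]
        adj = zz.copy()
        for i in range(1, len(adj)):
            adj[i] = max(adj[i], adj[i - 1] + d_min)
        z[order] = adj + (zz.mean() - adj.mean())
    return z


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _grid(config: PhantomConfig, spacing, geom: dict):
    c = config
    spacing = np.asarray(spacing, dtype=float) * np.ones(3)
    amp_max = float(geom["amplitudes"].max() * (1 + abs(geom["beta"]))) \
        if len(geom["amplitudes"]) else 0.0
    rad = max(c.disc_radius + 0.85 * c.marker_diameter + amp_max,
              c.disc_radius + c.endcap_extra_radius) + c.margin
    zhalf = 0.5 * c.disc_height + c.bone_height + c.endcap_height \
        + 0.5 * c.pinpoint_diameter + 0.7
    n_xy = np.ceil(2 * rad / spacing[:2]).astype(int)
    n_z = int(np.ceil(2 * zhalf / spacing[2]))
    shape = (n_xy[0], n_xy[1], n_z)
    origin = np.array([-rad, -rad, -zhalf]) + 0.5 * spacing
    return shape, origin, spacing


def _render_labels(config: PhantomConfig, geom: dict, shape, origin, spacing,
                   D: float = 0.0, perturb: RigidTransform | None = None,
                   with_np: bool = True) -> np.ndarray:
    """Evaluate the (possibly deformed and rigidly moved) tissue label field."""
    c = config
    h = c.disc_height
    hp = h - D
    z0 = -0.5 * h
    nx, ny, nz = shape
    lab = np.zeros(shape, dtype=np.int8)
    xs = (origin[0] + spacing[0] * np.arange(nx)).astype(np.float32)
    ys = (origin[1] + spacing[1] * np.arange(ny)).astype(np.float32)
    zs = (origin[2] + spacing[2] * np.arange(nz)).astype(np.float32)
    if perturb is not None:
        Rt = perturb.rotation.T
        shift = perturb.center - Rt @ (perturb.center + perturb.translation)
        Rt32 = Rt.astype(np.float32)
        sh32 = shift.astype(np.float32)
    else:
        Rt32 = sh32 = None

    block = max(1, int(6e6 // (nx * ny)))
    for zb in range(0, nz, block):
        ze = min(nz, zb + block)
        X, Y, Z = np.meshgrid(xs, ys, zs[zb:ze], indexing="ij")
        if Rt32 is not None:
            pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()])
            pts = Rt32 @ pts + sh32[:, None]
            X = pts[0].reshape(X.shape)
            Y = pts[1].reshape(X.shape)
            Z = pts[2].reshape(X.shape)
        R2 = X * X + Y * Y
        out = np.zeros(X.shape, dtype=np.int8)

        rec2 = (c.disc_radius + c.endcap_extra_radius) ** 2
        rb2 = max(c.disc_radius - c.bone_radius_margin, 0.1) ** 2
        # bottom endcap / bone (fixed)
        zcap0 = z0 - c.bone_height - c.endcap_height
        out[(Z >= zcap0) & (Z < z0 - c.bone_height) & (R2 <= rec2)] = LBL_ENDCAP_BOTTOM
        out[(Z >= z0 - c.bone_height) & (Z < z0) & (R2 <= rb2)] = LBL_BONE_CAUDAL
        # disc (deformed): radial boundary with bulge
        zeta = (Z - z0) / hp
        in_disc_z = (zeta >= 0) & (zeta < 1)
        if np.any(in_disc_z):
            theta = np.arctan2(Y, X)
            amp = geom["amplitudes"][_step_of(geom, D)] if D > 0 else 0.0
            A = amp * (1 + geom["beta"] * np.sin(theta))
            Rd = c.disc_radius + A * np.sin(np.pi * np.clip(zeta, 0, 1))
            disc = in_disc_z & (R2 <= Rd * Rd)
            out[disc] = LBL_AF
            if with_np:
                ox, oy = geom["np_center"]
                rnp2 = (X - ox) ** 2 + (Y - oy) ** 2
                out[disc & (rnp2 <= geom["np_radius"] ** 2)] = LBL_NP
        # top bone / endcap (translated down by D)
        zt = z0 + hp
        out[(Z >= zt) & (Z < zt + c.bone_height) & (R2 <= rb2)] = LBL_BONE_CRANIAL
        out[(Z >= zt + c.bone_height) & (Z < zt + c.bone_height + c.endcap_height)
            & (R2 <= rec2)] = LBL_ENDCAP_TOP
        lab[:, :, zb:ze] = out
    return lab


def _step_of(geom: dict, D: float) -> int:
    return int(np.argmin(np.abs(geom["cumulative"] - D)))


def _paint_spheres(values: np.ndarray, origin, spacing, centers, radius: float,
                   intensity: float) -> None:
    """Anti-aliased spheres: alpha-blend by a linear edge profile one voxel
    wide, so the intensity-weighted centroid is recoverable to sub-voxel
    accuracy."""
    spacing = np.asarray(spacing, dtype=float)
    for cpt in np.atleast_2d(centers):
        lo = np.floor((cpt - radius - 2 * spacing - origin) / spacing).astype(int)
        hi = np.ceil((cpt + radius + 2 * spacing - origin) / spacing).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, values.shape)
        if np.any(lo >= hi):
            continue
        ax = [origin[d] + spacing[d] * np.arange(lo[d], hi[d]) for d in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        d = np.sqrt((X - cpt[0]) ** 2 + (Y - cpt[1]) ** 2 + (Z - cpt[2]) ** 2)
        alpha = np.clip((radius - d) / spacing.mean() + 0.5, 0.0, 1.0)
        sub = values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = \
            sub * (1 - alpha) + alpha * intensity


_CT_LEVEL_OF_LABEL = ("background", "bone", "bone", "disc", "disc",
                      "endcap", "endcap")
_MR_LEVEL_OF_LABEL = ("background", "bone", "bone", "disc", "np",
                      "endcap", "endcap")


def _labels_to_intensity(lab: np.ndarray, levels: dict, key_of_label) -> np.ndarray:
    lut = np.array([levels[k] for k in key_of_label], dtype=np.float32)
    return lut[lab]


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def generate_labels(config: PhantomConfig, rng: np.random.Generator | None = None):
    """Sample a specimen and return its tissue label volume (CT grid).

    Cheap path used when only the geometry is needed (e.g. nucleus volume
    fraction sampling); ``generate_phantom`` builds on the same routine.
    Returns ``(labels, geometry_dict)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    geom = _sample_geometry(config, rng)
    shape, origin, spacing = _grid(config, config.voxel_spacing, geom)
    lab = _render_labels(config, geom, shape, origin, spacing, D=0.0)
    return VoxelVolume(lab, spacing, origin, "CT"), geom


def generate_phantom(config: PhantomConfig, with_mr: bool = True):
    """Generate the preloaded CT volume, the MR-like volume and ground truth.

    The CT volume contains two greyscale-bright bone blocks, mid-grey PMMA
    endcaps, a low-intensity disc and the 40 bright ~1 mm surface markers;
    the MR-like volume is generated directly on its own coarse grid
    (0.3 x 0.3 x 1.0 mm) with the nucleus brighter than the annulus.
    Reference (PinPoint-style) markers are embedded in the endcaps of both.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    geom = _sample_geometry(config, rng)

    shape, origin, spacing = _grid(config, config.voxel_spacing, geom)
    lab = _render_labels(config, geom, shape, origin, spacing, D=0.0)
    labels = VoxelVolume(lab, spacing, origin, "CT")

    lv = config.greyscale_levels
    ct = _labels_to_intensity(lab, lv, _CT_LEVEL_OF_LABEL)
    pos0 = _marker_positions(config, geom, 0.0)
    _paint_spheres(ct, origin, spacing, pos0, 0.5 * config.marker_diameter,
                   lv["marker"])
    _paint_spheres(ct, origin, spacing, geom["pinpoints"],
                   0.5 * config.pinpoint_diameter, lv["pinpoint"])
    noise_sd = config.noise_sd_fraction * lv["bone"]
    if noise_sd > 0:
        ct += rng.standard_normal(ct.shape, dtype=np.float32) * np.float32(noise_sd)
    ct_vol = VoxelVolume(ct, spacing, origin, "CT")

    mr_vol = None
    if with_mr:  # MR-like volume generated directly on its own coarse grid
        mshape, morigin, mspacing = _grid(config, config.mr_spacing, geom)
        mlab = _render_labels(config, geom, mshape, morigin, mspacing, D=0.0)
        mlv = config.mr_levels
        mr = _labels_to_intensity(mlab, mlv, _MR_LEVEL_OF_LABEL)
        _paint_spheres(mr, morigin, mspacing, geom["pinpoints"],
                       0.5 * config.pinpoint_diameter, mlv["pinpoint"])
        if config.mr_noise_sd > 0:
            mr += rng.standard_normal(mr.shape, dtype=np.float32) * np.float32(config.mr_noise_sd)
        mr_vol = VoxelVolume(mr, mspacing, morigin, "MR")

    np_mask = VoxelVolume((lab == LBL_NP).astype(np.uint8), spacing, origin, "CT")
    n_np = int((lab == LBL_NP).sum())
    n_disc = int(((lab == LBL_AF) | (lab == LBL_NP)).sum())
    truth = GroundTruth(
        config=config,
        markers_per_step={0: _marker_table(config, geom, pos0, pos0)},
        applied_displacement_per_step=geom["cumulative"].copy(),
        step_increments=geom["increments"].copy(),
        np_label_volume=np_mask,
        labels=labels,
        field_params={k: geom[k] for k in
                      ("amplitudes", "beta", "sbar", "bulge_factor",
                       "np_radius", "np_center", "pinpoints", "marker_theta",
                       "marker_r", "marker_z", "marker_lines", "marker_levels",
                       "increments", "cumulative", "np_fraction_sampled")},
        rigid_per_step={0: RigidTransform.identity()},
        np_volume_fraction=n_np / n_disc if n_disc else float("nan"),
    )
    return ct_vol, mr_vol, truth


def deform_phantom(truth: GroundTruth, step: int,
                   rigid_only: bool = False) -> VoxelVolume:
    """Render the CT volume after compression step ``step`` (1-based).

    Applies the analytic deformation (axial disc compression between rigid
    bone blocks plus the planted zone-dependent radial bulge), moves the
    markers with the disc surface, re-voxelizes on the preloaded grid, and
    applies a small random rigid perturbation of the whole specimen.  Updates
    ``truth.markers_per_step`` and ``truth.rigid_per_step`` in place and
    returns the deformed volume.  With ``rigid_only`` the deformation is
    suppressed (pure rigid motion, for registration invariance checks).
    """
    config = truth.config
    geom = truth.field_params
    if not (1 <= step <= config.n_steps):
        raise ValueError(f"step must be in 1..{config.n_steps}")
    D = 0.0 if rigid_only else float(truth.applied_displacement_per_step[step - 1])

    rng = np.random.default_rng([config.seed % (2 ** 31), 1000 + step])
    ang = rng.uniform(-config.rigid_rot_deg, config.rigid_rot_deg, size=3)
    tra = rng.uniform(-config.rigid_trans_mm, config.rigid_trans_mm, size=3)
    from scipy.spatial.transform import Rotation
    perturb = RigidTransform(Rotation.from_euler("xyz", ang, degrees=True).as_matrix(),
                             tra, np.zeros(3))

    ref = truth.labels
    shape, origin, spacing = ref.shape, ref.origin, ref.spacing
    lab = _render_labels(config, geom, shape, origin, spacing, D=D,
                         perturb=perturb, with_np=False)
    lv = config.greyscale_levels
    ct = _labels_to_intensity(lab, lv, _CT_LEVEL_OF_LABEL)

    pos = _marker_positions(config, geom, D)
    pos_vol = perturb.apply(pos)
    _paint_spheres(ct, origin, spacing, pos_vol, 0.5 * config.marker_diameter,
                   lv["marker"])
    # the top endcap (and its reference markers) moves down with the platen
    pin = geom["pinpoints"].copy()
    pin[pin[:, 2] > 0, 2] -= D
    pin_vol = perturb.apply(pin)
    _paint_spheres(ct, origin, spacing, pin_vol, 0.5 * config.pinpoint_diameter,
                   lv["pinpoint"])
    noise_sd = config.noise_sd_fraction * lv["bone"]
    if noise_sd > 0:
        ct += rng.standard_normal(ct.shape, dtype=np.float32) * np.float32(noise_sd)

    truth.markers_per_step[step] = _marker_table(config, geom, pos, pos_vol)
    truth.rigid_per_step[step] = perturb
    return VoxelVolume(ct, spacing, origin, "CT")


def generate_load_record(config: PhantomConfig, truth: GroundTruth,
                         noise_sd: float = 0.0,
                         rng: np.random.Generator | None = None,
                         model=None, materials=None) -> pd.DataFrame:
    """Synthetic load-displacement record at the phantom's step displacements.

    Default analytic mode: a monotone convex ramp from the 50 N preload to
    the configured peak, ``F(D) = F0 + (Fmax - F0) (a x + (1 - a) x^3)`` with
    ``x = D / D_total`` -- the stiffening shape of the measured curves without
    claiming their per-specimen values.  When ``model`` and ``materials`` are
    given, the record instead contains the forward FE reaction forces plus
    the preload (used by calibration-recovery tests).
    """
    cum = truth.applied_displacement_per_step
    if model is not None:
        from osteodisc.solver import forward_load_curve

        rec = forward_load_curve(model, materials, list(cum[:3]))
        rec["peak_load_N"] = rec["reaction_N"] + config.preload_N
        rec = rec[["step", "displacement_mm", "peak_load_N"]]
        rec = pd.concat([pd.DataFrame([{"step": 0, "displacement_mm": 0.0,
                                        "peak_load_N": config.preload_N}]), rec],
                        ignore_index=True)
    else:
        fmax, a = config.load_curve_params
        x = np.concatenate([[0.0], cum]) / cum[-1]
        F = config.preload_N + (fmax - config.preload_N) * (a * x + (1 - a) * x ** 3)
        rec = pd.DataFrame({"step": np.arange(len(x)),
                            "displacement_mm": np.concatenate([[0.0], cum]),
                            "peak_load_N": F})
    if noise_sd > 0:
        rng = np.random.default_rng(config.seed + 77) if rng is None else rng
        rec.loc[1:, "peak_load_N"] += rng.normal(0.0, noise_sd, size=len(rec) - 1)
    truth.peak_load_per_step = rec["peak_load_N"].to_numpy()[1:]
    return rec
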