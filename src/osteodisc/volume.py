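"""Voxel volumes and the image-processing arm.

Implements the in vitro image chain: greyscale rescaling to the 0-255 range
used by the calibrated bone-property mapping, rigid registration of each
compression-step CT volume to the preloaded CT (caudal-bone intensity
matching) and of the MR volume to the CT (reference-marker point matching),
trilinear resampling onto the CT grid, automatic glass-marker centroid
detection, and measurement of the applied platen displacement from the
distance between the inner surfaces of the PMMA endcaps.

Coordinate convention: right-handed world coordinates in mm, axes ordered
(x, y, z) with z the cranio-caudal (loading) axis and +y anterior; voxel
indices are 0-based and world = origin + index * spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.segmentation import watershed

__all__ = [
    "VoxelVolume",
    "RigidTransform",
    "MarkerSet",
    "ZONES",
    "rescale_greyscale",
    "register_rigid",
    "resample_to",
    "detect_markers",
    "detect_reference_markers",
    "measure_applied_displacement",
]

#: Zone labels of the eight 45-degree azimuthal sectors of the disc surface,
#: indexed counterclockwise from the +x (left lateral) axis; anterior is +y.
ZONES = ("L", "AL", "A", "AR", "R", "PR", "P", "PL")


@dataclass
class VoxelVolume:
    """3D scalar field on a regular grid with physical spacing and origin."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    modality: str = "CT"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float) * np.ones(3)
        self.origin = np.asarray(self.origin, dtype=float) * np.ones(3)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self):
        return self.values.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.values.copy(), self.spacing.copy(),
                           self.origin.copy(), self.modality)

    def sample(self, xyz: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Interpolate the field at world points (n, 3)."""
        idx = self.world_to_index(np.atleast_2d(xyz))
        return ndimage.map_coordinates(self.values.astype(np.float32), idx.T,
                                       order=order, cval=cval, mode="constant")

    # -- NIfTI I/O -----------------------------------------------------------
    def save(self, path: str) -> None:
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, path)

    @classmethod
    def load(cls, path: str, modality: str = "CT") -> "VoxelVolume":
        import nibabel as nib

        img = nib.load(path)
        aff = img.affine
        spacing = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
        return cls(np.asanyarray(img.dataobj).astype(np.float32),
                   spacing, aff[:3, 3], modality)


@dataclass
class RigidTransform:
    """Rigid map ``x_fixed = R @ (x_moving - center) + center + translation``.

    ``center`` is a convenience pivot; ``det(R) = +1`` always.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    residual: float = float("nan")

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.center) @ self.rotation.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        # x_m = R^T (x_f - c - t) + c  ->  rewrite about the same pivot
        t = R @ (-self.translation)
        return RigidTransform(R, t, self.center, self.residual)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        R = self.rotation @ other.rotation
        # self(other(x)) with both pivots folded into a single pivot at self.center
        shift = self.apply(other.apply(self.center)) - self.center
        return RigidTransform(R, shift, self.center)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.center + self.translation - self.rotation @ self.center
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3], np.zeros(3))

    def save(self, path: str) -> None:
        np.savetxt(path, self.as_matrix())

    @classmethod
    def load_file(cls, path: str) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path))


@dataclass
class MarkerSet:
    """Labelled fiducial-marker centroids in a common specimen frame.

    ``table`` columns: id, line (0-7), level (0-4), zone, x, y, z (mm).
    Marker ids are stable across compression steps so that displacement is
    tracked per physical marker, never re-derived from deformed azimuth.
    """

    table: pd.DataFrame

    def __len__(self):
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    def transformed(self, transform: RigidTransform) -> "MarkerSet":
        out = self.table.copy()
        out[["x", "y", "z"]] = transform.apply(self.centroids)
        return MarkerSet(out)

    def save(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str) -> "MarkerSet":
        return cls(pd.read_csv(path))


def zone_from_azimuth(theta: np.ndarray) -> np.ndarray:
    """Map azimuth (rad, atan2(y, x)) to the eight 45-degree sector labels."""
    sector = np.round(np.asarray(theta) / (np.pi / 4)).astype(int) % 8
    return np.asarray(ZONES)[sector]


# ---------------------------------------------------------------------------
# Greyscale rescaling
# ---------------------------------------------------------------------------

def rescale_greyscale(volume: VoxelVolume) -> VoxelVolume:
    """Linearly map intensities onto [0, 255] (order preserving).

    The greyscale-to-bone-modulus mapping is calibrated on normalised images,
    so every CT volume is rescaled before material assignment.
    """
    v = volume.values
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise ValueError("cannot rescale a constant volume")
    out = (v.astype(np.float32) - lo) * (255.0 / (hi - lo))
    return VoxelVolume(out, volume.spacing.copy(), volume.origin.copy(), volume.modality)


# ---------------------------------------------------------------------------
# Bright-blob segmentation (shared by glass and reference marker detection)
# ---------------------------------------------------------------------------

def _bright_threshold(values: np.ndarray) -> float:
    """Threshold separating the brightest intensity class.

    Two-stage Otsu: first split background/soft tissue from dense material,
    then split the dense set again; bright blobs are above the second cut.
    """
    sub = values[::2, ::2, ::2].ravel()
    t1 = threshold_otsu(sub)
    upper = sub[sub > t1]
    if upper.size < 16 or np.ptp(upper) == 0:
        return t1
    return float(threshold_otsu(upper))


def _split_touching(mask: np.ndarray, spacing: np.ndarray, radius_mm: float):
    """Watershed split of fused blobs seeded at distance-transform maxima.

    The mask is upsampled 2x first: on the native grid the distance
    transform of two touching spheres can plateau across the neck, merging
    the seeds.  Peak plateaus closer than about one blob radius are merged
    into a single seed so that a lone sphere is never over-split."""
    up = mask.repeat(2, 0).repeat(2, 1).repeat(2, 2)
    s2 = np.asarray(spacing, dtype=float) / 2.0
    dist = ndimage.distance_transform_edt(up, sampling=s2)
    r_vox = max(2, int(round(radius_mm / float(np.mean(s2)))))
    peaks = (dist == ndimage.maximum_filter(dist, size=r_vox + 1)) & (dist > 0)
    peaks = ndimage.binary_dilation(peaks, iterations=max(1, r_vox // 3))
    seeds, n = ndimage.label(peaks & up)
    if n < 2:
        return mask.astype(np.int32), 1
    lab = watershed(-dist, seeds, mask=up)
    return lab[::2, ::2, ::2], int(lab.max())


def _bright_components(volume: VoxelVolume, nominal_mm3: float,
                       gate=(0.3, 3.0), threshold: float | None = None,
                       split: bool = True):
    """Centroids (intensity weighted, mm) and volumes of bright blobs.

    Blobs outside the ``gate`` (in multiples of the nominal blob volume) are
    discarded, which removes both single-voxel noise speckle and the large
    bone/endcap bodies whose noise tails exceed the intensity threshold.
    Components larger than ~1.5 nominal volumes are treated as touching blobs
    and split by watershed on the distance transform.
    """
    v = volume.values
    thr = _bright_threshold(v) if threshold is None else threshold
    mask = v > thr
    voxel_vol = float(np.prod(volume.spacing))
    radius_mm = (3 * nominal_mm3 / (4 * np.pi)) ** (1 / 3)
    lab, n = ndimage.label(mask)
    if n == 0:
        return np.zeros((0, 3)), np.zeros(0)
    counts = np.bincount(lab.ravel())[1:]
    vols = counts * voxel_vol
    lo, hi = gate[0] * nominal_mm3, gate[1] * nominal_mm3
    split_lo = min(1.25 * nominal_mm3, hi)
    singles = np.flatnonzero((vols >= lo) & (vols < split_lo)) + 1
    fused = np.flatnonzero((vols >= split_lo) & (vols <= 2.2 * hi)) + 1

    objects = ndimage.find_objects(lab)
    centroids, out_vols = [], []

    def _component_centroid(comp_mask, slc):
        idx = np.argwhere(comp_mask)
        w = np.clip((v[slc][comp_mask] - thr).astype(float), 1e-6, None)
        c_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
        c_idx += [s.start for s in slc]
        return volume.index_to_world(c_idx)

    for lb in singles:
        slc = objects[lb - 1]
        comp = lab[slc] == lb
        centroids.append(_component_centroid(comp, slc))
        out_vols.append(vols[lb - 1])
    for lb in fused:
        slc = objects[lb - 1]
        comp = lab[slc] == lb
        if not split:
            if vols[lb - 1] <= hi:
                centroids.append(_component_centroid(comp, slc))
                out_vols.append(vols[lb - 1])
            continue
        sub_lab, m = _split_touching(comp, volume.spacing, radius_mm)
        parts = []
        for k in range(1, m + 1):
            pmask = sub_lab == k
            cvol = pmask.sum() * voxel_vol
            if cvol >= lo:
                parts.append((pmask, cvol))
        if len(parts) <= 1 and vols[lb - 1] <= hi:
            centroids.append(_component_centroid(comp, slc))
            out_vols.append(vols[lb - 1])
        else:
            for pmask, cvol in parts:
                centroids.append(_component_centroid(pmask, slc))
                out_vols.append(cvol)
    if not centroids:
        return np.zeros((0, 3)), np.zeros(0)
    return np.asarray(centroids), np.asarray(out_vols)


# ---------------------------------------------------------------------------
# Marker detection
# ---------------------------------------------------------------------------

def detect_markers(volume: VoxelVolume, expected_n: int = 40,
                   marker_diameter: float = 1.0, n_lines: int = 8,
                   threshold: float | None = None) -> MarkerSet:
    """Detect glass fiducial markers and match them to the line/level layout.

    Bright blobs are segmented by two-stage Otsu thresholding and connected
    components, size-gated to [0.3, 3.0] x the nominal marker volume, and the
    centroid of each is the intensity-weighted mean of its voxels.  Detected
    blobs are assigned a craniocaudal line by azimuth about the marker-cloud
    axis, and a level by axial rank within the line.

    Raises ``ValueError`` when the count differs from ``expected_n``.
    """
    nominal = (np.pi / 6.0) * marker_diameter ** 3
    cents, _vols = _bright_components(volume, nominal, gate=(0.3, 3.0),
                                      threshold=threshold)
    if len(cents) != expected_n:
        raise ValueError(
            f"marker detection found {len(cents)} blobs, expected {expected_n}")
    if expected_n == 0:
        return MarkerSet(pd.DataFrame(
            columns=["id", "line", "level", "zone", "x", "y", "z"]))

    center_xy = cents[:, :2].mean(axis=0)
    rel = cents[:, :2] - center_xy
    theta = np.arctan2(rel[:, 1], rel[:, 0])

    # global azimuthal offset of the line layout (circular mean of n_lines*theta)
    phase = np.angle(np.exp(1j * n_lines * theta).mean()) / n_lines
    sector = np.round((theta - phase) / (2 * np.pi / n_lines)).astype(int) % n_lines
    line = sector  # stable layout index in [0, n_lines)

    per_line = expected_n // n_lines
    rows = []
    for ln in range(n_lines):
        sel = np.flatnonzero(line == ln)
        if len(sel) != per_line:
            raise ValueError(
                f"line {ln}: found {len(sel)} markers, expected {per_line} "
                "(missing or spurious detections)")
        order = sel[np.argsort(cents[sel, 2])]
        for lvl, i in enumerate(order):
            rows.append({
                "id": ln * per_line + lvl, "line": ln, "level": lvl,
                "zone": zone_from_azimuth(theta[i]),
                "x": cents[i, 0], "y": cents[i, 1], "z": cents[i, 2],
            })
    return MarkerSet(pd.DataFrame(rows))


def detect_reference_markers(volume: VoxelVolume, diameter: float = 3.0,
                             threshold: float | None = None) -> np.ndarray:
    """Centroids (mm) of the large multi-modality reference markers."""
    nominal = (np.pi / 6.0) * diameter ** 3
    cents, _ = _bright_components(volume, nominal, gate=(0.3, 3.0),
                                  threshold=threshold, split=False)
    return cents[np.lexsort((cents[:, 0], cents[:, 1], cents[:, 2]))]


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

def _bone_roi_bbox(volume: VoxelVolume, caudal: bool = True, margin: float = 1.0):
    """Bounding box (world mm) of the most caudal bone block."""
    v = volume.values[::2, ::2, ::2]
    t1 = threshold_otsu(v)
    upper = v[v > t1]
    t2 = threshold_otsu(upper) if upper.size else t1
    # bone sits between the endcap class and the bright marker class: take the
    # largest dense components and pick the lowest one
    mask = volume.values > 0.5 * (t1 + t2)
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no dense structure found for the bone ROI")
    counts = np.bincount(lab.ravel())[1:]
    big = np.argsort(counts)[::-1][:2] + 1
    zc = [ndimage.center_of_mass(lab == b)[2] for b in big]
    pick = big[int(np.argmin(zc))] if caudal else big[int(np.argmax(zc))]
    idx = np.argwhere(lab == pick)
    lo = volume.index_to_world(idx.min(axis=0)) - margin
    hi = volume.index_to_world(idx.max(axis=0)) + margin
    return lo, hi


def _crop(volume: VoxelVolume, lo: np.ndarray, hi: np.ndarray) -> VoxelVolume:
    i0 = np.maximum(np.floor(volume.world_to_index(lo)).astype(int), 0)
    i1 = np.minimum(np.ceil(volume.world_to_index(hi)).astype(int) + 1,
                    np.array(volume.shape))
    vals = volume.values[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    return VoxelVolume(vals, volume.spacing.copy(),
                       volume.index_to_world(i0), volume.modality)


def _rotation_from_euler_deg(angles_deg):
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()


def kabsch(moving_pts: np.ndarray, fixed_pts: np.ndarray) -> RigidTransform:
    """Least-squares rigid alignment of matched point sets (moving -> fixed)."""
    moving_pts = np.asarray(moving_pts, dtype=float)
    fixed_pts = np.asarray(fixed_pts, dtype=float)
    cm, cf = moving_pts.mean(axis=0), fixed_pts.mean(axis=0)
    H = (moving_pts - cm).T @ (fixed_pts - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cf - cm  # with pivot at the moving centroid
    out = RigidTransform(R, t, cm)
    res = np.sqrt(np.mean(np.sum((out.apply(moving_pts) - fixed_pts) ** 2, axis=1)))
    return replace(out, residual=float(res))


def _match_points(a: np.ndarray, b: np.ndarray):
    """Correspondence between two centroid constellations (translation-robust)."""
    from scipy.optimize import linear_sum_assignment

    da = a - a.mean(axis=0)
    db = b - b.mean(axis=0)
    cost = np.linalg.norm(da[:, None, :] - db[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(cost)
    return ri, ci


def register_rigid(moving: VoxelVolume, fixed: VoxelVolume,
                   roi: str = "caudal_bone", residual_threshold: float = 25.0,
                   max_iter: int = 200) -> RigidTransform:
    """Rigid registration of ``moving`` onto ``fixed``.

    ``roi='caudal_bone'``: multi-resolution mean-squares intensity matching
    restricted to the most caudal vertebra (the bone below the disc moves
    least during compression, so it anchors the common frame).
    ``roi='pinpoint_markers'``: closed-form Kabsch alignment of the reference
    marker constellations detected in both volumes (used for MR-to-CT).

    The returned transform maps moving-frame world points into the fixed
    frame.  A ``ValueError`` is raised when the final metric residual exceeds
    ``residual_threshold`` (RMS intensity units for the caudal mode, RMS mm
    times 100 for the pinpoint mode).
    """
    if roi == "pinpoint_markers":
        pm = detect_reference_markers(moving)
        pf = detect_reference_markers(fixed)
        if len(pm) < 3 or len(pf) < 3 or len(pm) != len(pf):
            raise ValueError(
                f"pinpoint registration needs matched marker sets "
                f"(found {len(pm)} moving, {len(pf)} fixed)")
        ri, ci = _match_points(pm, pf)
        t = kabsch(pm[ri], pf[ci])
        if t.residual * 100 > residual_threshold:
            raise ValueError(f"pinpoint registration residual too large: "
                             f"{t.residual:.3f} mm RMS")
        return t
    if roi != "caudal_bone":
        raise ValueError(f"unknown roi mode {roi!r}")

    lo, hi = _bone_roi_bbox(fixed, caudal=True)
    center = 0.5 * (lo + hi)
    fixed_roi = _crop(fixed, lo, hi)
    moving_roi = _crop(moving, lo - 2.0, hi + 2.0)
    bg = float(np.percentile(moving_roi.values[::4, ::4, ::4], 1))

    best = np.zeros(6)
    for stride, sigma, xtol in ((4, 1.5, 1e-6), (3, 0.8, 1e-6)):
        fv = ndimage.gaussian_filter(fixed_roi.values.astype(np.float32), sigma)
        mv = ndimage.gaussian_filter(moving_roi.values.astype(np.float32), sigma)
        sub = fv[::stride, ::stride, ::stride]
        ii = np.stack(np.meshgrid(*[np.arange(0, n, stride) for n in fv.shape],
                                  indexing="ij"), axis=-1).reshape(-1, 3)
        xf = fixed_roi.index_to_world(ii).astype(np.float32)
        target = sub.ravel().astype(np.float32)
        scale = 1.0 / np.sqrt(float(target.size))

        def residuals(p):
            R = _rotation_from_euler_deg(p[:3])
            xm = (xf - center - p[3:]) @ R + center  # R^T applied to rows
            idx = (xm - moving_roi.origin) / moving_roi.spacing
            vals = ndimage.map_coordinates(mv, idx.T, order=1, cval=bg,
                                           mode="constant")
            return (vals - target) * scale

        res = optimize.least_squares(residuals, best, method="lm",
                                     diff_step=1e-3, xtol=xtol, ftol=xtol,
                                     max_nfev=min(max_iter, 60))
        best = res.x
    rms = np.sqrt(np.mean((res.fun / scale) ** 2))
    if rms > residual_threshold:
        raise ValueError(f"registration residual too large: {rms:.2f}")
    return RigidTransform(_rotation_from_euler_deg(best[:3]), best[3:],
                          center, float(rms))


def resample_to(volume: VoxelVolume, reference: VoxelVolume,
                transform: RigidTransform, order: int = 1,
                cval: float | None = None) -> VoxelVolume:
    """Resample ``volume`` onto the grid of ``reference`` through ``transform``.

    Trilinear interpolation by default; voxels mapping outside the source
    field of view take the background value (the source minimum unless
    ``cval`` is given).
    """
    if cval is None:
        cval = float(volume.values.min())
    nx, ny, nz = reference.shape
    out = np.empty(reference.shape, dtype=np.float32)
    xs = reference.axis_coords(0).astype(np.float32)
    ys = reference.axis_coords(1).astype(np.float32)
    zs = reference.axis_coords(2).astype(np.float32)
    src = volume.values.astype(np.float32)
    # fold the inverse rigid map and the world->index map into one affine
    Rt = transform.rotation.T
    shift = transform.center - Rt @ (transform.center + transform.translation)
    A = (Rt / volume.spacing[:, None]).astype(np.float32)
    b = ((shift - volume.origin) / volume.spacing).astype(np.float32)
    block = max(1, int(6e6 // (nx * ny)))
    for z0 in range(0, nz, block):
        z1 = min(nz, z0 + block)
        X, Y, Z = np.meshgrid(xs, ys, zs[z0:z1], indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()])
        idx = A @ pts + b[:, None]
        out[:, :, z0:z1] = ndimage.map_coordinates(
            src, idx, order=order, cval=cval, mode="constant"
        ).reshape(nx, ny, z1 - z0)
    return VoxelVolume(out, reference.spacing.copy(), reference.origin.copy(),
                       volume.modality)


# ---------------------------------------------------------------------------
# Applied-displacement measurement
# ---------------------------------------------------------------------------

def _endcap_masks(volume: VoxelVolume):
    """Binary masks of the two PMMA endcaps (intensity class between soft
    tissue and bone, split into the top and bottom axial bodies)."""
    sub = volume.values[::2, ::2, ::2]
    thr = threshold_multiotsu(sub, classes=4)
    band = (volume.values > thr[1]) & (volume.values < thr[2])
    # remove the 1-2 voxel interpolation-blur shells around bone surfaces,
    # which otherwise connect to the endcap bodies and corrupt the surfaces
    band = ndimage.binary_opening(band, iterations=2)
    lab, n = ndimage.label(band)
    if n < 2:
        raise ValueError("could not isolate two endcap bodies")
    counts = np.bincount(lab.ravel())[1:]
    big = np.argsort(counts)[::-1][:2] + 1
    zc = [ndimage.center_of_mass(lab == b)[2] for b in big]
    bottom = lab == big[int(np.argmin(zc))]
    top = lab == big[int(np.argmax(zc))]
    return bottom, top


def _inner_surface_z(mask: np.ndarray, volume: VoxelVolume, inner_is_max: bool,
                     trim: float = 0.10) -> float:
    """Trimmed-mean world z of the endcap surface facing the disc.

    For each transverse column crossing the endcap, the inner surface sits at
    the last (bottom cap) or first (top cap) masked voxel; the voxel boundary
    is half a voxel beyond the centre.  Columns with fewer than 3 masked
    voxels are ignored, and a 10% trimmed mean over columns rejects bleed
    from markers or bone.
    """
    counts = mask.sum(axis=2)
    cols = counts >= 3
    if not cols.any():
        raise ValueError("endcap mask footprint is empty")
    nz = mask.shape[2]
    zidx = np.arange(nz)
    if inner_is_max:
        surf = np.where(mask, zidx[None, None, :], -1).max(axis=2)[cols] + 0.5
    else:
        surf = np.where(mask, zidx[None, None, :], nz).min(axis=2)[cols] - 0.5
    surf = np.sort(surf.astype(float))
    k = int(trim * len(surf))
    if 2 * k < len(surf):
        surf = surf[k:len(surf) - k]
    return float(volume.origin[2] + volume.spacing[2] * surf.mean())


def endcap_inner_distance(volume: VoxelVolume) -> float:
    """Axial distance (mm) between the inner surfaces of the PMMA endcaps."""
    bottom, top = _endcap_masks(volume)
    z_bot = _inner_surface_z(bottom, volume, inner_is_max=True)
    z_top = _inner_surface_z(top, volume, inner_is_max=False)
    return z_top - z_bot


def measure_applied_displacement(preloaded: VoxelVolume,
                                 deformed: VoxelVolume) -> float:
    """Applied platen displacement between two registered volumes (mm).

    Measured as the reduction in the axial distance between the inner
    surfaces of the PMMA endcaps; quantization error is of the order of one
    voxel (82 um at the reference CT resolution).
    """
    return endcap_inner_distance(preloaded) - endcap_inner_distance(deformed)
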