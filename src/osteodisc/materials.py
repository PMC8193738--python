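"""Hyperelastic constitutive models of the osteodisc tissues.

The annulus fibrosus (AF) is a Gasser-Ogden-Holzapfel (GOH) material: a
neo-Hookean matrix with two exponential tension-only fibre families at an
oblique/counter-oblique angle of 20 degrees to the transverse plane.  The
nucleus pulposus (NP) is a two-parameter Mooney-Rivlin solid.  Bone and PMMA
are effectively linear elastic (implemented as compressible neo-Hookean,
which coincides with linear elasticity at small strain); the bone modulus is
mapped element-by-element from the rescaled CT greyscale.  Near-
incompressibility is controlled through a calibrated bulk modulus K with the
volumetric energy U(J) = (K/2)(J - 1)^2 by default.

Energies use the isochoric split F_bar = J^(-1/3) F for both the deviatoric
matrix terms and the fibre pseudo-invariants:

    W_MR  = C10 (I1_bar - 3) + C01 (I2_bar - 3) + U(J)
    W_GOH = C10 (I1_bar - 3)
            + sum_f k1/(2 k2) [exp(k2 <I4f_bar - 1>^2) - 1] + U(J)

with Macaulay bracket <x> = max(x, 0): fibres carry load in extension only.
Stresses are the exact analytic derivatives of W; tangents (dP/dF) are
central finite differences of the analytic stress.

All quantities are in a consistent mm / N / MPa system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParams",
    "invariants",
    "mooney_rivlin_energy_stress",
    "goh_energy_stress",
    "neo_hookean_energy_stress",
    "bone_modulus_from_greyscale",
    "equivalent_poisson",
    "linearize_af_shear",
]


@dataclass
class MaterialParams:
    """Constitutive parameters for all tissues (MPa, degrees).

    AF/NP deviatoric constants are fixed, previously validated values; the
    bulk moduli ``af_K``/``np_K`` are the calibrated quantities and default
    to the bulk modulus of water (2200 MPa), which is also the calibration
    starting point.  ``af_C10_lin`` is a linear-equivalent AF shear constant
    used only when converting K to an equivalent Poisson's ratio.
    """

    af_C10: float = 0.25
    af_k1: float = 1.43
    af_k2: float = 1.63
    af_K: float = 2200.0
    af_fibre_angle_deg: float = 20.0
    np_C10: float = 0.07
    np_C01: float = 0.02
    np_K: float = 2200.0
    bone_slope: float = 842.0 / 255.0     # MPa per greyscale unit; intercept 0
    bone_intercept: float = 0.0           # reverse-engineered, non-authoritative
    bone_E_min: float = 3.6
    bone_nu: float = 0.3
    pmma_E: float = 1035.0                # table value; 2450.0 is the text variant
    pmma_nu: float = 0.3
    af_C10_lin: float = 1.92
    volumetric: str = "quadratic"         # or "simo-taylor": (K/2)((J^2-1)/2 - ln J)

    def validate(self) -> None:
        for name in ("af_C10", "af_k1", "af_k2", "af_K", "np_C10", "np_C01",
                     "np_K", "bone_E_min", "pmma_E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.af_fibre_angle_deg < 90):
            raise ValueError("fibre angle must be in (0, 90) degrees")


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def invariants(F: np.ndarray) -> dict:
    """Deformation state derived from F (batched over leading axes).

    Returns J, C, C^-1, I1, I2 and their isochoric counterparts.
    Raises on non-positive J.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("non-positive Jacobian det(F)")
    C = np.einsum("...ki,...kj->...ij", F, F)
    Cinv = np.linalg.inv(C)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I2 = 0.5 * (I1 ** 2 - np.trace(np.einsum("...ik,...kj->...ij", C, C),
                                   axis1=-2, axis2=-1))
    Jm23 = J ** (-2.0 / 3.0)
    return {"J": J, "C": C, "Cinv": Cinv, "I1": I1, "I2": I2,
            "I1b": Jm23 * I1, "I2b": Jm23 ** 2 * I2, "Jm23": Jm23}


def _vol_terms(J: np.ndarray, K: float, kind: str):
    """Volumetric energy U(J) and the pressure-like term dU/dJ."""
    if kind == "quadratic":
        return 0.5 * K * (J - 1.0) ** 2, K * (J - 1.0)
    if kind == "simo-taylor":
        return 0.5 * K * (0.5 * (J ** 2 - 1.0) - np.log(J)), 0.5 * K * (J - 1.0 / J)
    raise ValueError(f"unknown volumetric energy {kind!r}")


def _finalize(F, inv, S_iso, W, dUdJ):
    """Assemble total second PK stress and convert to Cauchy."""
    J, Cinv = inv["J"], inv["Cinv"]
    S = S_iso + (J * dUdJ)[..., None, None] * Cinv
    P = np.einsum("...ik,...kj->...ij", F, S)
    sigma = np.einsum("...ik,...jk->...ij", P, F) / J[..., None, None]
    return W, S, P, sigma


def _mr_core(F, C10, C01, K, volumetric):
    inv = invariants(F)
    J, C, Cinv = inv["J"], inv["C"], inv["Cinv"]
    I1, I2, Jm23 = inv["I1"], inv["I2"], inv["Jm23"]
    U, dUdJ = _vol_terms(J, K, volumetric)
    W = C10 * (inv["I1b"] - 3.0) + C01 * (inv["I2b"] - 3.0) + U
    eye = np.broadcast_to(np.eye(3), C.shape)
    # d(I1_bar)/dC and d(I2_bar)/dC (isochoric projections)
    dI1b = Jm23[..., None, None] * (eye - (I1 / 3.0)[..., None, None] * Cinv)
    dI2b = (Jm23 ** 2)[..., None, None] * (
        I1[..., None, None] * eye - C - (2.0 * I2 / 3.0)[..., None, None] * Cinv)
    S_iso = 2.0 * (C10 * dI1b + C01 * dI2b)
    return _finalize(F, inv, S_iso, W, dUdJ)


def _goh_core(F, C10, k1, k2, K, fibre_dirs, volumetric):
    inv = invariants(F)
    J, C, Cinv = inv["J"], inv["C"], inv["Cinv"]
    I1, Jm23 = inv["I1"], inv["Jm23"]
    U, dUdJ = _vol_terms(J, K, volumetric)
    eye = np.broadcast_to(np.eye(3), C.shape)
    dI1b = Jm23[..., None, None] * (eye - (I1 / 3.0)[..., None, None] * Cinv)
    S_iso = 2.0 * C10 * dI1b
    W = C10 * (inv["I1b"] - 3.0) + U

    fibre_dirs = np.asarray(fibre_dirs, dtype=float)
    norms = np.linalg.norm(fibre_dirs, axis=-1, keepdims=True)
    if np.any(np.abs(norms - 1.0) > 1e-8):
        import warnings

        warnings.warn("fibre directions not unit length; normalizing")
        fibre_dirs = fibre_dirs / norms
    nfam = fibre_dirs.shape[-2]
    for f in range(nfam):
        a = fibre_dirs[..., f, :]
        I4 = np.einsum("...i,...ij,...j->...", a, C, a)
        I4b = Jm23 * I4
        x = np.maximum(I4b - 1.0, 0.0)     # Macaulay: compressed fibres idle
        expo = np.exp(k2 * x ** 2)
        W = W + k1 / (2.0 * k2) * (expo - 1.0)
        dWdI4b = k1 * x * expo
        aa = np.einsum("...i,...j->...ij", a, a)
        dI4b = Jm23[..., None, None] * (aa - (I4 / 3.0)[..., None, None] * Cinv)
        S_iso = S_iso + 2.0 * dWdI4b[..., None, None] * dI4b
    return _finalize(F, inv, S_iso, W, dUdJ)


def _nh_core(F, E, nu):
    """Compressible neo-Hookean for the stiff, small-strain phases
    (bone, PMMA): W = mu/2 (I1 - 3) - mu ln J + lam/2 (ln J)^2."""
    E = np.asarray(E, dtype=float)
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    inv = invariants(F)
    J, Cinv = inv["J"], inv["Cinv"]
    lnJ = np.log(J)
    W = 0.5 * mu * (inv["I1"] - 3.0) - mu * lnJ + 0.5 * lam * lnJ ** 2
    eye = np.broadcast_to(np.eye(3), Cinv.shape)
    S = mu[..., None, None] * (eye - Cinv) + (lam * lnJ)[..., None, None] * Cinv
    P = np.einsum("...ik,...kj->...ij", F, S)
    sigma = np.einsum("...ik,...jk->...ij", P, F) / J[..., None, None]
    return W, S, P, sigma


def _tangent_fd(piola_fn, F, h: float = 1e-6):
    """dP/dF by central differences of the analytic first PK stress."""
    F = np.asarray(F, dtype=float)
    A = np.empty(F.shape[:-2] + (3, 3, 3, 3))
    for k in range(3):
        for L in range(3):
            dF = np.zeros((3, 3))
            dF[k, L] = h
            A[..., :, :, k, L] = (piola_fn(F + dF) - piola_fn(F - dF)) / (2 * h)
    return A


# ---------------------------------------------------------------------------
# Public constitutive operations
# ---------------------------------------------------------------------------

def mooney_rivlin_energy_stress(F, C10: float, C01: float, K: float,
                                volumetric: str = "quadratic",
                                with_tangent: bool = True):
    """Mooney-Rivlin energy, Cauchy stress and tangent at F (batched).

    Returns ``(W, sigma, A)`` with ``A = dP/dF`` (or None when
    ``with_tangent`` is off); W in MPa (energy per reference volume).
    """
    W, _S, _P, sigma = _mr_core(F, C10, C01, K, volumetric)
    A = _tangent_fd(lambda G: _mr_core(G, C10, C01, K, volumetric)[2], F) \
        if with_tangent else None
    return W, sigma, A


def goh_energy_stress(F, C10: float, k1: float, k2: float, K: float,
                      fibre_dirs, volumetric: str = "quadratic",
                      with_tangent: bool = True):
    """GOH (two discrete fibre families, no dispersion) energy/stress/tangent.

    ``fibre_dirs``: unit vectors, shape (..., n_families, 3).  Fibres under
    compression (I4_bar < 1) contribute nothing (Macaulay bracket).
    """
    W, _S, _P, sigma = _goh_core(F, C10, k1, k2, K, fibre_dirs, volumetric)
    A = _tangent_fd(lambda G: _goh_core(G, C10, k1, k2, K, fibre_dirs,
                                        volumetric)[2], F) if with_tangent else None
    return W, sigma, A


def neo_hookean_energy_stress(F, E, nu: float, with_tangent: bool = True):
    """Compressible neo-Hookean (bone/PMMA); E may vary per batch entry."""
    W, _S, _P, sigma = _nh_core(F, E, nu)
    A = _tangent_fd(lambda G: _nh_core(G, E, nu)[2], F) if with_tangent else None
    return W, sigma, A


def first_piola(F, kind: str, **kw):
    """First Piola-Kirchhoff stress for a named material (solver entry)."""
    if kind == "mooney_rivlin":
        return _mr_core(F, kw["C10"], kw["C01"], kw["K"],
                        kw.get("volumetric", "quadratic"))[2]
    if kind == "goh":
        return _goh_core(F, kw["C10"], kw["k1"], kw["k2"], kw["K"],
                         kw["fibre_dirs"], kw.get("volumetric", "quadratic"))[2]
    if kind == "neo_hookean":
        return _nh_core(F, kw["E"], kw["nu"])[2]
    raise ValueError(f"unknown material kind {kind!r}")


def strain_energy(F, kind: str, **kw):
    """Energy density for a named material (same keywords as first_piola)."""
    if kind == "mooney_rivlin":
        return _mr_core(F, kw["C10"], kw["C01"], kw["K"],
                        kw.get("volumetric", "quadratic"))[0]
    if kind == "goh":
        return _goh_core(F, kw["C10"], kw["k1"], kw["k2"], kw["K"],
                         kw["fibre_dirs"], kw.get("volumetric", "quadratic"))[0]
    if kind == "neo_hookean":
        return _nh_core(F, kw["E"], kw["nu"])[0]
    raise ValueError(f"unknown material kind {kind!r}")


def bone_modulus_from_greyscale(greyscale, slope: float = 842.0 / 255.0,
                                intercept: float = 0.0,
                                e_min: float = 3.6) -> np.ndarray:
    """Linear greyscale-to-modulus map for bone, E = a GS + b (MPa).

    Input greyscale must already be rescaled to [0, 255].  The default slope
    is reverse-engineered so that GS = 255 maps to ~842 MPa (the reported
    upper bound) and is not an authoritative calibration; E is clamped below
    at 3.6 MPa (the reported lower bound).
    """
    gs = np.asarray(greyscale, dtype=float)
    if np.any(gs < 0) or np.any(gs > 255):
        raise ValueError("greyscale outside [0, 255]; rescale first")
    return np.maximum(slope * gs + intercept, e_min)


def equivalent_poisson(K, C10) -> np.ndarray:
    """Equivalent linear Poisson's ratio nu = (3K - 4C10) / (6K + 4C10).

    A reporting convenience for a calibrated bulk modulus K, using the
    linear-equivalent shear modulus G = 2 C10: strictly increasing in K and
    bounded above by the incompressible limit 0.5.
    """
    K = np.asarray(K, dtype=float)
    C10 = np.asarray(C10, dtype=float)
    if np.any(K <= 0) or np.any(C10 <= 0):
        raise ValueError("K and C10 must be positive")
    return (3.0 * K - 4.0 * C10) / (6.0 * K + 4.0 * C10)


def linearize_af_shear(params: MaterialParams | None = None,
                       max_strain: float = 0.02, n_points: int = 8) -> dict:
    """Linear-equivalent C10 of the annulus from a small-strain uniaxial fit.

    Simulates uniaxial tension along the circumferential direction (in the
    fibre plane) of the GOH model at strains up to ``max_strain``, solving
    the lateral traction-free conditions, fits the stress-strain slope E and
    returns ``C10_lin = E / 6`` (incompressible relation E = 3G, G = 2 C10).
    With k1 = 0 this recovers the matrix C10 exactly.  Returns a dict with
    the fitted value, the fit mode, and the discrepancy from the reference
    linear-equivalent constant ``af_C10_lin`` (reported, not asserted: the
    strain mode/range behind that reference value is not fully specified).
    """
    from scipy.optimize import least_squares

    p = params or MaterialParams()
    alpha = np.deg2rad(p.af_fibre_angle_deg)
    # circumferential = e1, axial = e3; families at +/- alpha from transverse
    fibres = np.array([[np.cos(alpha), 0.0, np.sin(alpha)],
                       [np.cos(alpha), 0.0, -np.sin(alpha)]])

    def stress_for(lam1):
        def lateral(q):
            F = np.diag([lam1, q[0], q[1]])
            sig = _goh_core(F, p.af_C10, p.af_k1, p.af_k2, p.af_K, fibres,
                            p.volumetric)[3]
            return [sig[1, 1], sig[2, 2]]

        sol = least_squares(lateral, [1.0 / np.sqrt(lam1)] * 2, xtol=1e-12,
                            ftol=1e-12)
        F = np.diag([lam1, sol.x[0], sol.x[1]])
        return _goh_core(F, p.af_C10, p.af_k1, p.af_k2, p.af_K, fibres,
                         p.volumetric)[3][0, 0]

    strains = np.linspace(max_strain / n_points, max_strain, n_points)
    sig = np.array([stress_for(1.0 + e) for e in strains])
    E = float(np.polyfit(strains, sig, 1)[0])
    c10_lin = E / 6.0
    return {
        "C10_lin": c10_lin,
        "E_fit": E,
        "fit_mode": f"uniaxial circumferential, strains <= {max_strain:g}, "
                    "traction-free lateral, incompressible-limit E = 6 C10",
        "reference": p.af_C10_lin,
        "discrepancy": c10_lin - p.af_C10_lin,
    }
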