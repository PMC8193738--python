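# Methods

`osteodisc` implements a combined experimental/computational workflow for
bone–disc–bone (osteodisc) specimens under stepwise axial compression: the
*in vitro* arm measures disc surface bulge from fiducial markers tracked in
micro-CT volumes, and the *in silico* arm builds specimen-specific nonlinear
finite-element (FE) models whose tissue compressibility is calibrated
against the measured peak loads. A synthetic phantom generator stands in for
physical specimens so that every stage is testable end to end.

## The synthetic specimen (stated world)

Each phantom is a cylindrical osteodisc: two vertebral bone blocks (15 mm
per side), an intervertebral disc (annulus fibrosus, AF, enclosing a nucleus
pulposus, NP), and PMMA endcaps, imaged on an 82 µm isotropic CT-like grid
and a coarse (0.3 × 0.3 × 1.0 mm) MR-like grid. Values fixed by the
experimental protocol being emulated:

| quantity | default | origin |
|---|---|---|
| CT voxel size | 0.082 mm isotropic | scanner protocol |
| markers | 40 glass beads, ~1 mm, 8 craniocaudal lines at 45°, 5 per line | specimen preparation |
| platen displacement per step | N(0.89, 0.14²) mm, 4 steps | measured across the cohort |
| preload | 50 N | protocol |
| peak load at final step | 2.0 kN (monotone convex ramp) | measured maximum |
| NP volume fraction | U(0.07, 0.17) of disc volume | MR morphometry range |
| planted mean bulge per step | 0.24 / 0.48 / 0.67 / 0.84 mm | measured cohort means |
| marker-detection validation bounds | 90 µm transverse, 350 µm axial | manual-vs-automatic comparison |

Quantities the protocol does not fix were chosen once as realistic for young
bovine caudal segments and are config fields: disc height 7 mm, disc
diameter 14 mm (deliberately below full bovine size so an 82 µm volume stays
desk-tractable; resolution and layout are what the detection bounds depend
on), endcap thickness 4 mm, greyscale class means
(background/disc/PMMA/bone/bead = 20/60/120/175/235) with Gaussian noise of
sd 5% of the bone intensity, and a ±1°/±0.3 mm random rigid perturbation of
every deformed volume to exercise registration.

**Planted deformation field.** The disc compresses axially between rigid
bone blocks; the radial surface field is
`u_r(θ, ζ) = A(θ) sin(π ζ)` with `ζ` the relative height inside the
(compressed) disc and `A(θ) = a (1 + β sin θ)`, anterior = +y, β = 0.4 by
default — smooth, zero at the endplates, anterior-biased. Per specimen,
`a = f · m_k / s̄` where `m_k` is the configured step-k cohort mean,
`f ~ N(1, 0.3²)` is a specimen factor and `s̄` the mean of the marker-level
sine factors, so the across-cohort mean transverse marker displacement is
`m_k` by construction. The combination of the specimen factor (cv 0.30),
the anterior modulation (cv ≈ 0.28) and the level profile (cv ≈ 0.27)
yields a total scatter close to the measured cv ≈ 0.46.

**Markers.** Beads are rendered as anti-aliased spheres (linear one-voxel
edge profile) so intensity-weighted centroids are recoverable to sub-voxel
accuracy. Rigid beads cannot interpenetrate: when compression drives the
axial spacing of a line below one bead diameter, positions are decluttered
to contact spacing while preserving the line's mean height (the transverse
ground truth is unchanged). The vertebral radius sits 0.3 mm inside the
disc radius so displaced beads never touch the bone blob in intensity
space.

**What the generator does not emulate.** MR physics, beam hardening and
scanner artefacts; trabecular texture (bone is a uniform intensity class
plus noise, so greyscale-based moduli are near-uniform); soft-tissue
remnants on the disc surface; time-dependent relaxation. A green pipeline
test therefore establishes correctness of the measurement chain on clean
but realistically noisy geometry, not robustness to all clinical image
pathology.

## In vitro arm

1. **Rescaling** — linear map to [0, 255]; the bone greyscale→modulus map is
   calibrated on normalised images.
2. **Rigid registration** — each step volume is registered to the preloaded
   CT using the most caudal vertebra as reference: a mean-squares metric
   over the bone ROI, Gauss–Newton (Levenberg–Marquardt on intensity
   residuals) at two pyramid levels (stride 4/σ=1.5 then stride 3/σ=0.8).
   The MR volume is registered via the multi-modality endcap reference
   markers with closed-form Kabsch alignment (Hungarian correspondence).
3. **Marker detection** — two-stage Otsu threshold isolates the brightest
   class; connected components are size-gated to [0.3, 3.0]× the nominal
   bead volume (removing both noise speckle and bone/endcap bodies); blobs
   above 1.25× nominal are split by watershed on a 2× upsampled distance
   transform (touching beads); centroids are intensity-weighted; blobs are
   assigned to lines by azimuth (global phase estimated by circular mean)
   and to levels by axial rank. A count different from the expected 40 is
   an error, not a silent result.
4. **Applied displacement** — the axial distance between endcap inner
   surfaces: the PMMA intensity band (multi-Otsu) is opened (2 iterations,
   to remove one–two-voxel interpolation-blur shells around bone that would
   otherwise attach to the endcap component), split into the two cap
   bodies, and each inner surface is the 10%-trimmed mean of per-column
   boundary heights. Quantization error is of order one voxel.
5. **Bulge** — per marker, the Euclidean norm of the transverse-plane
   centroid displacement between the registered deformed and preloaded
   states, paired by marker id; normalised by the applied displacement for
   zone comparisons. Zones are compared with a Welch ANOVA (Shapiro and
   Levene are reported but do not gate it), Bonferroni-corrected pooled-SD
   pairwise t-tests follow a significant ANOVA, and agreement scoring drops
   markers in the lowest tenth percentile of experimental bulge (pooled,
   linear-interpolation percentile).

## In silico arm

**Materials** (mm/N/MPa). AF: Gasser–Ogden–Holzapfel with two discrete
fibre families (no dispersion parameter, since none is reported) at ±20° to
the transverse plane, C10 = 0.25 MPa, k1 = 1.43 MPa, k2 = 1.63, tension-only
fibres via the Macaulay bracket. NP: Mooney–Rivlin, C10 = 0.07, C01 = 0.02
MPa. Both use the isochoric split and the volumetric energy
U(J) = (K/2)(J−1)² (simplest convex choice; a Simo–Taylor form is available
via config); the bulk moduli K_AF, K_NP are the calibrated parameters,
starting from water (2200 MPa). Bone and PMMA are compressible neo-Hookean
(linear elastic at their small strains), bone E mapped linearly from the
0.5 mm mean-pooled greyscale with slope 842/255 MPa per unit (reverse-
engineered from the reported 3.6–842 MPa range; non-authoritative, config-
overridable) and clamped at 3.6 MPa. PMMA E = 1035 MPa (the tabulated
value; the alternative 2.45 GPa from the text is a config option). Stresses
are exact analytic derivatives of the energies; tangents are central finite
differences of the analytic stress (step 10⁻⁶).

**Equivalent Poisson's ratio.** Calibrated K values are reported as
ν = (3K − 4C10)/(6K + 4C10) with C10 = 0.07 (NP) and the linear-equivalent
C10 = 1.92 (AF). `linearize_af_shear` recomputes the AF linear-equivalent
constant from a small-strain uniaxial fit of the GOH model (traction-free
lateral directions, strains ≤ 2%, E = 6·C10 in the incompressible limit);
it yields ≈1.54 MPa against the 1.92 MPa reference — the fit mode behind
the reference is unspecified, so the function reports the discrepancy
rather than asserting agreement, and 1.92 remains the reporting constant.

**Meshing.** Conforming Kuhn (6-tet) subdivision of a cubic cell grid
sampled from the label volume; cell size = target_edge/√2 so the median
edge equals the target. Reference scale is 0.5–1.0 mm (≈10⁶ elements);
desk-scale runs use 1.5–2.5 mm with mesh-convergence checks standing in for
full resolution. Nucleus variants: `std_cyl` (NP:AF diameter ratio 0.5),
`fit_cyl` (cylinder volume matched to the MR mask, full disc height — the
height convention is a package choice), `mr` (MR mask mapped into the
mesh). Fibres are assigned per AF element from the local circumferential
direction; markers map to nearest disc-surface nodes and are not meshed.

**Solver.** Total-Lagrangian linear tetrahedra, Newton–Raphson with
adaptive substepping (halving on divergence, up to 8 times), sparse direct
linear solves, convergence at a free-dof residual below 10⁻⁶ of the
reaction-force norm. Axial reaction is the sum of internal axial forces on
the driven endcap face. *Known limitation:* pure-displacement linear tets
lock volumetrically as K/G grows; no F-bar or mixed element is implemented.
The same element is used to generate synthetic loads and to invert them, so
the locking bias cancels in calibration recovery, and on cohort studies the
calibrated K simply absorbs the element's residual stiffness bias — the
same logic by which the original calibration absorbs model error. An
optional `k_cap` limits the effective bulk modulus when exploring stiffer
regimes.

**Calibration.** Trust-region-reflective least squares in the
compressibilities (1/K_AF, 1/K_NP), bounds K ∈ [1, 10⁵] MPa, forward-
difference Jacobian with 1% relative steps (forward solves are expensive),
cost = RMS difference between experimental and computational loads over the
first three steps (the constitutive model is validated to ~30% compression;
the fourth step exceeds 50%). Success means RMS < 10% of the maximum
experimental load. Failed forward solves inside the optimisation return a
large penalty residual so the trust region retreats. With three load
targets and two parameters, (K_AF, K_NP) is identifiable only up to a
shallow cost valley; recovery quality is therefore judged on the load cost,
not on the individual moduli. Averaging across a
cohort is done on compressibility (mean of 1/K, then invert) by default —
compressibility is the stated calibrated quantity — with a `mode="modulus"`
alternative.

**Agreement.** Lin's concordance correlation coefficient with population
(1/n) moments and a Fisher-z CI using Lin's asymptotic variance (a sample-
moment option exists). Load agreement pools all specimen×step pairs per
(nucleus model, calibration mode) cell; bulge agreement applies the
tenth-percentile filter to the in-vitro values first and reports the
fraction of pairs whose difference is below the 82 µm image resolution.

## Numerical choices and degenerate inputs

- Registration assumes a coarse pre-alignment (the rig constrains the
  specimen); perturbations up to a few degrees/voxels converge. A metric
  residual above threshold raises instead of returning a bad transform.
- Constant volumes cannot be rescaled (error); a detection count other than
  expected, an empty endcap footprint, a single bulge zone, zero applied
  displacement, zero-variance CCC input, and non-positive J all raise.
- Percentile definition is linear interpolation (type 7), config-switchable.
- Welch ANOVA is computed directly from the closed form; the published
  implementation in `pingouin` is kept as an independent oracle in tests.
- Determinism: every stochastic stage takes a seed or Generator;
  `run_study` derives per-specimen seeds from the root seed.

## Desk scale vs reference scale

Tests and the acceptance script run the imaging chain at the reference
82 µm resolution but on a reduced-diameter specimen, and the FE chain on
coarse meshes (10³–10⁴ elements). Both scales are pure configuration; the
reference-scale settings (full bovine diameter, 0.5–1.0 mm edges) run the
identical code, only longer.
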