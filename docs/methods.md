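# Methods

## Problem and model

MEG source estimation needs the gain (leadfield) matrix `L` (M sensors ×
N sources), whose entry `L_ij` is the output of sensor `i` per unit dipole
moment at source `j` with a fixed (cortex-normal) orientation.  The
classical route fills `L` column by column: one quasi-static forward solve
per dipole.  This package instead fills it row by row using Lorentz
reciprocity: driving sensor coil `i` with a unit current slope `dI/dt`
induces an electric field `E_i` throughout the head, and

    L_ij = n_j · E_i(r_j)

up to the flux/area normalization of the sensor.  One charge solve per
*sensor* yields a whole row across arbitrarily many sources, so the cost
scales with M (hundreds) instead of N (up to millions).  Both routes are
implemented; their agreement on identical meshes is the package's central
validation.

### Charge-based boundary element solver

The head is a set of closed triangulated interfaces with piecewise-constant
isotropic conductivity.  The unknown is the induced surface charge density
at the interfaces.  Internally charges are stored in E-field units,
`rho_t = rho / (2 eps0)` (V/m); in these units the collocation system is

    rho_t_n − K_n n_n · Σ_{m≠n} A_m rho_t_m (r_n−r_m)/(2π|r_n−r_m|³)
        = K_n n_n · E_inc(r_n),

with `K = (σ_in − σ_out)/(σ_in + σ_out)` the conductivity contrast.  This
normalization keeps the system free of permittivity constants; a documented
accessor converts to C/m².  The boundary-condition side limits follow
directly from the stored density:

    n·E_outside = 2 σ_in /(σ_in−σ_out) · rho_t,
    n·E_inside  = 2 σ_out/(σ_in−σ_out) · rho_t,

which is how reciprocal rows are read off a cortical interface without any
secondary-field evaluation (the "charge shortcut").  A general path that
evaluates the total E-field at arbitrary interior points is kept for
source spaces that are not tied to a contrast surface.

Numerical choices:

- Collocation at face centers; the self term is excluded, its
  principal-value contribution being absorbed in the jump term.
- Near-field correction: source faces whose centers lie within
  `2·sqrt(mean face area)` of an evaluation point are integrated by
  barycentric subdivision into 16 subtriangles (order configurable).  The
  self entry of the surface-potential matrix uses the equal-area-disk value
  `rho_t·sqrt(A/π)`.
- Solver: restart-free GMRES, relative tolerance 1e-4, at most 60
  iterations, initial iterate equal to the right-hand side (the first-order
  approximation).  The matrix-vector backend is pluggable; the default
  assembles the dense interaction matrix once per head model and reuses it
  across all solves of a leadfield assembly, which is exact and, at phantom
  scale (≤ ~15k faces), faster than any approximate summation.  A blocked
  matrix-free backend provides the backend-equivalence cross-check.

### Sensors

Magnetometers are single square loops (side 21 mm by default),
planar gradiometers opposed coil pairs (10 mm loops, 16.8 mm baseline) —
representative values, configurable.  For flux integration each loop
carries a tensor-grid midpoint rule (64 points per loop; 128 observation
points per gradiometer).  Outputs are flux/area (T) for magnetometers and
flux difference/(baseline·area) (T/m) for gradiometers, so the two kinds
stay separable for whitening.  As induction coils, loop outlines are
discretized into ≥8 uniform current elements; with right-hand-rule winding
the reciprocity identity takes the form `flux = − p·E_coil`, a sign fixed
once in the row assembly and pinned by a free-space unit test.  The drive
slope is `dI/dt = 1 A/s`; the operating frequency is arbitrary in the
quasi-static regime.

### Direct (column-wise) forward path

Per dipole: primary field of a current dipole in the compartment
conductivity, charge solve, total surface potential (incident + single
layer), then the magnetic field at sensor quadrature points as the dipole's
Biot–Savart term plus the volume-current surface integral

    B_v(r) = −(μ0/4π) Σ_faces (σ_in−σ_out) A_m φ_m n_m×(r−r_m)/|r−r_m|³.

The sign convention was verified against the spherical-conductor closed
form (sub-percent agreement at 5120 faces).  The path has no adaptive
refinement, so its accuracy requires the dipole's clearance from any
interface to be of the order of the local face size or larger; phantom
generators are designed to respect this.

### Minimum-norm inverse and dSPM

The inverse chain follows the standard MNE construction: whitening by the
inverse matrix square root of the noise covariance (eigendecomposition,
eigenvalues below 1e-10 of the maximum truncated), a diagonal source prior
`R` from leadfield column norms, and

    M̄ = R L̄ᵀ (L̄ R L̄ᵀ + λ² I)⁻¹,  L̄ = Σ^(−1/2) L.

`λ² = 1/SNR²` with the whitened gain trace-normalized
(`trace(L̄RL̄ᵀ)/M = 1`); with `R = I`, `λ² = 0` the operator is the
minimum-norm pseudoinverse.  dSPM divides each source strength by
`sqrt(diag(M Σ Mᵀ))`.

**Depth weighting.** The package parameterizes the prior as
`R_jj = w_j^(−2e)` with `w_j` the column norm.  Two conventions circulate:
the literal `R = diag(w^(−1/2))` (e = 0.25) and the full column
normalization `R = diag(w^(−2))` (e = 1).  The default is e = 0.25 with an
additional weight floor at `max(w)/10`: on phantoms whose source spaces
contain magnetically near-silent (radially oriented) dipoles, the e = 1
prior assigns those sources unbounded variance and the minimum-norm
solution collapses onto them (tens of mm of localization error even for
noiseless self-consistent data), while the gentler default localizes to a
few mm.  Both readings remain available through the `exponent` knob.

## Synthetic phantoms and what they do (not) represent

- **Nested-sphere heads** (skin 0.25, skull 0.01, CSF 1.654, GM 0.275,
  WM 0.126 S/m) exercise the solver and the two assembly routes; icosphere
  meshes quantize face counts to 20·4^s.
- **Folded cortex**: a radially modulated sphere
  `r(θ,φ) = R(1 + a sin(kθ) sin(k(φ+φ0)))` with the azimuthal phase drawn
  from the seed.  With `a·k > 1` the discrete mean curvature (cotangent
  Laplace–Beltrami, positive convex) changes sign between gyral crowns and
  sulcal valleys, and sulcal-wall face normals become strongly tangential —
  the MEG-visible orientation.  The evaluation phantom
  (`build_evaluation_phantom`) uses one folded cortical boundary
  (base 62 mm, amplitude 11 mm, k = 8) inside skin/skull/CSF shells, with
  one source per cortical face placed 8 mm radially inward and oriented
  along the folded surface normal.  The radial depth keeps source-to-
  surface clearance comparable to the face size, which the unrefined direct
  path needs.
- What the phantoms do **not** emulate: subject anatomy (no real
  segmentations), a true two-surface cortical ribbon (a thin WM/GM pair
  would put sources closer to a surface than the mesh resolves — the
  regime the adaptive-refinement literature addresses), sensor noise with
  instrumental (sensor-space) components, and MEG/MRI coregistration
  error.  Passing tests therefore validate the numerics and the method's
  internal consistency, not performance on experimental data.

## Evaluation machinery

- **Noise model**: K dipoles drawn area-weighted without replacement from
  the cortical source space, each column a direct forward solve; noise
  draws are `ε = L_noise X/‖L_noise X‖`, `X ~ N(0,1)`.
- **SNR mixing**: `signal = (1−η) ε + η b` with unit-norm `b`, `ε`; the
  mixing weight η is bisected until the power-ratio SNR
  `std((1−η)ε+ηb)/std((1−η)ε)` hits the target within 0.1 %.  (The mixing
  weight is called η here to avoid clashing with the regularization λ².)
- **Localization**: peak of |x| and the unweighted arithmetic-mean centroid
  of the region `|x| ≥ T·max|x|` (T = 0.75 by default; area weighting by
  flag).  Magnitudes are used because fixed-orientation estimates are
  signed.
- **Error maps**: per probed dipole, `(1−λ0)·b_j + λ0·ε` at a fixed
  absolute noise fraction λ0, with the probed dipole's own noise strength
  forced to zero; both terms unit-normalized, which is what makes λ0 an
  absolute noise percentage.  Means and standard deviations of the
  centroid/peak distances are reported per dipole.
- **ROC/AUC**: sources above a strength threshold inside/outside a target
  region are classified TP/FP; the threshold sweeps all distinct normalized
  strengths, so the trapezoidal AUC is exact.  Target regions are tagged by
  thresholding discrete mean curvature (valleys) and growing a geodesic-
  radius ball around a seed until a requested fraction of the candidate
  area is covered.

## Problem sizes used by the validation suite

Chosen as the package's desk-scale study conditions: reciprocity
equivalence on three-shell spheres at 320 and 1280 faces per surface with 6
magnetometers and 500 tangential sources; the spherical-conductor oracle at
5120 faces; dense-solve verification at 400 faces; the localization phantom
with 5120 cortical faces (≈3.8 mm source spacing), 32 magnetometers, 64
noise dipoles, and 60–100 noise samples per level.  These are scaled-down
versions of the corresponding full-size experiments (which use hundreds of
sensors, thousands of noise dipoles and ~10× the samples); the qualitative
quantities they produce (sub-percent route agreement, few-mm noiseless
centroid error, noise-level-dependent scatter) are stable under the
scaling, while absolute error statistics naturally depend on sensor count
and mesh density.

## Known limitations

- No adaptive mesh refinement: dipoles closer to an interface than about
  one face size make the direct path unreliable (the reciprocal path is
  unaffected — the induced field of an external coil is smooth near the
  cortex).
- Fast-multipole acceleration is an interface, not an implementation; the
  dense backend bounds practical head models to a few tens of thousands of
  faces.
- Fixed normal orientations only; no free- or loose-orientation priors.
- The GMRES iteration count grows on geometrically degenerate models
  (nearly touching surfaces meshed coarser than their separation).
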