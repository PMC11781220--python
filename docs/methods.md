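# Methods

This note documents the physical model, the numerical choices, the synthetic
data generator, and the known limitations of `dftomo`.

## Forward model

Light propagation at both the excitation (x) and fluorescence-emission (m)
wavelengths is modeled by the continuous-wave diffusion approximation in a
highly scattering medium (μa ≪ μs′), with diffusion coefficient
D = 1/(3 μs′) and effective attenuation μeff = √(μa/D) = √(3 μa μs′). The
Galerkin finite-element discretization on linear tetrahedra yields
(K + C + B/2A) Φ = Q with the stiffness matrix K (diffusion), absorption
mass matrix C and boundary mass matrix B (Robin condition, effective
Fresnel coefficient A). All element integrals are closed-form for
element-constant coefficients, taken as the mean of the four nodal values:
the tet mass matrix is V(1+δij)/20 and the boundary-triangle mass is
area·(1+δij)/12. Units are cm and cm⁻¹ internally; the public API uses mm
for coordinates.

Point sources sit exactly at the fiber-tip coordinates (bare-tip model) and
are distributed to the containing element's nodes by barycentric weights;
no one-transport-mean-free-path depth offset is applied (the tips are
interstitial, not on a surface). The effective Fresnel coefficient defaults
to A = 1 (index matched): every source and detector is far from the box
boundary, so boundary handling is second order for all studies. Excitation
and emission optical properties default to identical values; distinct
per-wavelength fields are supported, and identical fields share one matrix
factorization. One sparse LU factorization per (mesh, optics, wavelength)
serves all fiber sources; reciprocity of the symmetric operator gives the
detector-side Green's functions from the same solves.

Accuracy: on an 80 mm box with default optics (μa = 0.50, μs′ = 8.7 cm⁻¹)
and a mesh graded to ~1 mm spacing around the source, the FEM fluence
matches the infinite-medium analytic kernel exp(−μeff d)/(4πDd) to better
than 5% everywhere between 5 and 15 mm from the source. The dominant error
is the O(h²) dispersion of linear elements against a field decaying with
μeff ≈ 3.6 cm⁻¹; mesh quality matters as much as density, which is why
meshes are built from body-centered-cubic (BCC) lattices (near-regular
Delaunay tetrahedra) rather than jittered cubic grids (sliver-prone).

## Measurements

Each ordered fiber pair (s, d), s ≠ d, contributes one normalized Born
ratio (fluorescence power over excitation power), indexed by
f(s,d) = d − 1 + (n−1)(s−1) + [s > d]. The Born model is linear in the
nodal fluorescent yield η = γ μaf, with the lumped nodal volume
(quarter of incident element volumes) discretizing the volume integral —
a graded mesh has no single element volume. The Jacobian is therefore
constant and is computed once per (mesh, optics) and reused across all
iterations and across parameter sweeps sharing the geometry.

## Stage 1: Levenberg–Marquardt / Tikhonov

The damped update η ← η + (JᵀJ + λᵢLᵀL)⁻¹Jᵀδ runs on a coarse inversion
mesh: with P the barycentric prolongation from inversion-mesh nodes to
forward-mesh nodes, the reduced Jacobian is J·P — exactly ∂F/∂η_coarse,
which keeps the update adjoint-consistent with the residual evaluated on
the forward mesh. λ is initialized to the largest diagonal entry of JᵀJ
(on the inversion mesh; J is constant, so the printed 10^(−i/4) schedule is
exact) and iteration stops when the residual norm decreases by less than
2% relative, rises, or after 20 iterations. The regularization matrix L
defaults to the identity; the soft-prior variant (−1/N_R off-diagonals for
same-region node pairs) is implemented for region-informed smoothing. The
default initial guess is a small uniform positive field ~1e-4 of the data
scale; both the modified update above and the full Tikhonov gradient step
(with the −λLᵀL(η−η₀) pull) are available, the modified form being the
default. For the identity regularizer the damped normal equations are
solved in measurement space (Woodbury identity) — exact, and far cheaper
than forming the coarse-mesh Hessian.

Stage-1 images look the way single-stage diffuse fluorescence
reconstructions always look: the inclusion appears as a smooth blob with
sensitivity-shaped artifacts near the fiber tips, the background is pushed
toward zero, and the node-averaged absolute relative error ⟨|e|⟩ sits near
90% even when the residual has dropped by orders of magnitude.

## Stage 2: region growing and hard-prior refit

Negative stage-1 lobes are clamped to zero, then regions are grown on the
forward mesh: seed at the global maximum (ties → lowest node index), take
as reference the mean of the seed and its mesh neighbors, absorb any
neighboring node above t_p × reference until exhaustion; seed further
regions while the best remaining node exceeds t_b × (region 1's reference),
each with its own neighborhood reference; everything left is background.
With t_p = t_b an extra (non-background) region can only arise from a
disconnected bright component. The transition matrix T collapses the
unknowns to one value per region; a Gauss–Newton step from the region-mean
initial guess solves the now-overdetermined problem exactly (the model is
linear; the iteration loop is kept for contract symmetry). Nine equidistant
threshold fractions spanning 0.33–0.87 (endpoints included; the grid is
configurable, and an "ordered" mode sweeps all 45 pairs t_b ≤ t_p for
smooth-profile targets) are tried and the partition with the smallest
residual norm wins; identical partitions arising from different thresholds
are fitted once.

## Synthetic phantoms and study conditions

The default scenario is a 52×57×40 mm box, background μa = 0.50 cm⁻¹,
μs′ = 8.7 cm⁻¹, a spherical inclusion of radius 6.7 mm centered at
(19, 25, 18) mm with μaf = 0.10 cm⁻¹ over a 0.01 cm⁻¹ background,
γ = 0.1, and the packaged 13-fiber clinical configuration. The 12-fiber
scenario (50×50×40 mm box, sphere R = 5.5 mm at (22.5, 27.5, 20) mm,
background μa = 0.24/μs′ = 8.3 cm⁻¹, inclusion optics μa = 0.20/μs′ = 15.7
cm⁻¹, zero background fluorophore) drives the detector cut-off study.
Corruption models:

* multiplicative Gaussian noise, s′ = s(1 + aZ), independent per pair and
  wavelength; results that would go negative are floored at 1e-3·s (Born
  ratios must stay positive; the event is logged);
* an absolute fluorescence cut-off Pcut = 4.5e-11 W. Born ratios are
  calibration-free, so an absolute power scale exists only for the cut-off:
  the source-power×coupling constant is set so the *weakest* clean
  fluorescence signal of the reference scenario equals 1e-11 W, placing the
  low tail below Pcut; sweeps calibrate once at their lowest-signal level
  and reuse the constant, mimicking a fixed instrument;
* uniform fiber-tip perturbations with per-axis intervals (e.g. ±0.5 mm
  laterally, ±1 mm axially).

Data generation and reconstruction never share a discretization: the two
meshes are independent random BCC-lattice realizations *of equal density*.
At the ~2 mm spacing used here, a denser data mesh (the classic
inverse-crime guard) injects a systematic Born-ratio mismatch of ~2% of
the data norm, because the two densities no longer share the same O(h²)
dispersion bias; that mismatch, not noise, then dominates the stage-2
partition selection. Equal-density independent realizations cancel the
shared bias (residual floor 0.7–0.9%) while guaranteeing that no node,
element or matrix of the data mesh enters the reconstruction. A denser
data mesh remains one parameter away (`Scenario.data_mesh_nodes`).

The studies in `dftomo.studies` (and `scripts/acceptance.py`) run at desk
scale: 16k-node forward/data meshes and 2.5k-node inversion meshes, versus
64k/28k/6.5k in the larger studies this emulates; a full sweep suite takes
a few minutes on one CPU. The noise study uses matched data/reconstruction
meshes (isolating noise from discretization effects), the optics-mismatch
study a single matched mesh, both with the coarse inversion mesh in the
loop.

## What passing tests do and do not show

The generator reproduces the *statistical* structure of interstitial CW
fluorescence data — geometry-dependent Born-ratio magnitudes,
multiplicative detection noise, cut-off censoring — but not spectrally
resolved detection, filter leakage, fiber NA effects, needle/fiber
perturbation of the light field, or tissue heterogeneity beyond a single
ellipsoidal/spherical inhomogeneity. Passing the synthetic studies shows
the two-stage inversion recovers piecewise-homogeneous fluorophore maps
under the diffusion model's own assumptions; it does not validate the
diffusion approximation itself against real tissue.

## Known limitations

* **Selection fragility at desk scale.** The stage-2 winner is the
  partition with the smallest data residual. The residual separating a
  correct 2-region partition from a spurious 3+-region one (split
  background, core/shell pairs) is of the order of the region-shape misfit
  left by the ~2 mm mesh (~1.4% of the data norm). Whenever measurement
  noise (1–2% amplitude) or model mismatch reaches that level, a minority
  of realizations select multi-region partitions whose background value is
  badly off, inflating seed-averaged noise-study metrics well beyond what
  the same pipeline achieves on clean data. Finer meshes lower the shape
  misfit and push this boundary out; at the sizes used here the noise
  study's background metric and node-averaged error should be read with
  that caveat. The same mechanism produces an occasional third
  "transitional" region in the low-contrast and mid-contrast scenarios —
  behavior the method genuinely exhibits, which at full scale appears only
  at contrast ≈ 2.5.
* Volume quantization: an inclusion of radius R is represented by
  ~(R/h)³ nodes; at R = 3–4 mm and h ≈ 2 mm single boundary nodes move the
  recovered volume by several percent.
* The background region is identified as the region with the most nodes
  and the inclusion as the region with the highest fitted value; for
  zero-background phantoms the background metric is reported as an
  absolute error scaled by the ground-truth inclusion value and flagged.
* No structural priors (ultrasound anatomy), no time- or frequency-domain
  propagation, no radiative-transfer/Monte-Carlo reference solver.
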