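# Methods

`emroadmap` implements, at desk scale, a navigation workflow for
endovascular aneurysm repair (EVAR) in which a precomputed database of
guidewire-insertion simulations is combined with intra-operative
electromagnetic (EM) sensor positions: the simulation whose virtual sensors
best match the measured ones is selected as the deformed 3D roadmap, and its
accuracy is quantified against the ground-truth deformed anatomy. This note
documents the models, their assumptions, the parameters that matter, and
the numerical choices.

## Synthetic phantom

The phantom emulates the anatomy class of a manufactured patient-specific
benchmark: an aneurysmatic abdominal aorta bifurcating into two markedly
tortuous iliac arteries, mounted in a box and fixed at connector rings.

* **Frame.** Right-handed, millimetres: +x patient-left→right, +y
  posterior→anterior, +z caudal→cranial. Frontal plane = x–z, sagittal
  plane = y–z. The aortic bifurcation sits at the origin.
* **Centerline.** The trunk runs straight down the z-axis (length 120 mm,
  base radius 9 mm) with a Gaussian radius bulge (amplitude 9 mm, σ = 22 mm,
  centered at 45% of trunk length) standing in for the fusiform aneurysm
  sac. Each iliac leaves at a 25° half-angle and is perturbed by windowed
  sinusoids in two transverse directions (amplitude 10 mm, wavelength
  100 mm; the window vanishes at both ends so the bifurcation and the
  connector positions stay put). The seed only draws sinusoid phases.
* **Iliac length 160 mm** (traversed arc ≈ 170 mm): chosen so that at the
  first scheduled stop — just past the aortic bifurcation — the full
  175 mm tip-to-last-sensor span of the tool is inside the model, as in the
  benchmark protocol.
* **Surface.** Each branch is swept with rotation-minimizing frames; the
  bifurcation is closed with a pair-of-pants triangulation (two outer
  half-ring strips, a saddle strip, two apex triangles), giving a surface
  watertight except for the three open rings (inlet + two iliac outlets).
  Open-ring vertices form the Dirichlet set (the connector rings).
  Sweeps whose centerline curvature radius drops below the local tube
  radius are rejected as self-intersecting, naming the branch.
* **Label maps.** A lumen volume marks a voxel 1 iff its center lies inside
  the ring-capped surface, computed slice-by-slice (planar section →
  polygon → vectorized point-in-polygon). Default spacing 1 mm, matching
  the slice thickness of typical abdominal CT. Voxel-center classification
  (no partial volume) matches the binary label-map overlap metrics below.

## Guidewire–vessel mechanics

The stiff-guidewire + sensorized-catheter assembly is a discrete elastic
rod; the vessel wall is a linearized elastic surface; the two couple through
frictionless penalty contact. This deliberately replaces a full explicit
finite-element simulation with a quasi-static solver that runs on a desk.

* **Rod.** Nodes every h = 3 mm; discrete bending energy
  Σ (EI/h)(1 − cos θ) at each interior joint. The free (intracorporeal)
  portion is parameterized by its segment unit tangents, so inextensibility
  is exact (segment strain 0, well under the 1% acceptance bound) and the
  stiff axial penalty that would otherwise dominate the conditioning
  disappears from the solve; an axial-penalty term remains in the energy
  bookkeeping for position-space states (warm starts). Default tool
  EI = 6000 N·mm², the flexural rigidity scale of a 0.035" steel-core
  stiff guidewire (E π d⁴/64 ≈ 6·10³ N·mm²); the distal 30 mm is a floppy
  tip at 1% EI. EI can instead be calibrated from a four-point bending
  record via `estimate_bending_stiffness`, which fits the initial slope
  k = dF/dδ and inverts the Euler–Bernoulli midspan closed form
  δ = F a (3L² − 4a²) / 48EI with a = (support span − load span)/2.
* **Wall.** Per-vertex springs to the reference position (elastic
  foundation) with stiffness `foundation_factor · E_eff · t · A_v / R²`,
  plus per-edge springs along the reference edge direction and an isotropic
  neighbor-coupling (graph-Laplacian) term. The Laplacian term stands in
  for shell bending: it spreads point loads into segment-scale deformation
  instead of local dimples. `foundation_factor = 0.01` is deliberately
  small: the physical benchmark model hangs between its connector rings and
  deforms mostly by global tube bending, which the neighbor coupling
  represents, while the foundation only anchors the configuration.
  E_eff = 0.05 MPa and t = 2 mm are free calibration parameters of this
  simplified wall, not measured material constants. Connector-ring
  vertices are eliminated from the system; the stiffness matrix is
  assembled once per vessel and prefactorized.
* **Contact.** One-sided quadratic penalty (60 N/mm) on the signed distance
  of rod nodes outside the lumen surface; the equal-and-opposite reaction
  is spread barycentrically onto the nearest triangle. Closest-point
  queries use nearest-vertex/nearest-centroid candidate faces plus all
  long junction faces. Friction is not modeled (μ = 0; the parameter is
  validated to zero).
* **Insertion.** The rod enters at the center of an iliac outlet ring along
  the direction d ∝ (tan θ_f, tan θ_s, 1) defined by the frontal- and
  sagittal-plane angles; the extracorporeal part is pinned to that line
  (the straight introducer channel). Insertion advances in 5 mm arc-length
  increments (with exact stops at scheduled depths), warm-starting each
  increment by sliding the rod along its own previous path and projecting
  any node that extrapolated outside the lumen back inside.
* **Equilibrium.** Each increment alternates two exact block
  minimizations: the rod block (L-BFGS in tangent space against frozen
  contact planes, with the wall's condensed normal compliance folded into
  the contact stiffness as a series spring — the standard cure for
  stiff-contact/soft-wall interface zigzag) and the wall block (the exact
  quadratic minimizer with linearized contact, solved as a low-rank
  Woodbury update on the prefactored stiffness). A damped fallback with
  per-block backtracking guarantees the total energy is non-increasing
  across accepted iterates. The solve stops when the relative energy change
  stays below 2·10⁻⁴ for three consecutive iterations *and* the
  pseudo-kinetic ratio — ½‖step displacement‖² (reference stiffness
  1 N/mm) over internal energy — is below 5%, the quasi-static counterpart
  of the kinetic/internal energy check used with explicit dynamics.
  A state is rejected if any rod node penetrates beyond the wall thickness.
  The truncation leaves ≈ 0.05 mm of slack along nearly-flat sliding modes;
  symmetry and reproducibility tests assert at that scale.

## EM tracking virtualization

Three virtual sensors sit on the rod at arc-length offsets 5, 105 and
175 mm from the tip (0.5/10.5/17.5 cm), measured along the deformed rod —
matching sensors glued to a bent catheter. Only positions are used.
Synthetic readings add isotropic Gaussian noise per coordinate
(default σ = 0.5 mm, a typical EM tracker accuracy scale; seeded), after an
optional rigid map into a physical (tracker) frame. Image and physical
frames are registered from ≥3 non-collinear fiducials by least-squares
rigid registration (Kabsch, reflection guarded out), reporting the RMS
fiducial registration error. The pipeline's seven synthetic fiducials sit
on the phantom's bounding box, one placed asymmetrically.

## Selection and evaluation

* **Sensor error.** e_sensor = (1/3) Σᵢ ‖s_exp,i − s_sim,i‖, invariant
  under any common rigid transform of both point sets.
* **Selection.** For each database record, e_sensor per scheduled step;
  records ranked by the unweighted mean across steps (the weighting is
  configurable but the plain mean is the default policy); argmin wins; ties
  within 10⁻⁹ mm go to the first record in database order with a flag.
  Records whose simulation failed are excluded with a logged reason rather
  than failing the database.
* **Surface mismatch.** Surfaces are sampled uniformly by area (default
  1 sample/mm², seeded) and measured against the other surface's triangles
  (exact nearest-triangle distance), both directions; reported as the
  symmetric Hausdorff maximum, percentiles, and fraction-below-threshold.
  Roles: u_gt (baseline vs ground-truth deformed), u_p (baseline vs
  predicted), e_aorta (predicted vs ground-truth deformed).
* **Regions.** Two mid-planes between consecutive sensors (normal along the
  inter-sensor chord) split the model into regions I (tip side), II, III.
  Points classified to both I and III (possible when planes intersect
  inside a bent model) go to the nearest sensor's region, with a logged
  count. Region masks classify voxel centers; an empty region reports NaN,
  never 0, to avoid fake improvements.
* **Overlap.** OV(Va, Vb) = 100·|Va ∩ Vb| / min(va, vb) on a shared grid;
  OV_P is predicted vs ground-truth deformed, OV_GT undeformed vs deformed
  (the same function applied to the baseline), and the roadmap improvement
  is Δ_OV = OV_P − OV_GT. Exports round to one decimal; full precision is
  kept internally.

## Reference experiment and what it shows

`emroadmap.experiments` builds the default phantom, runs the three-preset
database (α: θ_f = 4°, θ_s = 13°; β: 4°, 38°; γ: 23°, 30° — attitudes
respecting supine anatomical bounds of ±60°), designates one record the
experimental truth, and checks: (1) noiseless self-readings select their
generating record with zero error; (2) over 20 seeded σ = 0.5 mm replicates
per record, the generating record is re-selected; (3) the record selected
from noisy truth readings also attains the highest Δ_OV in the
most-deformed region (lowest OV_GT at the final position). At the frozen
study conditions the phantom deforms by roughly 3–12 mm (regional OV_GT
down to ≈ 68%), a scaled-down counterpart of the tens-of-millimetres
deformations reported for highly tortuous patient anatomy; problem sizes
(≈ 2 600 surface vertices, h = 3 mm, ≈ 60 increments per run) are chosen so
the full experiment runs in minutes on one core.

Passing these tests shows that the selection machinery identifies the
correct insertion condition from sensor data *under the generator's
assumptions*: exact rigid frames, isotropic noise, a single deformation
mode family parameterized by two angles, and the same solver producing
database and truth. It does not show robustness to real-world effects the
generator omits: EM field distortion, segmentation and registration error,
material heterogeneity and non-constant wall thickness, friction and
torsion of the tool, or model–patient mismatch.

## Numerical choices and degenerate inputs

* Voxelization slices dodge exact cap planes by a 10⁻⁶·spacing offset;
  grids can be forced to a shared origin/shape for overlap work.
* Coarse voxelization (spacing ≫ radius) yields few or zero voxels without
  error; empty intersections raise only when both volumes are empty.
* `sweep_tube_surface` rounds the circumferential resolution up to a
  multiple of 4 so the junction saddle vertices fall on the left/right
  separation plane.
* The rod's free nodes must form a contiguous suffix ending at the tip
  (the insertion problem's structure); other masks are rejected.
* All randomness (phantom phases, sensor noise, surface sampling) flows
  from explicit seeds; identical inputs reproduce bit-identical records.

## Known limitations

* The wall is linear and kinematically simplified; large rotations of the
  vessel are only approximated, and contact uses node-to-surface distance
  (no edge-edge terms), so the guard on penetration is part of the model.
* Quasi-static truncation leaves ~0.05 mm of configuration slack; metrics
  derived from positions inherit that scale.
* The bifurcation junction uses long strips; mesh quality there is lower
  than on the tubes (handled explicitly by the distance queries).
* Only frictionless contact is implemented; the friction hook validates
  μ = 0.
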