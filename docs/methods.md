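# Methods

## Model and objective

The estimand is the 6-DOF pose `Q = (p_x, p_y, p_z, θ_x, θ_y, θ_z)` of the
patella's local coordinate system (LCS) in the frame that holds the skin
markers. Conventions: millimetres and degrees; right-handed frames; Cardan
x-y-z sequence, `R = R_x(θ_x) R_y(θ_y) R_z(θ_z)`, chosen to match the
symbol order of the pose vector (the decomposition is implemented
explicitly; at gimbal lock, `|θ_y| = 90°`, the convention is `θ_z = 0`
with the residual rotation folded into `θ_x`). Pose error between a true
and an estimated LCS is reported as the translation offset expressed in
the *true* frame plus the Cardan decomposition of the relative rotation.

Each analysis-area face `i` of the bone mesh carries a soft-tissue
thickness `ε_i`: the distance from its centroid along its outward normal
to the first skin intersection, measured once in the CT frame and
pose-invariant thereafter. At a candidate pose the face measures a signed
vertical distance `d_i` to the marker whose perpendicular distance to the
face's normal line is smallest (correspondence is recomputed at every
objective evaluation, since the lines move with the pose). The objective
is the L1 mismatch `S(Q) = Σ |d_i − ε_i|`, minimized by per-coordinate
trial moves of fixed size `h`: evaluate `S` at `q_i`, `q_i + h`,
`q_i − h`; move only when one trial is strictly smallest; ties keep the
coordinate. The default *sequential* mode applies each accepted move
before testing the next coordinate, which makes the per-sweep `S` trace
non-increasing by construction; a *simultaneous* mode (all trials against
the incoming pose) exists for comparison. Convergence is a full sweep
with zero moves; `max_sweeps` (default 10 000) is a safety cap.
With `h` fixed (no decay), `h = 0.5` mm/degree is the accuracy floor.

## Preparation parameters

| parameter | default | meaning |
|---|---|---|
| target edge length | 3 mm | isotropic remesh resolution of the bone; 2–4 mm is the useful window (finer is needlessly expensive, coarser distorts the shape) |
| thickness threshold | 0–20 mm | faces whose `ε` falls in this range form the analysis area; below ~5 mm the area is too small to use, above 20 mm posterior faces leak in |
| marker minimum distance | 10 mm | spacing of generated skin markers; 10 mm is the densest physically attachable grid |
| step `h` | 0.5 mm / degree | fixed trial-move size of the descent |
| perturbation | ±10 mm / degree | uniform per-DOF offset applied to the true pose to form the initial guess in simulation runs |

The defaults are the winning condition of the factorial calibration study
(27 conditions × 4 knee angles × 10 repetitions = 1080 runs; per-DOF mean
absolute errors pooled over angles and repetitions, ranked 1..27 per DOF
with average ranks on ties, total = sum of six ranks, minimum total wins;
deterministic tie-break: finer edge, wider thickness range, denser
markers).

## Remeshing

Classic incremental isotropic remeshing: split edges longer than 4/3 of
the target, collapse edges shorter than 4/5 (midpoint, link-condition and
long-edge guards, boundary vertices pinned), flip edges toward regular
valence (6 interior / 4 boundary, with fold guards), then relax vertices
tangentially and project them back onto the input surface by closest-point
query; five iterations by default. Edge lengths are met only
approximately — the contract is a mean edge within 50% of the target, no
degenerate faces, and bounded surface deviation. Ray–triangle
intersection (Möller–Trumbore) and point–triangle closest-point queries
are vectorized numpy implementations, chunked to bound memory.

## The phantom

The phantom substitutes for a CT + motion-capture session and defines the
conditions under which the estimator is tested.

* **Bone**: superellipsoid, semi-axes 22.5 × 20 × 10 mm (≈45 × 40 × 20 mm
  overall), latitudinal exponent 0.8, azimuthal exponent 0.65. The boxier
  azimuthal exponent gives the cornered patellar outline; without it,
  rotation about the anterior axis is nearly unobservable from surface
  distances. The LCS is the principal-axes frame (x mediolateral,
  y proximodistal, z anteroposterior, centroid origin), so the mesh is
  generated directly in its LCS.
* **Skin**: the bone surface offset along its analytic normals by a
  thickness profile τ: 3 mm over the anterior prominence rising through a
  smoothstep to 20 mm at 90° polar angle, growing to a 32-mm posterior
  cap. A `cos(azimuth)` exponent modulation (0.25) makes the medial side
  fleshier than the lateral — the second rotation-symmetry breaker. An
  optional tilt of the profile center exists but defaults to off: a
  tilted thickness pattern couples axial rotation with in-plane
  translation, which the per-coordinate optimizer handles poorly.
* **Markers**: the default `grid` style lays rings on the skin at ~10 mm
  of meridian and circumferential arc out to 95° (≈79–91 markers,
  emulating a hand-attached anterior-knee grid); `virtual` throws
  Poisson-disk markers at a minimum distance; `exact` places one marker
  per analysis face at exactly `ε` along the face normal — the *noiseless*
  construction, for which `S` at the true pose is exactly zero and
  estimator behaviour can be studied free of marker error. Skin-sampled
  markers (grid/virtual) additionally carry an irreducible mismatch of
  order (lateral offset to the nearest marker) × (thickness gradient),
  roughly 1 mm per face for the default scene — the synthetic analogue of
  what real marker grids measure.
* **Scenarios and noise**: per knee angle β ∈ {0, 30, 60, 90}° the true
  pose follows a linear glide+tilt fixture
  (0.03, −0.25, −0.10, 0.60, 0.05, 0.04) per degree — distinct known
  truths, not a claim about real patellar kinematics. `add_noise` applies
  isotropic Gaussian marker jitter and/or an outward skin-offset bias,
  seed-reproducibly.
* Four lower-leg landmark markers are emitted in both the CT frame and a
  fixed synthetic motion-capture frame so the least-squares (Kabsch)
  mocap→CT transfer is exercised end to end.

What the phantom does not emulate: skin deformation and sliding over the
bone, muscle-contraction thickness changes, segmentation error, camera
occlusion. Passing tests on it therefore demonstrate the estimator's
geometric correctness and its intrinsic optimizer behaviour, not
real-session accuracy.

## Numerical choices and degenerate inputs

Strict inequalities implement the three-way move rule, so exact ties keep
the coordinate (deterministic). Faces whose normal ray never reaches the
skin have undefined `ε` and are excluded from the analysis area; an empty
analysis area raises rather than returning a vacuous fit. Zero-area faces
are rejected with their index. Rigid fits require ≥3 non-collinear
points; the proper-rotation branch of the SVD solution is enforced.
Outward normal orientation is defined as pointing away from the mesh
centroid, adequate for the star-shaped surfaces registered here. Marker
CSV round-trips are lossless (`%.17g`, round-trip float parsing).

## Known limitations

* **Stalling of the fixed-step descent.** With exactly consistent
  markers, `S` is a polyhedral cone around the truth (every term kinks at
  zero simultaneously). Per-coordinate descent with fixed `h` on such
  non-separable L1 surfaces stalls wherever no single ±h move improves —
  typically within 2–4 steps (1–2 mm/deg) of the optimum — and
  occasionally locks into deeper rotation minima several degrees away
  (mesh/marker lattice aliasing). In repeated ±10 mm/deg perturbed starts
  about one third of runs end more than two steps from truth on at least
  one DOF, although median per-DOF errors stay well under the step size.
  Frozen-correspondence inner loops and simultaneous updates were tried
  and do not reduce the stall rate; the behaviour is intrinsic to the
  optimizer, whose local-minimum risk the original method left
  unevaluated.
* **Axial rotation is the weak DOF.** Surface-to-marker distances over a
  smooth, nearly symmetric bone constrain rotation about the anterior
  axis weakly; with realistic (skin-sampled) markers its error is
  routinely several times larger than the other five DOFs.
* The estimator is for static poses; dynamic tracking, kinematic-chain
  constraints, and gradient-based or global optimizers are out of scope.
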