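# Methods

This note records the modelling assumptions, parameter choices, numerical
decisions and known limitations of `macgrip`. It documents what the code
computes and why; every quantitative claim here is one the test suite or
`scripts/acceptance.py` computes at run time.

## Units and conventions

Model files and anatomical tables use mm, g, g·mm², cm² and N (the units of
the source anatomy); all dynamics is computed in SI and converted through
the single-sourced factors in `macgrip.units`. Bone frames sit at the bone
centroid with z along the shaft (distal), x dorsal, y radial→ulnar; the
carpus (root) frame is x dorsal, y ulnar, z distal. Every
flexion/extension axis is a frame y-axis and positive rotation is
extension; positive thumb-CMC deviation is adduction. Joint angles are
reported trial-relative (zero at the first frame) where that convention is
wanted (`JointTrajectory.relative_to_first_frame`).

## Skeleton and inertia

The hand is a tree of 20 bone segments rooted at the carpus. Hinges (1 DOF)
model the interphalangeal joints, universal joints (2 DOF, orthogonal axes,
intrinsic composition R₀·Rot(a₁,q₁)·Rot(a₂,q₂)) model the MCPs and the
thumb CMC, and CMC 2–5 are fused (`fixed` joints), leaving 16 rigid links
and 21 kinematic coordinates. Masses and principal moments are the
published cadaver measurements and are kept verbatim; centers of mass
coincide with the frame origins. Inertia of arbitrary closed meshes uses
exact polyhedral (divergence-theorem) integrals via trimesh rather than
voxelization, so results are independent of mesh resolution; the
rectangular-solid closed forms serve the metacarpals and carpus.

## Geometry template

The source anatomy does not publish joint-center or via-point coordinates,
so the default model generates them from a parametric template
(`GeometryParams`): straight digit columns along +z spaced along y, the
thumb column rotated −90° about z so its palmar face opposes the index;
segment lengths loosely follow macaque hand proportions (index ray 36 mm
metacarpal, 25/15/10 mm phalanges). Tendon via points sit at fixed dorsal or
palmar offsets that *are* the moment arms: long flexors 4 mm palmar,
extrinsic extensors 4 mm dorsal, interossei 3 mm palmar at the MCP,
extensor-slip and terminal-tendon branches 3 / 2.5 mm dorsal at PIP / DIP.
The template is explicitly non-anatomical: every geometry-dependent test is
a property (equivariance, two-route consistency, finite-difference
equality), not a comparison with anatomical coordinates.

Two template choices deserve emphasis:

- **Landmark placement.** "Head" markers sit 2.5 mm dorsal of the bone
  head, as a digitized skin point does. This also removes a genuine
  degeneracy: markers placed exactly at joint centers admit a mirrored
  (elbow-up/elbow-down) registration solution with identical residuals.
- **Thumb lever obliquity.** FDP1 is absent in this species (PCSA 0), so
  the thumb IP joint has extensors (EPL) but no flexor. The default thumb
  lever line is tilted 10° off the pinch axis toward the palmar direction
  of the thumb, and the EPL via offsets (8 mm at MCP, 2 mm at IP) satisfy
  a_MCP/a_IP > r_MCP/r_IP, which keeps the thumb demand pattern inside the
  actuated cone: EPL balances the IP extension demand and the thenar
  flexors absorb the MCP surplus. This reproduces the reported activity
  pattern (EPL and ADPt active, OP and ABPL silent) as a consequence of
  the geometry rather than by assumption.

## Primitive fits

Sphere: algebraic linear least squares refined by geometric Gauss–Newton on
radial residuals. Cylinder: PCA-direction initializations (all three), then
Levenberg–Marquardt over axis angles, planar offset and radius; the joint
center is the on-axis point nearest the patch centroid. Paraboloid: PCA
frame, linear quadric initialization, then LM over rotation, apex and the
two curvatures; the frame is canonicalized (opens along +z′, larger
curvature on x′). Degenerate inputs (coplanar sphere patches, collinear
cylinder patches, curve-like paraboloid patches detected by rank of the
quadric design matrix) raise `DegenerateFitError`. Convergence tolerances
are 1e-14 (xtol/ftol); apex localization along a shallow curvature
direction is weakly identified against frame tilt and needs patch spans of
several times 1/curvature for sub-0.1 mm accuracy — the tests derive their
expectation from a seeded ladder at noise σ = 0.02 mm.

## Kinematics and registration

Marker filtering is a zero-phase 4th-order Butterworth low-pass (applied
forward–backward) at 5 Hz; the protocol prescribes only the cutoff, the
realization is this package's documented dialect (likewise 30 Hz/2.5 Hz for
EMG, 10 Hz for lever forces). Registration minimizes the summed squared
marker-to-model-point distances per frame with Levenberg–Marquardt on the
analytic Jacobian, warm-started from the previous frame; only coordinates
proximal to at least one landmark are solved (digits 3–5 carry no markers
in the 12-landmark protocol and stay at their initial pose). Axes
immobilized for dynamics remain kinematic DOF during registration.
Derivatives default to second-order central differences; a degree-5
least-squares polynomial with analytic derivatives is available
(`differentiate_trajectory(..., mode="polynomial")`) — the protocol's
polynomial smoothing of coordinates — but the central-difference route is
the default because it commutes exactly with the synthetic ground-truth
definition. Scaling to the subject multiplies all geometry by
`target / index-finger length` (MCP→PIP→DIP→tip at reference pose) and
deliberately leaves masses and inertias at their measured values: scaling
is a registration aid, not a new specimen; at ~2 N fingertip forces the
inertial torques are ≤1% of the external ones, so the approximation is
immaterial.

## Inverse dynamics

Recursive Newton–Euler over the segment tree in world coordinates, gravity
folded into the base acceleration (default −9.81 m/s² along the palmar
axis; configurable, and zero-gravity supported). External lever forces are
magnitude series along fixed global directions (the gauges are uniaxial)
applied at configurable fingertip contact points stored with the model.
Per-axis torque is the projection of the inter-segment torque onto the
instantaneous world axis. The implementation is verified against the
closed-form planar two-link Lagrangian equations (1e-9 relative) and an
energy-rate identity, plus linearity/zero-case properties. Torques on
immobilized axes (MCP radio-ulnar; both thumb-CMC axes) are reported as
structural reactions and excluded from muscle balance, leaving 14
muscle-balanced axes (5 MCP + 9 IP flexion/extension).

## Static optimization

Per frame, minimize Σ(fᵢ/PCSAᵢ)³ subject to R_eff f = τ and
0 ≤ fᵢ ≤ PCSAᵢσ_max, independently across frames (no activation dynamics).
In stress variables sᵢ = fᵢ/PCSAᵢ the bounds are uniform [0, σ_max] and the
objective is strictly convex on the positive orthant, so the optimum is
unique. The solver works on the dual: the KKT conditions give
sᵢ(λ) = √(max(aᵢᵀλ, 0)/3) clipped to the bounds, and a damped semismooth
Newton iteration drives A s(λ) = τ to 1e-13 N·m; multipliers are
canonicalized by projecting out the numerical null space of the dual
Jacobian so the reported solution does not depend on warm-start history.
If the iteration stalls, an LP feasibility probe (HiGHS) decides between a
genuinely infeasible demand — the unattainable torque remainder is
reported per axis, the attainable projection is solved, and the frame is
flagged `infeasible` — and a hard feasible frame, which falls back to
SLSQP refined by the same dual polish. Zero-PCSA muscles (FDP1, CD2 —
absent in this species) are excluded from the objective and pinned to zero
force. Tolerances: equality 1e-8 N·m absolute, bound slack 1e-8 N,
stationarity reported via least-squares multipliers. Extensor-net branches
are inextensible transmitters: they add no variables, their tensions are
T f and their arms fold into R_eff; branch coefficients beyond the
published index-finger values (proprius extensors, digits 3–5) default to
the same 0.167/0.333 pattern and are configurable in the model file, and
the US/CS/RS/IT branches ship with geometry but zero coefficients.

## Synthetic trials

The generator emulates the study conditions: trial of 2.4 s at 100 Hz with
grip onset α = 0.5 s, peak β = 1.2 s, release γ = 1.9 s; lever-force peaks
1.5 N (index) and 2.0 N (thumb); marker noise SD 1.4 mm (the reported
calibration error); joint-angle amplitudes with the reported qualitative
signs (index MCP flexes 0.35 rad, PIP extends 0.15 rad; thumb CMC adducts
0.25 rad, MCP flexes 0.20 rad, IP extends 0.12 rad; digits 3–5 static).
Angles and forces share one C² minimum-jerk bell (zero value, velocity and
acceleration outside [α, γ], unit peak at β): the spring levers displace in
proportion to force, so posture tracks load. Posture lags the force by
50 ms — the levers are loaded before they move — which keeps joint-angle
accelerations inside the window where the lever torque dominates; without
the lag, acceleration transients at the window edges create ~10⁻⁸ N·m
flexion demands at the thumb IP, which has no flexor. Surrogate EMG is an
envelope-level activation proxy (channel envelope ∝ summed truth force of
its muscles, plus band-limited seeded noise), with optional 5 kHz carrier
synthesis so the full envelope chain is exercised; it models none of the
physiology of motor-unit recruitment. Determinism: one `SeedSequence` per
trial; identical config + seed gives bit-identical artifacts.

The recovery experiment closes the loop: synthesize markers (+noise) →
filter → register → differentiate → inverse dynamics → optimize → compare
with the generator's own ground truth (per-muscle zero-lag r and RMSE).
The 5 Hz filter belongs to the measurement-noise pathway and is applied
only when noise is present, so the noise-free loop is an exact inversion
of the generator (recovered forces match truth to ~1e-12 N, limited only by
solver determinism). What passing recovery shows about real data is
limited: the synthetic trials share the model's geometry exactly (no
model-form error), the noise is isotropic and white (digitization error is
neither), lever directions are exactly known, and digits 3–5 are truly
static — so recovery quality on real recordings will be worse in ways these
tests cannot measure.

## Known limitations

- Template geometry is schematic; no anatomical claim attaches to any
  coordinate, only to the published masses, inertias, PCSAs and the
  transmission coefficients.
- No force–length/velocity muscle properties, pennation, passive joint
  elasticity, or lumbrical muscles; no contact mechanics — lever forces are
  prescribed, horizontal and uniaxial.
- Static (frame-wise) optimization: no activation dynamics or muscle
  synergies; the cubed-stress criterion is one hypothesis about
  recruitment, not a measurement.
- The thumb IP flexion side is unactuated (FDP1 absent): torque demands on
  that side are structurally infeasible and are reported as such rather
  than absorbed.
- C3D marker input is not supported (TRC and long CSV are); the published
  matching-bias and EMG-correlation figures require the original
  recordings, for which the synthetic recovery experiment is an explicit
  stand-in.
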