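# macgrip

Musculoskeletal modelling and inverse-dynamics muscle-force estimation for
precision grip in the Japanese macaque (*Macaca fuscata*) hand.

## The problem

During a precision grip — thumb and index finger pinching spring-loaded
levers — dozens of hand muscles act across a kinematic chain with far more
muscles than mechanical degrees of freedom. Direct recording (EMG) is only
feasible for a handful of muscles, so the forces of *all* muscles must be
estimated by modelling: reconstruct the hand motion, compute the net joint
torques required by that motion and the measured fingertip forces, and
resolve the muscle redundancy with a physiological optimality criterion.
`macgrip` implements that pipeline end to end for researchers in motor
control and biomechanics, together with a synthetic-trial generator so every
stage can be exercised and validated without animal data.

## The model and method

**Skeleton.** A chain of 20 bone segments (carpus, 5 metacarpals, 14
phalanges). Interphalangeal joints are hinges (1 DOF), metacarpophalangeal
(MCP) joints and the first carpometacarpal (CMC) joint are universal joints
(2 DOF), and CMC 2–5 are fused with the carpus (negligible mobility in
grip), leaving an open chain of 16 rigid links. Segment masses and principal
moments of inertia are the published cadaver values (density 1.0 g/cm³,
phalanges by exact polyhedral integrals of the bone surface meshes,
metacarpals/carpus as rectangular solids). Joint centers and axes come from
geometric primitives fitted to articular surfaces (sphere → MCP, cylinder →
IP, elliptic paraboloid → thumb CMC), all available in
`macgrip.geometry`.

**Muscles.** 23 named muscles along 41 via-point paths (split muscles such
as FDP contribute one path per digit); path length is the summed length of
straight segments between points fixed in bone frames, and moment arms use
the tendon-excursion definition R[i,j] = −∂Lⱼ/∂qᵢ, computed geometrically.
Maximum isometric force is `PCSA × σ_max` with σ_max = 23 N/cm². The dorsal
extensor mechanism of each finger is a tendon network: branch tensions are
linear in the contributing muscle tensions (for the index finger,
f_RB = 0.167 f_EDC2, f_UB = 0.167 f_EDC2 + 0.333 f_1PIO, f_TE = f_RB + f_UB,
f_ES = 0.167 f_EDC2 + 0.333 (f_1PIO + f_1DIOr + f_1DIOu)), and branch
moment arms fold into the contributing muscles as R_eff = R_direct + R_b T.

**Estimation.** Markers (the 12 landmarks digitized in the grip protocol)
are zero-phase low-pass filtered at 5 Hz; the model is scaled to the subject
by index-finger length and registered frame-by-frame by least squares
(damped Gauss–Newton on the analytic chain Jacobian). Net joint torques
follow from recursive Newton–Euler inverse dynamics with the lever forces
applied at the fingertips. MCP radio-ulnar deviation and both thumb-CMC axes
are treated as instantaneously immobile (balanced by reaction torques); on
the remaining 14 muscle-balanced axes the redundancy is resolved per frame
by

    minimize   Σᵢ (fᵢ / PCSAᵢ)³
    subject to R_eff f = τ,   0 ≤ fᵢ ≤ PCSAᵢ σ_max

a strictly convex program solved through its dual KKT characterization.
Predicted forces are compared with EMG linear envelopes (30 Hz high-pass →
rectify → 100 Hz → 2.5 Hz low-pass) by the zero-lag cross-correlation *r*,
skipping muscles whose EMG is effectively zero or whose predicted force
never reaches 0.3 N.

## Worked example

```python
from macgrip import build_default_model, GripInverseDynamics, GripTrial
from macgrip.synth import SynthConfig, generate_trial

model = build_default_model()
data = generate_trial(SynthConfig(seed=7, marker_noise_mm=1.4), model=model)
trial = GripTrial(markers=data.markers, lever_forces=data.lever_forces,
                  name="synthetic grip, seed 7", emg=data.emg)

results = GripInverseDynamics(model, trial).fit()
print(results.summary())
```

```
Precision-grip inverse dynamics
===============================================
Trial: synthetic grip, seed 7   frames: 240 @ 100 Hz
Model: 20 segments / 16 links, 41 muscle paths
Matching bias (mm): 0.61 +/- 0.18
Peak lever force (N): thumb 2.00, index 1.50
Muscle-balanced axes: 14 (reaction axes: 7)
Torque-balance residual (N*m): max 8.05e-07
Solver: 166/240 frames optimal

Peak muscle forces >= 0.3 N:
  FDS2       8.16 N
  FDP2       4.54 N
  1PIO       3.58 N
  1DIOu      2.27 N
  1DIOr      2.26 N
  EPL        1.49 N
  ABPB       0.62 N
  ADPt       0.34 N
```

The matching bias (0.61 ± 0.18 mm) is the mean distance between each
digitized marker and its model counterpart after registration — sub-
millimetre, i.e. the pose reconstruction is tight relative to the 1.4 mm
marker noise. The force ranking is the physiological grip pattern: index
flexors (FDS2, FDP2) and the first interossei carry the pinch, EPL holds the
thumb IP extended, and the frames not flagged `optimal` carry only a
residual torque below 10⁻⁶ N·m on axes that have no anatomical actuator for
a noise-induced demand. Comparing with the trial's (surrogate) EMG,

```python
print(results.validate().to_frame())
```

gives r ≈ 0.98 for 1DIO/FDS2, 0.94 for FDP2, skip rules firing for the
silent ABPL/EDC2/ED2P channels, and poor correlation for ADP/ABPB — the
same agreement pattern reported for the in-vivo recordings this pipeline is
modelled on.

A command-line interface mirrors the library:
`macgrip model build`, `macgrip fit sphere|cylinder|paraboloid`,
`macgrip inertia`, `macgrip ik`, `macgrip id`, `macgrip solve`,
`macgrip validate`, `macgrip synth trial`.

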