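# Methods

## Scope and architecture

`cssim` simulates the load-feedback signal chain of a dynamically scaled
robotic *C. morosus* middle leg entirely in software.  Five parts
cooperate:

1. `cs_model` — the adaptive campaniform-sensillum (CS) discharge model
   for groups 3, 4, 6A, 6B;
2. `kinematics` — the 3-DOF product-of-exponentials chain, inverse
   kinematics, and stepping footpaths;
3. `scaling` — the dynamic-scaling arithmetic that fixes the 4 s step;
4. `synthetic_leg` — the quasi-static strain generator plus the
   amplifier → ADC → median-filter acquisition chain that stands in for
   the physical robot;
5. `experiments` — declarative runners for the five loading protocols and
   the stance-event detector.

Physical hardware (servo firmware, treadmill electronics, finite-element
strain fields) and closed-loop control are out of scope.

## CS discharge model

    y = max(0, a·(u − x) + c·u + d)        (output, spikes/s)
    τ·ẋ = sign(u − x)·|u − x|^b            (adaptive threshold)

* Parameters per group (a, b, c, d, τ) are the published tibial-CS fits;
  groups 3/4/6B share one set, 6A differs only in a smaller |d|, giving
  it a lower tonic threshold −d/c (≈2.51 vs ≈3.90 input units).
* **Integration.**  Under a zero-order hold of `u` across one 60 Hz
  sample, the threshold ODE is separable and has the exact solution
  |e|(t) = (|e₀|^(1−b) + (b−1)t/τ)^(−1/(b−1)) for b > 1 (exponential for
  b = 1, finite-time arrival clamped at u for b < 1).  The integrator
  applies this flow per sample, so the update is exact for the held
  input: x can never overshoot u, no stability constraint exists, and
  sub-stepping provably changes nothing (the flow is a semigroup; the
  `substeps` argument exists to demonstrate that).  Unit tests cross-check
  the trajectory against `scipy.integrate.solve_ivp` at rtol 1e-11.
* **Hold convention.**  `u[i−1]` is held over the interval ending at
  `t[i]`; the output at a sample is evaluated against that sample's input
  with the just-advanced threshold, so a load step produces its full
  phasic burst `a·Δu` before adaptation begins.
* **Input sign convention.**  Each group receives its rosette channel
  *signed* (positive = compression of the gauged dorsal face for the
  axial channel).  During stance the transverse channels sit below zero
  and their thresholds adapt down to them; unloading then reads as a load
  increase and produces the end-of-stance rebound bursts of groups 4 and
  6A, and the mid-stance 6A burst at foot slip.  Rectifying the inputs
  instead would make those bursts impossible — the rebound is a direct
  consequence of threshold adaptation below zero.
* **Input scale.**  The model's input is dimensionless with a nominal
  0–10 range (the tonic thresholds only make sense on that scale).  Each
  rosette has one strain→u factor, frozen at 560 (trochanterofemur) and
  6900 (tibia) so that the peak axial strain of the baseline stepping
  condition maps to u = 5 for both rosettes.  This mirrors per-channel
  amplifier trim on real hardware and is configurable.
* **Initial threshold** defaults to x₀ = u(0) (fully adapted), avoiding a
  spurious startup transient; overridable.
* **Adaptation speed.**  Because b ≈ 2.27 > 1, adaptation is a power law,
  not an exponential: the residual gap at time t after a step is
  ≈ ((b−1)t/τ)^(−1/(b−1)) nearly independently of its initial size, i.e.
  ≈ 0.078 input units (≈26 spikes/s of residual discharge) at t = 20τ,
  and full convergence to the tonic value takes thousands of τ.  Slow,
  incomplete-looking adaptation on finite windows is a property of the
  published parameters, not an integration artifact.

## Kinematics and footpath

* Frame: x anterior, y lateral (distal along the leg at zero angles),
  z dorsal.  The ThC axis is slanted 37° in the y–z plane; CTr and FTi
  rotate about x.  The published twist table is embedded as the default
  `LegModel` (units mm); the foot frame at zero angles is the identity
  rotation at q_end.
* FK uses the screw closed form e^{ξ̂θ} = [R, (I−R)q]; IK solves
  p(θ) − p* = 0 with MINPACK's quasi-Newton hybrid method, analytic
  Jacobian (columns ωᵢ′ × (p − qᵢ′)), warm starts, residual tolerance
  1e-6 mm, and a fast reachability bound (sum of segment lengths about
  the ThC point).  The 3-DOF chain has locally unique solutions; near the
  straight-leg singularity (θ₃ ≈ 0) position closes to 1e-6 mm while
  angle recovery is ill-conditioned, so tests assert angles only on
  flexed postures.
* **Branch choice.**  The chain admits a knee-low and a knee-raised
  solution branch.  All defaults use the knee-raised branch (CTr levated,
  tibia descending steeply to the ground), the standing insect's posture;
  the warm-start guess (0, 0.3, −1.2) selects it deterministically.
* **Footpath.**  One period at 60 samples/s: stance (duty 0.5 of a 4 s
  period) moves the foot posteriorly at the belt speed (default 40 mm/s)
  on the plane z = −200 mm at y = 260 mm; swing is a single quintic in x
  whose end velocities both equal the belt velocity — which forces the
  anterior overshoot and rearward re-acceleration that give a
  velocity-matched, bounce-free touchdown — plus a sin² lift of 40 mm.
  The path is C¹-periodic by construction.  The stance line was placed
  once so that (i) the whole path is comfortably inside the IK workspace
  and (ii) the tibia is near plumb at touchdown, so tibial bending is
  small at contact and grows as the leg tilts through stance while the
  trochanterofemur carries the body weight on a long, nearly constant
  moment arm — the geometry behind the rosettes' very different load
  sensitivities.

## Dynamic scaling

T = 2π√(J/k) for a rotational spring–inertia joint.  Insect:
J = mL²/3 = 5.28e-10 kg·m² (11 mg, 1.2 cm slender rod),
k = 1e-6 N·m/rad → T ≈ 0.14 s.  Robot: J = 1e-2 kg·m² (geared rotor),
k = 1 N·m/rad → T ≈ 0.63 s.  A step of six natural periods (the insect's
~1 s step vs 0.14 s) gives 3.77 s, operated as 4 s.  The mass bookkeeping
helper reports the body-mass fraction (0.875 for 800 g total with 100 g
moving).

## Strain synthesis (the robot stand-in)

Quasi-static rigid-link beam model: at each sample the bending moment at
each gauge site is M = r × F (r from gauge to foot, F the total foot
force), resolved into segment-local dorso-ventral and anterior-posterior
axes; surface strain follows the hollow-square closed form
ε = M·(w/2)/(E·I), I = (w⁴ − wᵢ⁴)/12 (outer 10 mm, wall 1 mm, E 1.4 GPa
— E only sets the absolute strain scale, which the CS input scale
absorbs).  Gauges sit 10% along each segment from the proximal joint
(configurable).  Inertial strain is neglected: the motion is dynamically
scaled and slow, so a non-contacting leg is strain-free by construction,
matching the hardware observation that free movement produces essentially
zero strain.

* **Transverse channels** couple as −ν × (dorso-ventral axial bending
  strain), ν = 0.35, a Poisson-style antagonistic pairing that puts the
  axial and transverse directional maxima exactly 180° apart.  An
  optional `ap_weight` can mix anterior-posterior bending into the
  transverse channel; its default is 0 because a centreline gauge element
  sees no axial strain from AP bending and a nonzero weight would rotate
  the transverse maximum away from ventral.
* **Stance loading.**  The vertical reaction equals the supported weight
  (0.8 kg carriage + added mass) plus any perturbation; belt friction is
  kinetic, μN with μ = 0.4, opposing the leg's push.  Load transfer at
  touchdown and liftoff ramps at a fixed 100 N/s: the build-up *rate* is
  set by contact mechanics and is independent of the carried mass (only
  the ramp duration grows).  This is what makes the touchdown discharge
  burst load-robust while amplitudes scale with load.
* **Slip** is phenomenological (no slip physics is modeled): over the
  slip window the tibial gauge moment is scaled toward 0 (direction +1)
  or transiently increased (direction −1), with 50 ms smoothed edges,
  while the trochanterofemoral moment rises by up to 50%.
* **Acquisition chain.**  strain → bridge volts (0.2 V/strain) → ×250
  amplifier centred at vref/2 → slow sinusoidal offset drift (5 counts
  amplitude, 60 s period, seeded phase; trimpot/temperature effects) →
  Gaussian noise (SD 2 counts) → clip to [0, 3.3 V] with a saturation
  flag → 12-bit quantization → 13-sample moving median.  The bridge
  sensitivity leaves ~40% headroom at the heaviest load so nothing
  saturates in the bundled protocols.  The high-gain tibial channel
  resolves ~40 ADC counts at baseline, so its discharge carries a few
  spikes/s of quantization-noise blips — visible in "silent" conditions
  and quantified in the tests as the noise floor.

## Protocols and detector

Protocol magnitudes that the hardware experiments did not pin down
numerically are defaults in `ExperimentSpec`: ramp-hold-release 0.5/2/0.5 s
at 6 N dorsal; asterisk 12 × 30° with 1 s holds, 0.25 s transitions and a
return to centre (summary = mean strain over the central 60% of each
hold); stepping 20 steps at 0/500/1000 g; transient load = half-sine 5 N,
0.5 s wide, starting 1.25 s into stance; slip 0.4 s starting 0.9 s into
stance.  The stance-event detector marks onset at an upward threshold
crossing of group 3 and offset at one of group 4 (default threshold 10%
of that group's peak), then matches each ground-truth phase transition to
the nearest detection and reports the timing error.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the hardware data — phase-
locked loading, directional tuning, load-scaled amplitudes, slip
transients, ADC artifacts — under quasi-static, perfectly repeatable
conditions.  It does not emulate touchdown bounce, belt or carriage
compliance, servo torque ripple, temperature-dependent gauge drift beyond
a smooth sinusoid, or inertial strain.  Passing tests therefore show that
the model pipeline produces the documented signatures given realistic
strain inputs, not that a particular physical rig is calibrated.

## Numerical choices and degenerate inputs

Threshold update is exact per sample (no tolerance); gaps below 1e-15 are
snapped to convergence.  IK: residual 1e-6 mm, ≤200 iterations, fixed
fallback guess list, deterministic for a given guess; unreachable targets
raise with the residual attached.  Median filtering uses nearest-edge
padding.  Zero-length ramps, zero force, zero carriage mass and empty
discharge all degrade to empty/zero results rather than errors.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; runs are bit-reproducible for identical
spec + seed.

## Problem sizes

Bundled protocol runs use 20 steps × 4 s × 60 Hz per condition (4800
samples), 12 × ~2 s asterisk holds, and 100-point IK round-trip checks;
these sizes give stable statistics for every summary the tests assert
while keeping a full suite run around ten seconds.

## Known limitations

* Adaptation is the large-CS phenotype; the small, slowly adapting CS
  population (incomplete adaptation, prolonged discharge) is not modeled.
* The output is a continuous rate signal, not spike times.
* Strain is linear quasi-static beam bending at two points; no
  finite-element fields, no compliant tarsus.
* The slip event is imposed, not emergent from a friction model.
* Model parameters are the published tibial fits applied to all four
  groups (as on the hardware); no refitting to animal recordings is
  attempted.
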