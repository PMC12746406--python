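# Methods

## Scope

`blochflow` simulates the Bloch equations for ensembles of classical
isochromats under user-defined pulse sequences, with first-class support for
motion: parametric rigid and cardiac-like actions, arbitrary per-spin
trajectories, and flow with spin reinjection.  It is a desk-scale research
code: everything runs on one CPU in seconds to minutes, with problem sizes
(spin counts, matrix sizes) chosen accordingly.

## Motion model

### Time curves

A `TimeCurve` maps absolute time to normalized trajectory progress
`u ∈ [0, 1]` by piecewise-linear interpolation of user nodes.  Extensions:

* **Flat extrapolation** outside the node span (non-periodic curves): before
  the pattern the first node value, after it the value at the end of the last
  repetition.
* **Pseudo-periodic warping**: `periods = [p1, …, pK]` lays K copies of the
  base pattern back to back, copy *i* stretched to `p_i · D` seconds (D the
  base duration).  This models irregular physiological rhythms (arrhythmia,
  irregular breathing) with a single node pattern.
* **Periodic extension** repeats the whole (possibly warped) pattern
  indefinitely.

Numerical conventions: evaluation exactly at a node takes the node value;
an exact internal repetition boundary takes the value of the *ending*
repetition (left-continuous), while under periodic wrapping the exact
pattern end maps to the pattern start.  A relative tolerance of `1e-12 · D`
snaps evaluations a rounding error past a period boundary onto it.  Node
values outside `[0, 1]` are accepted (overshoot), though the built-in
generators only emit values in the unit interval.

### Actions and composition

Five actions exist.  `Translate` and `Path`-type displacements are
position-independent: they are computed from the initial coordinates and
*added* to the result, which makes translation-only motion lists
order-independent.  `Rotate` and `HeartBeat` depend on current positions and
are applied *sequentially*, ordered by the start time of their time curves
(ties broken by list position), each acting on the positions produced so
far.

Open design points resolved here:

* **Euler convention** for `Rotate`: intrinsic yaw (z) → pitch (y) → roll
  (x), angles in degrees, partial progress `u` scales all three angles.  The
  convention is serialized with the phantom.
* **Rotation center** defaults to the unweighted mean of the span's
  positions, evaluated in the sequential chain state at the motion's start
  time.
* **HeartBeat reference radius** `max(r)` is fixed from the span's
  configuration at the motion's start rather than recomputed on deformed
  positions; the printed strain equations read as referencing a fixed
  configuration, and a per-step `max(r)` would make the strain definition
  self-referential.  `θ` at the axis uses `atan2(0, 0) = 0`.
* **Path progress clamping**: progress outside `[0, 1]` clamps to the
  trajectory endpoints, mirroring time-curve flat extrapolation.

### Flow and reinjection

`FlowPath` adds a binary `spin_reset` matrix aligned with the displacement
matrices: a 1 marks the progress sample at which a spin leaves the volume
and re-enters elsewhere.  When the simulation traverses a marked sample
(interval `(u_prev, u_now]`, with wrap-around handling for periodic
forward-traversed curves), the spin's magnetization is reset to the
unexcited state (`Mxy = 0`, `Mz = ρ`).  The spin count never changes.  Reset
instants are quantized to the trajectory's progress samples; phantoms should
place the reinjection region outside the excited slab so a reinjected spin
carries no stale transverse magnetization into the imaging volume (the
built-in generators do this).

## Bloch solver

### Time discretization

The grid of each sequence block contains the block ends, every gradient
vertex and every ADC sample time, refined so that spacing never exceeds
`dt_rf` (default 1 µs) while RF is active and `dt_grad` (default 10 µs)
elsewhere.  Gradients are piecewise-linear within a block; field steps
(rect lobes) sit on block boundaries, where the grid is exact.

### Update rule

Per sub-interval: an exact rotation of `M` about the effective field
evaluated at the sub-interval midpoint (RF envelope, gradients and spin
positions all at the midpoint; positions as the mean of the endpoint
positions), followed by exact exponential T1/T2 relaxation.  During RF-free
stretches the z-rotation commutes with relaxation, so whole blocks are
evaluated in closed form: the precession phase
`φ = −γ ∫ G(t)·r(t) dt − Δω·dt` is accumulated by trapezoidal quadrature
over the grid nodes and applied together with T2 decay; this is exact for
rect gradients and linear spin motion.  `T2` (not `T2*`) governs the kernel;
`T2s` is carried in the phantom for forward compatibility but unused.

Mid-interval field sampling makes the scheme second-order accurate in the
smooth-field regions, and the rotate-then-relax splitting contributes an
error proportional to the step and to the RF amplitude times the relaxation
rate — negligible at the default steps (see the convergence study).  The
signal is the unweighted sum of `Mxy` over spins (single uniform receive
coil); the gyromagnetic ratio is γ/2π = 42.5774688 MHz/T.

Ideal elements for desk-scale imaging experiments: a `Slab` on a block
restricts the RF rotation to spins inside the slab (ideal slice profile;
out-of-slab spins still precess and relax), and `spoil=True` zeroes `Mxy`
at a block end (ideal spoiling).  True selective excitation — an apodized
sinc with slice gradient and rewinder — is used where the slice profile
itself is the object of study.

## Reference solver and convergence study

`rk_oracle` integrates the full Bloch ODE (rotation and relaxation
simultaneously, no splitting) with SciPy's adaptive Dormand–Prince RK45 at
tolerance `1e-10` (two orders below the smallest error the study reports),
splitting the integration at every field discontinuity so the error control
assumptions hold.  Spin positions are evaluated continuously from the motion
model at every right-hand-side call.

The convergence experiment (`slice_profile_experiment`) uses 50 evenly
spaced spins on a ±2 cm z-segment moving at constant axial velocities of
0–200 cm/s through a 90° Hann-apodized sinc (3 ms, time-bandwidth 4)
with a 10 mm slab gradient and a half-area rewinder; magnetization is
recorded at the end of the rewinder.  Agreement is quantified per component
as `NRMSE = 100 · RMS(sim − ref) / (max(ref) − min(ref))` — normalization by
the reference's peak-to-peak range is scale-free; normalizing by `max |ref|`
would rescale the numbers without changing the trends.  NRMSE of a constant
reference is undefined and raises.  The study's acceptance surface is the
convergence *trend and error levels*, not exact curve shapes, since the
exact published sequence parameters of the original experiment are not
fixed here.

## Imaging experiments

* **Cartesian encoding**: phase-encode line *l* at `ky = (l − n/2)·Δk`,
  readout sample *m* at `kx = (m − n/2)·Δk`, `Δk = 2π/FOV`; reconstruction
  is a centered inverse 2-D FFT.  Default desk-scale matrix 64×64.
* **Phase contrast**: the toggled acquisitions differ in gradient first
  moment by `M1 = π/(γ·VENC)` (each carries ∓M1/2 as a rect bipolar), so
  `Δφ = angle(I₊·conj(I₋)) = π·v/VENC` and `v = VENC·Δφ/π`; flow faster
  than VENC wraps.  Phase images are masked where the magnitude falls below
  10% of its 99th percentile (the mask level is a display/robustness choice,
  not physics).
* **bSSFP**: fully balanced gradients per TR, RF phase alternating 0/180°,
  optional α/2 catalyzation.  The static steady state matches the
  closed-form bSSFP level; the residual percent-level deviation scales with
  the RF-pulse duration relative to TR (finite-pulse effect).
* **SPAMM**: 1-1 preparation (90° – gradient of area `2π/(γ·spacing)` – 90°
  – spoiler) leaving `Mz ∝ cos(2πx/spacing)`.

## Synthetic phantoms

Generators emulate the canonical flow/motion test objects: a plug-flow
cylinder whose periodic time curve traverses the tube length in exactly one
period (TOF experiments; default 4 cm/s), a 1-D constant-velocity spin
segment (slice-profile validation; velocities 0–200 cm/s, 50 spins), two
parallel tubes with opposite flow (plug or Poiseuille `v(r) = v_max(1 −
r²/R²)`) with one tube embedded in static tissue (phase contrast), and a
contracting annulus with an asymmetric systole/diastole cycle (tagging).
All random seeding is explicit.  Tissue defaults are blood-like (T1 = 1.2 s,
T2 = 0.1 s) for flow phantoms.  Spin counts (≈3000 for the TOF cylinder,
≈11 000 for the two-tube phantom, concentrated in a 3 cm tube length around
the 5 mm slab) were chosen once to give a few spins per excited voxel at the
default matrix, the usual density consideration for discrete-spin flow
simulation.

What the generators do **not** emulate: receive noise, coil sensitivities,
turbulence, spin accumulation/depletion under compressible deformation
(proton density is not modulated by local volume change), and off-resonance
field maps.  Passing tests therefore demonstrate the correctness of the
motion resolution, the Bloch integration and the encoding/reconstruction
chain — not robustness to noise or realistic anatomy.

## Known limitations

One time curve is shared by all spins of a motion entry (per-spin timing
requires one entry per group); `rk_oracle` does not support reinjection
(it is a reference for continuous-trajectory phantoms); gradients within a
block must be continuous (steps go on block boundaries); no concomitant
fields, eddy currents, multiple receive coils, or GPU execution.
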