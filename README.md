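# blochflow

Motion-capable Bloch-equation MRI simulation in Python: dynamic digital
phantoms with flow and physiological motion, a sequence-aware discrete-time
Bloch solver, and an HDF5 `.phantom` file format for storing and sharing
dynamic phantoms.

## Who this is for

MRI physicists and sequence developers who want to study motion-related
effects — flow signal (time of flight), phase-contrast velocimetry, cardiac
contraction and tagging, slice-profile distortion under flow — on fully
controlled synthetic objects, without scanner time, and with a high-accuracy
numerical reference to quantify solver error.

## The model

A **phantom** is a set of isochromats ("spins") with initial positions
$(x, y, z)$, tissue parameters $(T_1, T_2, T_2^*, \rho)$, off-resonance
$\Delta\omega$, and a **motion** specification: a list of entries, each the
combination of

* an **action** — `Translate`, `Rotate`, `HeartBeat` (a cylindrical-coordinate
  contraction parameterized by circumferential, radial and longitudinal
  strain), or arbitrary per-spin trajectories `Path` / `FlowPath` given as
  displacement matrices sampled at equispaced points of trajectory progress;
* a **time curve** $u(t)$ — a piecewise-linear map from absolute time to
  normalized trajectory progress $u\in[0,1]$, with flat extrapolation,
  optional periodic extension, and *pseudo-periodic* time warping through a
  vector of per-repetition duration scale factors;
* a **spin span** — the subset of spins the motion affects.

Rotations and deformations act sequentially on updated positions (ordered by
time-curve start); translations and path displacements add to the initial
coordinates.  `FlowPath` supports flow: spins leaving the volume are
reinjected (the spin count stays constant) and a binary `spin_reset` matrix
marks the reinjection instants at which the magnetization is reset to the
unexcited state — this is what produces fresh-spin inflow contrast.

The solver advances the Bloch equations
$\dot{\mathbf M} = \gamma\,\mathbf M\times\mathbf B - R(\mathbf M - \mathbf M_0)$
on a sequence-aware grid (every block boundary, gradient vertex and ADC
sample is a node) using an exact rotation about the mid-interval effective
field $(\mathrm{Re}\,B_1,\ \mathrm{Im}\,B_1,\ \mathbf G\cdot\mathbf r +
\Delta\omega/\gamma)$ followed by exponential $T_1/T_2$ relaxation.  A
fifth-order adaptive Runge–Kutta integration of the same ODE serves as the
independent reference; agreement is measured as NRMSE (percent of the
reference profile's range).

## Worked example

```python
import numpy as np
import blochflow as bf

# a cylinder of spins flowing upward at 4 cm/s, reinjected at the top
phantom = bf.make_cylinder_flow_phantom(
    radius=0.004, length=0.02, vz=0.04, spin_density=3e9, seed=1)

slab = bf.Slab(center=0.0, thickness=0.006)          # 6 mm excitation slab
result = bf.tof_inflow_experiment(phantom, vz=0.04, slab=slab,
                                  n_tr=60, tr=5e-3)

fresh = result.in_slab & (result.residency_tr < 1)
resident = result.in_slab & (result.residency_tr > 20)
print(round(result.signal[fresh].mean(), 3),
      round(result.signal[resident].mean(), 3))
```

prints

```
0.765 0.323
```

— spins that entered the slab less than one TR ago are still near thermal
equilibrium and emit 0.77 (in units of equilibrium magnetization), while
spins resident for more than 20 TRs have been driven to the saturated
steady state at 0.32: a 2.4× time-of-flight inflow enhancement.

The `examples/` directory holds one short script per capability: time-curve
algebra, the solver-vs-Runge–Kutta convergence study, phase-contrast
velocimetry on a two-tube phantom, time-of-flight contrast, SPAMM tagging,
and `.phantom` file round trips.  Each prints what it computes and what the
numbers mean.

A thin CLI wraps the common operations:

```bash
blochflow phantom create --preset cylinder --out cyl.phantom
blochflow phantom inspect cyl.phantom
blochflow convergence --dt 1e-5,1e-6 --out conv.csv
```

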