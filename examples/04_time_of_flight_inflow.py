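"""Time-of-flight inflow enhancement in a flowing cylinder.

A cylinder of spins flows upward at 4 cm/s through a 6 mm excitation slab
driven by a balanced steady-state pulse train.  Fresh spins that just entered
the slab are still near thermal equilibrium and emit a strong signal, while
spins resident for many repetition times are saturated -- the classic bright-
blood inflow contrast.
"""

import numpy as np

import blochflow as bf

vz = 0.04  # 4 cm/s plug flow
phantom = bf.make_cylinder_flow_phantom(
    radius=0.004, length=0.02, vz=vz, spin_density=3e9, seed=1
)
slab = bf.Slab(center=0.0, thickness=0.006)
result = bf.tof_inflow_experiment(phantom, vz=vz, slab=slab, n_tr=60, tr=5e-3)

fresh = result.in_slab & (result.residency_tr < 1)
resident = result.in_slab & (result.residency_tr > 20)
print(f"phantom: {phantom.n_spins} spins, reinjected on wrap (spin count constant)")
print(f"fresh spins   (< 1 TR in slab):  n = {fresh.sum():4d}, "
      f"mean |Mxy| = {result.signal[fresh].mean():.3f}")
print(f"resident spins (> 20 TR in slab): n = {resident.sum():4d}, "
      f"mean |Mxy| = {result.signal[resident].mean():.3f}")
ratio = result.signal[fresh].mean() / result.signal[resident].mean()
print(f"-> inflow enhancement: fresh spins are {ratio:.1f}x brighter.")
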