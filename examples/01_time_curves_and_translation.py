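"""Animation time curves driving a simple translation.

Builds a phantom of five spins that translates 1 cm along x, forward over
1 s and back at double speed, then prints the spin positions over time.
The same node pattern, periodically extended with warped repetitions,
illustrates pseudo-periodic motion (e.g. an irregular breathing cycle).
"""

import numpy as np

import blochflow as bf

# forward in 1 s (u: 0 -> 1), back at twice the speed (1 -> 0 in 0.5 s)
curve = bf.TimeCurve([0.0, 1.0, 1.5], [0.0, 1.0, 0.0])
motion = bf.Motion(bf.Translate(0.01, 0.0, 0.0), curve)

ph = bf.Phantom(
    x=np.linspace(-0.02, 0.02, 5), y=np.zeros(5), z=np.zeros(5),
    T1=1.0, T2=0.1, motion=motion,
)

times = [0.0, 0.5, 1.0, 1.25, 1.5]
xt, _, _ = bf.get_spin_coords(ph, times)
print("x positions (mm) of spin 0 over time:")
for t, x in zip(times, xt[0]):
    print(f"  t = {t:5.2f} s   x = {1e3 * x:7.3f} mm   (progress u = {curve(t):.2f})")
print("-> the spin reaches +10 mm displacement at t = 1 s and is back at 1.5 s.")

# pseudo-periodic extension: 2nd repetition half as long, 3rd 50% longer
warped = bf.TimeCurve([0.0, 0.6], [0.0, 1.0], periods=[1.0, 0.5, 1.5], periodic=True)
print("\nwarped periodic ramp, one value per repetition midpoint:")
for t in (0.3, 0.75, 1.35, 0.3 + 1.8):
    print(f"  u({t:4.2f} s) = {warped(t):.3f}")
print("-> each repetition spans u = 0..1 over a different duration; the whole")
print("   1.8 s pattern repeats indefinitely.")
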