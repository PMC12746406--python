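"""SPAMM tagging on a contracting annulus.

A 1-1 SPAMM preparation (90 - tagging gradient - 90 - spoiler) imprints a
cosine modulation on the longitudinal magnetization with a 5 mm spatial
period.  Applied to a heart-like annulus mid-contraction, the tag pattern
deforms with the tissue -- the principle behind myocardial tagging.
"""

import numpy as np

import blochflow as bf

spacing = 0.005  # 5 mm tag period
phantom = bf.make_heartbeat_annulus(
    strains=(-0.15, 0.25, 0.0), period=1.0, n_spins=3000, seed=2
)
prep = bf.build_spamm_prep(grid_spacing=spacing)

_, state = bf.simulate(phantom, prep, return_state=True, dt_rf=1e-6)
mz = state.mz

# tag modulation follows the spin x coordinate at preparation time (t ~ 0)
expected = -np.cos(2 * np.pi * phantom.x / spacing)
corr = np.corrcoef(mz, expected)[0, 1]
print(f"Mz after SPAMM prep: range [{mz.min():.3f}, {mz.max():.3f}]")
print(f"correlation with cos(2 pi x / {1e3 * spacing:g} mm): {corr:.4f}")
print("-> the longitudinal magnetization carries a cosine tag grid; imaging at")
print("   later cardiac phases shows the grid deforming with the contraction.")
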