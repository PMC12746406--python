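"""Physical constants used throughout the simulator."""

import numpy as np

#: Proton gyromagnetic ratio over 2*pi (Hz/T).
GAMMA_HZ = 42.5774688e6

#: Proton gyromagnetic ratio (rad/s/T).
GAMMA = 2.0 * np.pi * GAMMA_HZ
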