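"""Physical constants and unit conventions.

Internal units throughout the package:

* k-space: cycles/mm
* gradients: mT/m
* slew rate: T/m/s  (equal to mT/m per ms)
* time: ms (trajectory design), µs (dwell)
* velocity: cm/s
* flow: mL/s, net flow mL
"""

import numpy as np

#: gyromagnetic ratio of 1H, Hz/T
GAMMA_HZ_PER_T = 42.5774688e6

#: gyromagnetic ratio, rad/(s*T)
GAMMA_RAD_PER_S_T = 2.0 * np.pi * GAMMA_HZ_PER_T

#: k-space speed per unit gradient: (cycles/mm)/ms per mT/m
#: dk/dt = gamma * G:  42.58e6 Hz/T * 1e-3 T/m = 42.58e3 cycles/m/s = 42.58e-3 cycles/mm/ms
K_PER_G = GAMMA_HZ_PER_T * 1e-9

#: golden-angle increment, degrees (360 - 360/phi, phi the golden ratio)
GOLDEN_ANGLE_DEG = 360.0 - 360.0 / ((1.0 + np.sqrt(5.0)) / 2.0)
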