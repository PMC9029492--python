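"""Physical constants (SI).

All internal computation in this package is strict SI; unit conversion to the
conventional hyperthermia units (kA/m, kHz, nm, W/g) happens exactly once, at
the configuration/CLI boundary.
"""

import math

#: Vacuum magnetic permeability, H/m (defined value 4*pi*1e-7).
MU0: float = 4.0e-7 * math.pi

#: Boltzmann constant, J/K (exact SI value).
KB: float = 1.380649e-23

#: Néel exponent clamp.  exp(700) ~ 1e304 sits just under the double-precision
#: ceiling; a Néel time above ~1e294 s is physically indistinguishable from
#: infinite, so larger exponents map to an "effectively infinite" time whose
#: reciprocal is zero.
NEEL_EXPONENT_MAX: float = 700.0
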