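"""Unit system and conversions.

The whole package works in a consistent mm-g-ms unit system:

========== =============== =========================================
quantity   unit            notes
========== =============== =========================================
length     mm
mass       g
time       ms
force      N               1 g*mm/ms^2 = 1 N
stress     MPa             1 g/(mm*ms^2) = 1 MPa
density    g/mm^3
velocity   mm/ms           1 mm/ms = 1 m/s
========== =============== =========================================

Pressures are reported clinically in mmHg; the conversion constant is
kept here so it appears exactly once.
"""

MMHG_TO_MPA = 1.33322e-4
MPA_TO_MMHG = 1.0 / MMHG_TO_MPA


def mmhg(p_mpa: float) -> float:
    """Convert a pressure from MPa to mmHg."""
    return p_mpa * MPA_TO_MMHG


def mpa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to MPa."""
    return p_mmhg * MMHG_TO_MPA
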