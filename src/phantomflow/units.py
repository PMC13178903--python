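"""Unit conventions and conversion constants.

All internal computation is SI (m, s, kg, Pa). Pressures cross text and
reporting interfaces in mmHg; the conversion constant is defined here and
nowhere else.
"""

#: Pascals per millimetre of mercury (conventional value).
MMHG_PA: float = 133.322387415


def pa_to_mmhg(p_pa):
    """Convert a pressure (array or scalar) from Pa to mmHg."""
    return p_pa / MMHG_PA


def mmhg_to_pa(p_mmhg):
    """Convert a pressure (array or scalar) from mmHg to Pa."""
    return p_mmhg * MMHG_PA
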