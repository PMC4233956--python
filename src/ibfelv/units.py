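"""Unit conversions.

All internal computation is in CGS (cm, g, s, dyn/cm^2).  Configuration
values may be given in kPa (moduli) or mmHg (pressures) and are converted
on entry.
"""

KPA_TO_CGS = 1.0e4          # 1 kPa = 1e4 dyn/cm^2
MMHG_TO_CGS = 1333.22       # 1 mmHg = 1333.22 dyn/cm^2
CGS_TO_KPA = 1.0 / KPA_TO_CGS
CGS_TO_MMHG = 1.0 / MMHG_TO_CGS
ML_PER_CM3 = 1.0


def kpa(x: float) -> float:
    """Convert kPa to dyn/cm^2."""
    return x * KPA_TO_CGS


def mmhg(x: float) -> float:
    """Convert mmHg to dyn/cm^2."""
    return x * MMHG_TO_CGS
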