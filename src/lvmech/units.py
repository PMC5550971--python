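"""Unit conventions and conversion constants.

Stresses and tensions are expressed in kPa throughout the package;
cavity/blood pressures are given in mmHg at the interfaces and converted
internally.  Lengths are mm, volumes ml (1 ml = 1000 mm^3), times ms.
"""

KPA_PER_MMHG: float = 0.133322
"""1 mmHg in kPa; the single place the conversion factor lives."""

MM3_PER_ML: float = 1000.0


def mmhg_to_kpa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to kPa."""
    return p_mmhg * KPA_PER_MMHG


def kpa_to_mmhg(p_kpa: float) -> float:
    """Convert a pressure from kPa to mmHg."""
    return p_kpa / KPA_PER_MMHG
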