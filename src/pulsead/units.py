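"""Unit conversions between clinical and SI quantities.

The 0D (lumped) layer works in clinical units — mmHg, ml/s, ml/mmHg —
because blood-pressure targets and Windkessel parameter tables are always
printed that way.  The quasi-1D solver works in SI (Pa, m³/s, m²).  All
conversions funnel through the single constant below.
"""

MMHG_TO_PA: float = 133.322
"""1 mmHg in Pa."""

ML_TO_M3: float = 1e-6

#: 1 mmHg·s/ml in Pa·s/m³ (hydraulic resistance).
RES_CLIN_TO_SI: float = MMHG_TO_PA / ML_TO_M3

#: 1 ml/mmHg in m³/Pa (hydraulic compliance).
CAP_CLIN_TO_SI: float = ML_TO_M3 / MMHG_TO_PA


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_TO_PA


def resistance_si_to_clinical(r: float) -> float:
    """Pa·s/m³ → mmHg·s/ml."""
    return r / RES_CLIN_TO_SI


def resistance_clinical_to_si(r: float) -> float:
    """mmHg·s/ml → Pa·s/m³."""
    return r * RES_CLIN_TO_SI


def compliance_si_to_clinical(c: float) -> float:
    """m³/Pa → ml/mmHg."""
    return c / CAP_CLIN_TO_SI


def compliance_clinical_to_si(c: float) -> float:
    """ml/mmHg → m³/Pa."""
    return c * CAP_CLIN_TO_SI


def inertance_si_to_clinical(l: float) -> float:
    """Pa·s²/m³ → mmHg·s²/ml."""
    return l / RES_CLIN_TO_SI
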