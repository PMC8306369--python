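"""Health states and ICD-10 primary-diagnosis classification.

The progression model uses four states: WELL (admitted for cardiovascular
disease other than myocardial infarction), NSTEMI, STEMI and DEAD. DEAD is
absorbing and the ordering WELL < NSTEMI < STEMI < DEAD defines the
"forward" direction of disease progression; only forward transitions are
modelled.
"""

from __future__ import annotations

from enum import Enum, IntEnum


class HealthState(IntEnum):
    """True/observed health state; integer order encodes severity."""

    WELL = 0
    NSTEMI = 1
    STEMI = 2
    DEAD = 3


#: live (non-absorbing) states, in severity order
LIVE_STATES = (HealthState.WELL, HealthState.NSTEMI, HealthState.STEMI)


class ICDClass(str, Enum):
    """Classification of a primary ICD-10 diagnosis code for this model."""

    WELL_OTHER_CVD = "well_other_cvd"
    NSTEMI = "nstemi"
    STEMI = "stemi"
    EXCLUDED_MI = "excluded_mi"


# I21.4: NSTEMI. I21.0-I21.3: STEMI (anterior/inferior/other-site/
# unspecified-site transmural). I21.9 and I21.A: unspecified / other MI,
# excluded from the analysis as events.
_NSTEMI_CODES = {"I214"}
_STEMI_CODES = {"I210", "I211", "I212", "I213"}
_EXCLUDED_MI_CODES = {"I219", "I21A"}


def _canonical(code: str) -> str:
    return code.strip().upper().replace(".", "")


def classify_icd10(code: str) -> ICDClass:
    """Classify a primary ICD-10 code into the model's observation classes.

    Total over non-empty strings: anything that is not one of the MI codes
    maps to ``WELL_OTHER_CVD`` — the "well" state is the *absence* of MI,
    not good health.

    Parameters
    ----------
    code : str
        ICD-10 code, with or without the dot (``"I21.4"`` or ``"I214"``).

    Raises
    ------
    ValueError
        If ``code`` is empty or whitespace.
    """
    if not isinstance(code, str) or not code.strip():
        raise ValueError("ICD-10 code must be a non-empty string")
    c = _canonical(code)
    if c in _NSTEMI_CODES:
        return ICDClass.NSTEMI
    if c in _STEMI_CODES:
        return ICDClass.STEMI
    if c in _EXCLUDED_MI_CODES:
        return ICDClass.EXCLUDED_MI
    return ICDClass.WELL_OTHER_CVD


def is_cvd_code(code: str) -> bool:
    """True if the code belongs to ICD-10 chapter IX (circulatory, ``I``)."""
    if not isinstance(code, str) or not code.strip():
        return False
    return _canonical(code).startswith("I")


#: observation classes that count as an MI event
MI_CLASSES = (ICDClass.NSTEMI, ICDClass.STEMI)

#: map from observation class to the health state it records
CLASS_TO_STATE = {
    ICDClass.WELL_OTHER_CVD: HealthState.WELL,
    ICDClass.NSTEMI: HealthState.NSTEMI,
    ICDClass.STEMI: HealthState.STEMI,
}
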