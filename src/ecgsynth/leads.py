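"""Canonical 12-lead montage: names, ordering, groups, and exact limb-lead algebra.

The six frontal-plane leads are linearly dependent: given leads I and II, the
remaining four are fixed linear combinations (Einthoven's triangle and the
Goldberger augmented leads).  Those identities are used both by the simulator
(which enforces them exactly) and by tests that check the lead-combination
search recovers them.
"""

from __future__ import annotations

import numpy as np

#: Canonical lead order used everywhere in this package.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

LEAD_INDEX: dict[str, int] = {name: i for i, name in enumerate(LEAD_NAMES)}

#: Lead groups as conventionally reported (bipolar limb, augmented, precordial).
STANDARD_LEADS: tuple[str, ...] = ("I", "II", "III")
EXTREMITY_LEADS: tuple[str, ...] = ("aVR", "aVL", "aVF")
PRECORDIAL_LEADS: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V5", "V6")

LEAD_GROUPS: dict[str, tuple[str, ...]] = {
    "standard": STANDARD_LEADS,
    "extremity": EXTREMITY_LEADS,
    "precordial": PRECORDIAL_LEADS,
}


def check_lead_name(name: str) -> str:
    """Return *name* if it is a canonical lead name, else raise ``ValueError``."""
    if name not in LEAD_INDEX:
        raise ValueError(f"unknown lead name {name!r}; expected one of {LEAD_NAMES}")
    return name


def derived_limb_leads(lead_i: np.ndarray, lead_ii: np.ndarray) -> dict[str, np.ndarray]:
    """Compute III, aVR, aVL, aVF exactly from leads I and II.

    III = II - I; aVR = -(I + II)/2; aVL = I - II/2; aVF = II - I/2.
    """
    lead_i = np.asarray(lead_i, dtype=float)
    lead_ii = np.asarray(lead_ii, dtype=float)
    return {
        "III": lead_ii - lead_i,
        "aVR": -(lead_i + lead_ii) / 2.0,
        "aVL": lead_i - lead_ii / 2.0,
        "aVF": lead_ii - lead_i / 2.0,
    }
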