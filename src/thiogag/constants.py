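"""Physical constants and atomic mass tables.

Monoisotopic masses are CODATA/IUPAC 2021 values; average masses are the
conventional IUPAC standard atomic weights. All masses in Da (u).
"""

from __future__ import annotations

#: Monoisotopic atomic masses (Da) of the most abundant isotope.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "P": 30.97376163,
}

#: IUPAC conventional standard atomic weights (Da).
AVERAGE_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Na": 22.98976928,
    "P": 30.973761998,
}

#: Mass of the proton (Da); subtracted for [M-H]- ions.
PROTON_MASS: float = 1.00727646688

#: Monoisotopic O -> S substitution shift (Da).
O_TO_S_SHIFT: float = MONOISOTOPIC_MASS["S"] - MONOISOTOPIC_MASS["O"]

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K: float = 0.0019872041
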