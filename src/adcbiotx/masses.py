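"""Elemental formula arithmetic and mass constants.

All mass computation delegates to :mod:`pyteomics.mass` (NIST atomic masses and
isotopic abundances).  Formulas are handled as :class:`pyteomics.mass.Composition`
objects, which behave like element->count Counters and support signed counts, so
modification deltas (e.g. deamidation to alcohol, ``+O -N -H``) are ordinary
compositions with negative entries.
"""

from __future__ import annotations

import re

from pyteomics import mass as _pmass

Composition = _pmass.Composition

#: Mass of a proton (charge carrier in positive-mode electrospray), Da.
PROTON_MASS = 1.00727646

#: Monoisotopic mass of hydrogen, Da (used for disulfide corrections).
H_MONO = _pmass.nist_mass["H"][0][0]

_MODES = ("monoisotopic", "average")


def formula_mass(formula: str | Composition, mode: str = "monoisotopic") -> float:
    """Mass of an elemental formula in Da.

    ``mode='monoisotopic'`` sums most-abundant-isotope masses; ``'average'``
    sums standard atomic weights.  The empty formula has mass 0.  Signed
    formula strings such as ``"+H2O-NH"`` are accepted.

    Raises
    ------
    ValueError
        If the mode or an element symbol is unknown.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    comp = formula if isinstance(formula, Composition) else parse_formula(formula)
    for element in comp:
        if element not in _pmass.nist_mass:
            raise ValueError(f"unknown element symbol: {element!r}")
    return _pmass.calculate_mass(composition=comp, average=(mode == "average"))


_SIGNED_PART = re.compile(r"([+-])\s*([A-Za-z0-9]+)")


def parse_formula(text: str) -> Composition:
    """Parse a formula string, optionally with signed parts (``"+H2O-C2H5N"``)."""
    text = text.strip()
    if not text:
        return Composition()
    if text[0] not in "+-" and "+" not in text and "-" not in text:
        return Composition(formula=text)
    total = Composition()
    if text[0] not in "+-":
        text = "+" + text
    consumed = 0
    for m in _SIGNED_PART.finditer(text.replace(" ", "")):
        part = Composition(formula=m.group(2))
        total = total + part if m.group(1) == "+" else total - part
        consumed += len(m.group(0))
    if consumed != len(text.replace(" ", "")):
        raise ValueError(f"cannot parse formula {text!r}")
    return total


_HILL_FIRST = ("C", "H")


def _hill_order(elements) -> list[str]:
    rest = sorted(e for e in elements if e not in _HILL_FIRST)
    return [e for e in _HILL_FIRST if e in elements] + rest


def format_formula(comp: Composition) -> str:
    """Render a composition in Hill order; mixed-sign compositions render as
    ``"+<gains>-<losses>"`` (e.g. ``"+O-HN"`` for deamidation to alcohol)."""
    comp = Composition(comp)
    pos = {e: n for e, n in comp.items() if n > 0}
    neg = {e: -n for e, n in comp.items() if n < 0}

    def block(d):
        return "".join(
            e + (str(d[e]) if d[e] != 1 else "") for e in _hill_order(d)
        )

    if not pos and not neg:
        return ""
    if not neg:
        return block(pos)
    if not pos:
        return "-" + block(neg)
    return "+" + block(pos) + "-" + block(neg)


def mh_to_neutral(mh_mass: float) -> float:
    """Convert a singly protonated (MH+) mass to the neutral mass.

    Raises ``ValueError`` when the input does not exceed the proton mass.
    """
    if mh_mass <= PROTON_MASS:
        raise ValueError(f"MH+ mass {mh_mass} must exceed the proton mass")
    return mh_mass - PROTON_MASS


def neutral_to_mz(neutral_mass: float, z: int) -> float:
    """m/z of a neutral mass carrying ``z`` protons."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + z * PROTON_MASS) / z
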