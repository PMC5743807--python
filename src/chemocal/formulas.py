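"""Elemental formulas: parsing, molar mass and degree of reduction.

The degree of reduction (generalized, ammonia as nitrogen source) counts
available electrons per mole: C +4, H +1, O -2, N -3, S +6.  Under this
convention NH3 and H2O carry zero electrons, O2 carries -4, glycerol 14
(4.67 per carbon) and methanol 6.
"""

from __future__ import annotations

import re

ATOMIC_MASS: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

#: electrons contributed per atom in the generalized degree-of-reduction balance
GAMMA: dict[str, float] = {"C": 4.0, "H": 1.0, "N": -3.0, "O": -2.0, "S": 6.0}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse ``"C3H8O3"`` (counts may be fractional, e.g. a C-mol formula)."""
    if not formula:
        return {}
    out: dict[str, float] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        n = float(m.group(2)) if m.group(2) else 1.0
        out[m.group(1)] = out.get(m.group(1), 0.0) + n
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


def format_formula(formula: dict[str, float]) -> str:
    """Render an element->count map as a Hill-ordered string."""
    order = ["C", "H"] + sorted(e for e in formula if e not in ("C", "H"))
    parts = []
    for el in order:
        n = formula.get(el, 0.0)
        if n == 0:
            continue
        if n == 1:
            parts.append(el)
        elif float(n).is_integer():
            parts.append(f"{el}{int(n)}")
        else:
            parts.append(f"{el}{n:g}")
    return "".join(parts)


def molar_mass(formula: dict[str, float] | str) -> float:
    """Molar mass in g/mol from an element->count map or formula string."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    try:
        return sum(ATOMIC_MASS[el] * n for el, n in formula.items())
    except KeyError as e:  # pragma: no cover - exotic elements
        raise ValueError(f"no atomic mass for element {e}") from None


def degree_of_reduction(formula: dict[str, float] | str) -> float:
    """Available electrons per mole; elements outside CHNOS contribute zero."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(GAMMA.get(el, 0.0) * n for el, n in formula.items())


WATER = parse_formula("H2O")
M_WATER = molar_mass(WATER)
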