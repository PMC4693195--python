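"""Elemental formula handling for medium components and metabolites.

Formulas are stored as plain ``{element: count}`` maps. The parser accepts
the notation used on reagent labels: nested parentheses with multipliers
(``(NH4)2SO4``) and hydrate/adduct parts separated by ``.`` or ``·`` with a
leading multiplier (``MgSO4.7H2O``). Counts are non-negative integers.
"""

from __future__ import annotations

import re

from .errors import FormatError

# Standard atomic weights (g/mol), CODATA/IUPAC abridged values. Only the
# elements that occur in culture-medium components are listed; unknown
# elements raise rather than silently contributing zero mass.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "K": 39.098, "Ca": 40.078, "Mn": 54.938, "Fe": 55.845, "Co": 58.933,
    "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "Mo": 95.95, "I": 126.904,
    "Ba": 137.327, "Se": 78.971,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse ``text`` into an element-count map.

    Raises FormatError on anything that is not a well-formed formula.
    """
    total: dict[str, int] = {}
    for part in re.split(r"[.·⋅]", text.strip()):
        if not part:
            raise FormatError(f"empty part in formula {text!r}")
        m = re.match(r"(\d+)(.*)", part)
        mult = 1
        if m and m.group(2):
            mult, part = int(m.group(1)), m.group(2)
        counts = _parse_group(part, text)
        for el, n in counts.items():
            total[el] = total.get(el, 0) + mult * n
    return total


def _parse_group(s: str, original: str) -> dict[str, int]:
    stack: list[dict[str, int]] = [{}]
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "(":
            stack.append({})
            i += 1
        elif ch == ")":
            if len(stack) == 1:
                raise FormatError(f"unbalanced ')' in formula {original!r}")
            group = stack.pop()
            i += 1
            m = re.match(r"\d+", s[i:])
            mult = int(m.group(0)) if m else 1
            i += len(m.group(0)) if m else 0
            for el, n in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + mult * n
        else:
            m = re.match(r"([A-Z][a-z]?)(\d*)", s[i:])
            if not m:
                raise FormatError(f"cannot parse {s[i:]!r} in formula {original!r}")
            el, digits = m.group(1), m.group(2)
            stack[-1][el] = stack[-1].get(el, 0) + (int(digits) if digits else 1)
            i += len(m.group(0))
    if len(stack) != 1:
        raise FormatError(f"unbalanced '(' in formula {original!r}")
    return stack[0]


def molar_mass(formula: dict[str, int] | str) -> float:
    """Molar mass (g/mol) of a formula map or formula string."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    mass = 0.0
    for el, n in formula.items():
        if el not in ATOMIC_MASS:
            raise FormatError(f"no atomic mass for element {el!r}")
        mass += ATOMIC_MASS[el] * n
    return mass


def format_formula(formula: dict[str, int]) -> str:
    """Render a count map as a Hill-order formula string (C, H, then others)."""
    keys = sorted(formula, key=lambda e: (e != "C", e != "H", e))
    out = []
    for el in keys:
        n = formula[el]
        if n == 0:
            continue
        out.append(el if n == 1 else f"{el}{n}")
    return "".join(out)
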