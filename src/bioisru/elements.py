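"""Atomic weights and chemical-formula parsing.

Standard atomic weights (IUPAC 2021, abridged to the conventional values)
for the elements that occur in mission resource inventories, metabolic
reactions and regolith oxides. Parsing supports plain Hill-style formulas
with optional integer counts and parenthesised groups, e.g. ``C8H9NO2`` or
``(CH3)2NNH2``.
"""

from __future__ import annotations

import re

__all__ = ["ATOMIC_WEIGHTS", "parse_formula", "formula_weight", "FormulaError"]

# g/mol; conventional IUPAC values
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.948,
    "K": 39.098,
    "Ca": 40.078,
    "Ti": 47.867,
    "Cr": 51.996,
    "Mn": 54.938,
    "Fe": 55.845,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


class FormulaError(ValueError):
    """Raised when a chemical formula cannot be parsed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a formula string into an element → count map.

    >>> parse_formula("C2H3O2")
    {'C': 2, 'H': 3, 'O': 2}
    """
    if not formula or not isinstance(formula, str):
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    stack: list[dict[str, int]] = [{}]
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.start() != pos:
            raise FormulaError(
                f"unparseable token at position {pos} in {formula!r}: "
                f"{formula[pos:pos + 3]!r}"
            )
        element, count, open_p, close_p, group_count = m.groups()
        if open_p:
            stack.append({})
        elif close_p:
            if len(stack) == 1:
                raise FormulaError(f"unmatched ')' in {formula!r}")
            group = stack.pop()
            mult = int(group_count) if group_count else 1
            for el, n in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + n * mult
        else:
            if element not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element {element!r} in {formula!r}")
            n = int(count) if count else 1
            stack[-1][element] = stack[-1].get(element, 0) + n
        pos = m.end()
    if len(stack) != 1:
        raise FormulaError(f"unmatched '(' in {formula!r}")
    return stack[0]


def formula_weight(formula: str) -> float:
    """Molar mass in g/mol of a parsed formula."""
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in parse_formula(formula).items())
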