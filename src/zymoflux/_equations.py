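"""Parsing of reaction equation strings.

The dialect used across pathway files and the core-network table is
``"1 glc + 1 atp -> 1 g6p + 1 adp"``; ``<->`` marks a reversible reaction,
a missing coefficient means 1, and a one-sided equation (``"glc_e ->"``)
denotes an exchange/sink.
"""

from __future__ import annotations

import re

_ARROWS = ("<->", "<=>", "->", "=>")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string into a signed stoichiometry map.

    Returns ``(stoich, reversible)`` with substrates negative and products
    positive. Raises ``ValueError`` on malformed input.
    """
    arrow = None
    for a in _ARROWS:
        if a in eq:
            arrow = a
            break
    if arrow is None:
        raise ValueError(f"no reaction arrow in equation: {eq!r}")
    reversible = arrow in ("<->", "<=>")
    lhs, rhs = eq.split(arrow, 1)
    stoich: dict[str, float] = {}
    for side, sign in ((lhs, -1.0), (rhs, +1.0)):
        side = side.strip()
        if not side:
            continue
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ValueError(f"empty term in equation: {eq!r}")
            m = re.match(r"^(\d+\.?\d*(?:[eE][+-]?\d+)?\s+)?(\S+)$", term)
            if m is None:
                raise ValueError(f"cannot parse term {term!r} in {eq!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    if not stoich:
        raise ValueError(f"equation has no species: {eq!r}")
    return stoich, reversible


def format_equation(stoich: dict[str, float], reversible: bool = False) -> str:
    """Inverse of :func:`parse_equation` (up to coefficient formatting)."""

    def fmt(items):
        return " + ".join(
            (f"{abs(c):g} {m}" if abs(c) != 1 else m) for m, c in items
        )

    subs = [(m, c) for m, c in stoich.items() if c < 0]
    prods = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<->" if reversible else "->"
    return f"{fmt(subs)} {arrow} {fmt(prods)}".strip()
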