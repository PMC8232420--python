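"""Elemental composition, molecular formula parsing, and the constitutional
descriptors built on them.

The descriptors computed here — molecular weight, average mass per atom
(``amw``) and hydrogen percentage (``h_percent``) — are deliberately
implemented from first principles on an explicit element->count map so that
they are auditable and independent of any structure toolkit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

from .masses import ELEMENTS, MassTable

__all__ = [
    "Composition",
    "FormulaParseError",
    "parse_formula",
    "molecular_weight",
    "amw",
    "h_percent",
]


class FormulaParseError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


@dataclass(frozen=True)
class Composition:
    """Element -> count map with explicit hydrogen accounting.

    Parameters
    ----------
    counts
        Mapping of element symbol to a non-negative integer count.  At least
        one element must have a strictly positive count.
    charge
        Net formal charge of the species (default 0).
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if not isinstance(n, int) or isinstance(n, bool):
                raise ValueError(f"count for {sym!r} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for {sym!r}: {n}")
            if n > 0:
                clean[sym] = n
        if not clean:
            raise ValueError("composition must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def count(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def scaled(self, k: int) -> "Composition":
        """Composition with every count multiplied by a positive integer."""
        if k < 1:
            raise ValueError("scale factor must be a positive integer")
        return Composition({s: n * k for s, n in self.counts.items()}, self.charge)

    def merged(self, other: "Composition") -> "Composition":
        out = dict(self.counts)
        for s, n in other.counts.items():
            out[s] = out.get(s, 0) + n
        return Composition(out, self.charge + other.charge)

    def hill_formula(self) -> str:
        """Hill notation: C first, H second, then remaining symbols
        alphabetically (all symbols alphabetical when carbon is absent)."""
        syms = set(self.counts)
        ordered: list[str]
        if "C" in syms:
            rest = sorted(syms - {"C", "H"})
            ordered = ["C"] + (["H"] if "H" in syms else []) + rest
        else:
            ordered = sorted(syms)
        return "".join(
            f"{s}{self.counts[s]}" if self.counts[s] != 1 else s for s in ordered
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Composition):
            return NotImplemented
        return dict(self.counts) == dict(other.counts) and self.charge == other.charge

    def __hash__(self) -> int:
        return hash((frozenset(self.counts.items()), self.charge))


_TOKEN = re.compile(
    r"(?P<element>[A-Z][a-z]?)"
    r"|(?P<digits>\d+)"
    r"|(?P<open>[\(\[])"
    r"|(?P<close>[\)\]])"
    r"|(?P<sign>[+-])"
    r"|(?P<dot>[.·])"
    r"|(?P<other>.)"
)


def parse_formula(formula: str) -> Composition:
    """Parse a Hill-notation molecular formula into a :class:`Composition`.

    Supports element/count runs, parenthesized or bracketed groups with
    trailing multipliers, dot-connected fragments with an optional leading
    multiplier (hydrates, salts written as adducts) and a trailing charge
    (``+``, ``2-``, ``-2`` ...).

    Raises
    ------
    FormulaParseError
        On an empty string, an unknown element symbol (named in the message),
        unbalanced groups, or stray characters.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaParseError("empty formula")
    text = formula.strip()

    tokens = []
    for m in _TOKEN.finditer(text):
        kind = m.lastgroup
        tok = m.group()
        if kind == "other":
            if tok.isspace():
                continue
            raise FormulaParseError(f"unexpected character {tok!r} in {formula!r}")
        tokens.append((kind, tok))

    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None)

    def take():
        nonlocal pos
        t = tokens[pos]
        pos += 1
        return t

    def read_count(default: int = 1) -> int:
        nonlocal pos
        if peek()[0] == "digits":
            return int(take()[1])
        return default

    def parse_group(closer: str | None) -> dict[str, int]:
        nonlocal pos
        counts: dict[str, int] = {}
        while pos < len(tokens):
            kind, tok = peek()
            if kind == "close":
                if closer is None:
                    raise FormulaParseError(f"unbalanced {tok!r} in {formula!r}")
                if tok != closer:
                    raise FormulaParseError(f"mismatched group delimiter in {formula!r}")
                return counts
            if kind == "element":
                take()
                if tok not in ELEMENTS:
                    raise FormulaParseError(f"unknown element symbol {tok!r}")
                counts[tok] = counts.get(tok, 0) + read_count()
            elif kind == "open":
                take()
                want = ")" if tok == "(" else "]"
                inner = parse_group(want)
                if peek()[1] != want:
                    raise FormulaParseError(f"unbalanced {tok!r} in {formula!r}")
                take()
                mult = read_count()
                for s, n in inner.items():
                    counts[s] = counts.get(s, 0) + n * mult
            elif kind == "dot":
                take()
                mult = read_count()
                inner = parse_group(closer)
                for s, n in inner.items():
                    counts[s] = counts.get(s, 0) + n * mult
                return counts
            elif kind in ("sign", "digits"):
                break  # trailing charge
            else:  # pragma: no cover - defensive
                raise FormulaParseError(f"unexpected token {tok!r}")
        return counts

    counts = parse_group(None)

    # Trailing charge: "+", "-", "2+", "+2", "2-", "-2".
    charge = 0
    if pos < len(tokens):
        kind, tok = peek()
        if kind == "digits":
            mag = int(take()[1])
            kind, tok = peek()
            if kind != "sign":
                raise FormulaParseError(f"dangling count in {formula!r}")
            take()
            charge = mag if tok == "+" else -mag
        elif kind == "sign":
            take()
            sign = 1 if tok == "+" else -1
            mag = read_count()
            charge = sign * mag
        if pos < len(tokens):
            raise FormulaParseError(f"trailing tokens in {formula!r}")

    if not counts:
        raise FormulaParseError(f"no atoms in formula {formula!r}")
    return Composition(counts, charge)


def molecular_weight(composition: Composition, masses: MassTable | None = None) -> float:
    """Sum of count(e) * atomic weight(e) over the composition, in u.

    Raises :class:`~dilitree.chem.masses.MissingMassError` naming the element
    if the table lacks an entry.
    """
    table = masses if masses is not None else MassTable.default()
    # summation in sorted element order makes the result exactly invariant
    # under permutations of the formula
    return sum(n * table.mass(sym) for sym, n in sorted(composition.counts.items()))


def amw(composition: Composition, masses: MassTable | None = None) -> float:
    """Average mass per atom: molecular weight / total atom count.

    Hydrogens are included in both the numerator and the denominator.  This
    is an intensive quantity: invariant under element ordering and under
    multiplying all counts by a positive integer.
    """
    n = composition.total_atoms
    if n <= 0:  # unreachable through the constructor; defensive
        raise ValueError("composition has no atoms")
    return molecular_weight(composition, masses) / n


def h_percent(composition: Composition) -> float:
    """Percentage of hydrogen atoms among all atoms, in [0, 100]."""
    n = composition.total_atoms
    if n <= 0:
        raise ValueError("composition has no atoms")
    return 100.0 * composition.count("H") / n
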