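"""Standard atomic weight table.

The average-mass-per-atom descriptor at the heart of the screening rule is
sensitive to the atomic weight convention near the decision boundary, so the
table is explicit, documented, and user-overridable rather than buried in a
toolkit.  Values are IUPAC conventional standard atomic weights (unified
atomic mass units, >= 4 significant decimals where defined).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = ["MassTable", "MissingMassError", "CONVENTIONAL_ATOMIC_WEIGHTS", "ELEMENTS"]

#: IUPAC conventional standard atomic weights (u).
CONVENTIONAL_ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.9984, "Ne": 20.1797,
    "Na": 22.9898, "Mg": 24.305, "Al": 26.9815, "Si": 28.085, "P": 30.9738,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95,
    "K": 39.0983, "Ca": 40.078, "Sc": 44.9559, "Ti": 47.867, "V": 50.9415,
    "Cr": 51.9961, "Mn": 54.938, "Fe": 55.845, "Co": 58.9332, "Ni": 58.6934,
    "Cu": 63.546, "Zn": 65.38, "Ga": 69.723, "Ge": 72.63, "As": 74.9216,
    "Se": 78.971, "Br": 79.904, "Kr": 83.798,
    "Rb": 85.4678, "Sr": 87.62, "Y": 88.9058, "Zr": 91.224, "Nb": 92.9064,
    "Mo": 95.95, "Tc": 97.0, "Ru": 101.07, "Rh": 102.9055, "Pd": 106.42,
    "Ag": 107.8682, "Cd": 112.414, "In": 114.818, "Sn": 118.71,
    "Sb": 121.76, "Te": 127.60, "I": 126.9045, "Xe": 131.293,
    "Cs": 132.9055, "Ba": 137.327, "La": 138.9055, "Ce": 140.116,
    "Pr": 140.9077, "Nd": 144.242, "Pm": 145.0, "Sm": 150.36,
    "Eu": 151.964, "Gd": 157.25, "Tb": 158.9254, "Dy": 162.500,
    "Ho": 164.9303, "Er": 167.259, "Tm": 168.9342, "Yb": 173.045,
    "Lu": 174.9668, "Hf": 178.486, "Ta": 180.9479, "W": 183.84,
    "Re": 186.207, "Os": 190.23, "Ir": 192.217, "Pt": 195.084,
    "Au": 196.9666, "Hg": 200.592, "Tl": 204.38, "Pb": 207.2,
    "Bi": 208.9804, "Po": 209.0, "At": 210.0, "Rn": 222.0,
    "Fr": 223.0, "Ra": 226.0, "Ac": 227.0, "Th": 232.0377,
    "Pa": 231.0359, "U": 238.0289,
}

#: Element symbols the formula parser accepts.
ELEMENTS: frozenset[str] = frozenset(CONVENTIONAL_ATOMIC_WEIGHTS)


class MissingMassError(KeyError):
    """Raised when an element has no entry in the mass table."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"no atomic weight for element {self.symbol!r}"


@dataclass(frozen=True)
class MassTable:
    """Element symbol -> standard atomic weight (u).

    Invariants: every mass is strictly positive; ``mass('H')`` lies in
    [1.007, 1.009] for any table accepted by :meth:`validate`.
    """

    masses: Mapping[str, float] = field(
        default_factory=lambda: dict(CONVENTIONAL_ATOMIC_WEIGHTS)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for sym, m in self.masses.items():
            if not m > 0:
                raise ValueError(f"non-positive mass for {sym!r}: {m}")
        h = self.masses.get("H")
        if h is not None and not (1.007 <= h <= 1.009):
            raise ValueError(f"implausible hydrogen mass {h}")

    def mass(self, symbol: str) -> float:
        try:
            return self.masses[symbol]
        except KeyError:
            raise MissingMassError(symbol) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.masses

    def __iter__(self) -> Iterator[str]:
        return iter(self.masses)

    def with_overrides(self, **overrides: float) -> "MassTable":
        """Return a new table with some masses replaced (or added)."""
        merged = dict(self.masses)
        merged.update(overrides)
        return MassTable(merged)

    @classmethod
    def default(cls) -> "MassTable":
        return cls()
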