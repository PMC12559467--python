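"""Elemental constants used by the stopping-power model.

Atomic numbers, standard atomic masses (g/mol) and mean excitation
energies I (eV, ICRU-style elemental values) for every element that
appears in the film, backing, air and water compositions.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ElementData:
    """One chemical element as seen by the Bethe formula."""

    symbol: str
    Z: int
    A: float  # g/mol
    I: float  # mean excitation energy, eV

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"{self.symbol}: Z must be >= 1")
        if self.A <= 0:
            raise ValueError(f"{self.symbol}: A must be > 0")
        if self.I <= 0:
            raise ValueError(f"{self.symbol}: I must be > 0")


#: Registry of supported elements.
ELEMENTS: dict[str, ElementData] = {
    e.symbol: e
    for e in [
        ElementData("H", 1, 1.008, 19.2),
        ElementData("Li", 3, 6.94, 40.0),
        ElementData("C", 6, 12.011, 78.0),
        ElementData("N", 7, 14.007, 82.0),
        ElementData("O", 8, 15.999, 95.0),
        ElementData("Na", 11, 22.990, 149.0),
        ElementData("Al", 13, 26.982, 166.0),
        ElementData("S", 16, 32.06, 180.0),
        ElementData("Cl", 17, 35.45, 174.0),
        ElementData("Ar", 18, 39.948, 188.0),
    ]
}


class UnknownElementError(KeyError):
    """Raised when a composition references an element not in the registry."""


def get_element(symbol: str) -> ElementData:
    try:
        return ELEMENTS[symbol]
    except KeyError as exc:
        raise UnknownElementError(
            f"element {symbol!r} is not in the registry "
            f"(known: {sorted(ELEMENTS)})"
        ) from exc
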