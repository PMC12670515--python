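"""Orbital index spaces.

Spatial-orbital indices are abstract positive integers ("ordinals"); which
orbitals an index may run over is recorded per term in a constraint map from
ordinal to :class:`OrbitalSpace`.  The three built-in spaces form a tiny
lattice: ``occupied`` and ``virtual`` are disjoint subspaces of ``general``.
Spaces are represented by bitmasks so that intersection is a bitwise AND,
which keeps the hot canonicalization path cheap.
"""

from __future__ import annotations

__all__ = [
    "OrbitalSpace",
    "GENERAL",
    "OCCUPIED",
    "VIRTUAL",
    "EMPTY",
    "space_from_letter",
]

_OCC_BIT = 0b01
_VIR_BIT = 0b10


class OrbitalSpace:
    """A set of spatial orbitals an index may run over.

    Parameters
    ----------
    name:
        Identifier used in diagnostics and rendered constraints.
    mask:
        Bitmask over the atomic subspaces (occupied, virtual).
    letters:
        Ordered glyphs used when printing indices of this space.
    short:
        One-character tag used in rendered constraints, e.g. ``C(a∈v)``.
    """

    __slots__ = ("name", "mask", "letters", "short")
    _registry: dict[int, "OrbitalSpace"] = {}

    def __init__(self, name: str, mask: int, letters: str, short: str):
        self.name = name
        self.mask = mask
        self.letters = letters
        self.short = short
        OrbitalSpace._registry[mask] = self

    def __and__(self, other: "OrbitalSpace") -> "OrbitalSpace":
        return OrbitalSpace._registry[self.mask & other.mask]

    def __contains__(self, other: "OrbitalSpace") -> bool:
        """True if ``other`` is a subspace of self."""
        return (self.mask & other.mask) == other.mask

    @property
    def is_empty(self) -> bool:
        return self.mask == 0

    @property
    def parent(self) -> "OrbitalSpace | None":
        if self.mask in (0, _OCC_BIT | _VIR_BIT):
            return None
        return GENERAL

    def __repr__(self) -> str:
        return f"OrbitalSpace({self.name})"

    # Spaces are singletons; identity comparison and default hash are fine.


EMPTY = OrbitalSpace("empty", 0, "", "0")
OCCUPIED = OrbitalSpace("occupied", _OCC_BIT, "ijklmn", "o")
VIRTUAL = OrbitalSpace("virtual", _VIR_BIT, "abcdefgh", "v")
GENERAL = OrbitalSpace("general", _OCC_BIT | _VIR_BIT, "pqrstuvw", "g")

_BY_LETTER = {}
for _sp in (OCCUPIED, VIRTUAL, GENERAL):
    for _ch in _sp.letters:
        _BY_LETTER[_ch] = _sp


def space_from_letter(letter: str) -> OrbitalSpace:
    """Map a printable index letter back to its orbital space.

    The leading alphabetic part of the glyph decides: ``i``–``n`` are
    occupied, ``a``–``h`` virtual, ``p``–``w`` general.
    """
    base = letter.rstrip("0123456789")
    try:
        return _BY_LETTER[base]
    except KeyError:
        raise ValueError(f"unknown index letter {letter!r}") from None
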