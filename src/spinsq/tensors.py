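"""Tensor references and tensor symmetry classes.

Three symmetry classes are supported:

``NONE``
    A plain n-index array; one canonical index ordering (the stored one).
``PAIR_PERMUTATION``
    Particle-exchange symmetry of 2n-index tensors: neighbouring index
    pairs may be permuted as blocks, e.g. ``g_pqrs = g_rspq`` — ``n!``
    equivalent orderings.
``FULL_REAL``
    Additionally each pair may be flipped internally, as for two-electron
    integrals over real orbitals (``g_pqrs = g_qprs = ... = g_srqp``) —
    ``n!·2^n`` equivalent orderings.

All symmetries here are signless, so canonical sorting never produces a
phase.  The canonical order sorts pairs (and, for ``FULL_REAL``, the two
members of each pair) ascending by index ordinal.
"""

from __future__ import annotations

from enum import IntEnum
from itertools import permutations, product
from typing import Iterator


class TensorSymmetry(IntEnum):
    NONE = 0
    PAIR_PERMUTATION = 1
    FULL_REAL = 2


def canonical_sort_indices(
    indices: tuple[int, ...], symmetry: TensorSymmetry
) -> tuple[int, ...]:
    """Return the symmetry-canonical ordering of ``indices``."""
    if symmetry == TensorSymmetry.NONE:
        return tuple(indices)
    if len(indices) % 2:
        raise ValueError(
            f"pair symmetries require an even index count, got {len(indices)}"
        )
    pairs = [tuple(indices[k : k + 2]) for k in range(0, len(indices), 2)]
    if symmetry == TensorSymmetry.FULL_REAL:
        pairs = [tuple(sorted(p)) for p in pairs]
    pairs.sort()
    return tuple(i for p in pairs for i in p)


def symmetry_orbit(
    indices: tuple[int, ...], symmetry: TensorSymmetry
) -> Iterator[tuple[int, ...]]:
    """Yield every index ordering equivalent to ``indices`` (with repeats
    when indices coincide); ``NONE`` yields 1, pair symmetry ``n!`` and
    full-real ``n!·2^n`` orderings."""
    if symmetry == TensorSymmetry.NONE:
        yield tuple(indices)
        return
    pairs = [tuple(indices[k : k + 2]) for k in range(0, len(indices), 2)]
    flips = (
        list(product((False, True), repeat=len(pairs)))
        if symmetry == TensorSymmetry.FULL_REAL
        else [(False,) * len(pairs)]
    )
    for perm in permutations(pairs):
        for flip in flips:
            out: list[int] = []
            for pair, fl in zip(perm, flip):
                out.extend(pair[::-1] if fl else pair)
            yield tuple(out)


class TensorRef:
    """One tensor factor of a term: a name, ordered indices and a symmetry.

    Indices are stored in the symmetry-canonical order.
    """

    __slots__ = ("name", "indices", "symmetry", "_key")

    def __init__(
        self,
        name: str,
        indices: tuple[int, ...],
        symmetry: TensorSymmetry = TensorSymmetry.NONE,
    ):
        if symmetry != TensorSymmetry.NONE and len(indices) % 2:
            raise ValueError(
                f"tensor {name!r}: pair symmetries require even arity"
            )
        self.name = name
        self.indices = canonical_sort_indices(tuple(indices), symmetry)
        self.symmetry = symmetry
        self._key = (name, len(self.indices), int(symmetry), self.indices)

    @property
    def key(self):
        return self._key

    def substitute(self, mapping: dict[int, int]) -> "TensorRef":
        return TensorRef(
            self.name,
            tuple(mapping.get(i, i) for i in self.indices),
            self.symmetry,
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, TensorRef) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        return f"TensorRef({self.name!r}, {self.indices}, {self.symmetry.name})"


def canonical_sort_tensor(t: TensorRef) -> TensorRef:
    """Return ``t`` with indices in symmetry-canonical order (idempotent;
    the constructor already sorts, so this is the identity on valid refs)."""
    return TensorRef(t.name, t.indices, t.symmetry)
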