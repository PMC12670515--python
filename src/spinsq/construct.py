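"""User-facing constructors mirroring the usual pen-and-paper notation.

Indices are plain positive integers.  Every constructor returns an
:class:`~spinsq.terms.Expression`, so pieces compose with ``*``, ``+`` and
exact rational scalars::

    from fractions import Fraction
    from spinsq import E, psym_tensor, occupied, virtual

    t2 = Fraction(1, 2) * (
        psym_tensor("t", 1, 2, 3, 4) * E(1, 2) * E(3, 4)
        * virtual(1, 3) * occupied(2, 4)
    ).sum_over(1, 2, 3, 4)
"""

from __future__ import annotations

from fractions import Fraction

from .operators import (
    ALPHA,
    BETA,
    BosonOp,
    SingletExcitation,
    SpinFermion,
    TripletExcitation,
)
from .spaces import GENERAL, OCCUPIED, VIRTUAL, OrbitalSpace
from .tensors import TensorRef, TensorSymmetry
from .terms import Expression, Term

__all__ = [
    "real_tensor",
    "psym_tensor",
    "rsym_tensor",
    "E",
    "e",
    "tau",
    "fermion",
    "boson",
    "delta",
    "electron",
    "occupied",
    "virtual",
    "constrain",
    "summation",
    "ALPHA",
    "BETA",
]


def _single(term: Term) -> Expression:
    return Expression((term,))


def real_tensor(name: str, *indices: int) -> Expression:
    """A tensor with no assumed symmetry (arity 0 gives a named scalar)."""
    return _single(
        Term(1, tensors=(TensorRef(name, indices, TensorSymmetry.NONE),))
    )


def psym_tensor(name: str, *indices: int) -> Expression:
    """A 2n-index tensor with particle-exchange (pair-permutation)
    symmetry, e.g. two-electron integrals or cluster amplitudes."""
    return _single(
        Term(
            1,
            tensors=(TensorRef(name, indices, TensorSymmetry.PAIR_PERMUTATION),),
        )
    )


def rsym_tensor(name: str, *indices: int) -> Expression:
    """A 2n-index tensor with the full n!·2^n real-orbital symmetry."""
    return _single(
        Term(1, tensors=(TensorRef(name, indices, TensorSymmetry.FULL_REAL),))
    )


def E(p: int, q: int) -> Expression:
    """The singlet one-electron excitation operator E_pq."""
    return _single(Term(1, operators=(SingletExcitation(p, q),)))


def e(p: int, q: int, r: int, s: int) -> Expression:
    """The two-electron singlet excitation operator
    ``e_pqrs = E_pq E_rs − δ_qr E_ps`` (an alias expansion, not an
    operator kind of its own)."""
    return _single(
        Term(1, operators=(SingletExcitation(p, q), SingletExcitation(r, s)))
    ) + _single(
        Term(
            -1,
            deltas=(frozenset((q, r)),),
            operators=(SingletExcitation(p, s),),
        )
    )


def tau(p: int, q: int) -> Expression:
    """The m_l = 0 triplet excitation operator
    ``τ_pq = a†_pα a_qα − a†_pβ a_qβ``."""
    return _single(Term(1, operators=(TripletExcitation(p, q),)))


def fermion(p: int, spin: int, dagger: bool = False) -> Expression:
    """An elementary spin-orbital annihilation (or creation) operator."""
    return _single(Term(1, operators=(SpinFermion(p, spin, dagger),)))


def boson(dagger: bool = False) -> Expression:
    """The photon annihilation (or creation) operator of the cavity mode."""
    return _single(Term(1, operators=(BosonOp(dagger),)))


def delta(*indices: int) -> Expression:
    """A Kronecker delta over two or more indices."""
    if len(set(indices)) < 2:
        raise ValueError("a Kronecker delta needs at least 2 distinct indices")
    return _single(Term(1, deltas=(frozenset(indices),)))


def constrain(space: OrbitalSpace, *indices: int) -> Expression:
    """An identity factor constraining ``indices`` to ``space``; multiply
    it into an expression to restrict the indices there."""
    return _single(Term(1, constraints={i: space for i in indices}))


def electron(*indices: int) -> Expression:
    """Constrain indices to the general electronic orbital space."""
    return constrain(GENERAL, *indices)


def occupied(*indices: int) -> Expression:
    """Constrain indices to the occupied orbital space."""
    return constrain(OCCUPIED, *indices)


def virtual(*indices: int) -> Expression:
    """Constrain indices to the virtual orbital space."""
    return constrain(VIRTUAL, *indices)


def summation(expr: Expression, *indices: int) -> Expression:
    """Sum an expression over the given indices (alias for
    ``expr.sum_over``)."""
    return expr.sum_over(*indices)


ONE_HALF = Fraction(1, 2)
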