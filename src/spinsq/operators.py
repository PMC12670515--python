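"""Second-quantization operator kinds and their pairwise commutation kernels.

Four operator kinds are implemented:

* :class:`SingletExcitation` ``E_pq = Σ_σ a†_pσ a_qσ`` — the spin-summed
  one-electron excitation operator.
* :class:`TripletExcitation` ``τ_pq = a†_pα a_qα − a†_pβ a_qβ`` — the
  m_l = 0 triplet excitation operator.
* :class:`SpinFermion` — elementary creation/annihilation operators for a
  spin orbital ``(p, σ)``.
* :class:`BosonOp` — photon ladder operators ``b``/``b†`` of a single
  cavity mode.

Each kind supplies three pieces of behaviour used by the expression
calculus:

1. a *reductive commutator kernel* against every other kind, returning
   ``[A,B]_Γ = AB + Γ·BA`` as a lower-rank expression fragment together
   with the sign ``Γ`` (``Γ = +1``, the anticommutator, exactly when both
   operators are elementary fermions; ``Γ = -1`` otherwise);
2. an ``act_on_ket`` base case against the closed-shell HF ⊗ photon-vacuum
   reference, which tightens index constraints and may drop the operator;
3. an excitation rank used to truncate projections (``E``, ``τ`` and ``b†``
   count one; an elementary fermion counts one half).

Kernels return *fragments* — bare ``(scalar, deltas, operators)`` triples —
rather than full terms; the expression layer grafts them into the
surrounding term context.
"""

from __future__ import annotations

from fractions import Fraction
from typing import NamedTuple

from . import config
from .spaces import OCCUPIED, VIRTUAL, OrbitalSpace

ALPHA = 0
BETA = 1

_ONE = Fraction(1)
_TWO = Fraction(2)


class Operator:
    """Base class for single second-quantization operators."""

    __slots__ = ()
    kind_rank: int = -1  # sort rank across kinds (comparison key only)

    @property
    def key(self) -> tuple:
        raise NotImplementedError

    @property
    def indices(self) -> tuple[int, ...]:
        return ()

    #: twice the excitation rank (kept integral for exact comparisons)
    rank2: int = 0

    def substitute(self, mapping: dict[int, int]) -> "Operator":
        return self

    def __eq__(self, other) -> bool:
        return type(other) is type(self) and other.key == self.key

    def __hash__(self) -> int:
        return hash(self.key)


class SingletExcitation(Operator):
    __slots__ = ("p", "q", "_key")
    kind_rank = 0
    rank2 = 2

    def __init__(self, p: int, q: int):
        self.p = p
        self.q = q
        self._key = (0, p, q)

    @property
    def key(self):
        return self._key

    @property
    def indices(self):
        return (self.p, self.q)

    def substitute(self, mapping):
        return SingletExcitation(
            mapping.get(self.p, self.p), mapping.get(self.q, self.q)
        )

    def __repr__(self):
        return f"E({self.p},{self.q})"


class TripletExcitation(Operator):
    __slots__ = ("p", "q", "_key")
    kind_rank = 1
    rank2 = 2

    def __init__(self, p: int, q: int):
        self.p = p
        self.q = q
        self._key = (1, p, q)

    @property
    def key(self):
        return self._key

    @property
    def indices(self):
        return (self.p, self.q)

    def substitute(self, mapping):
        return TripletExcitation(
            mapping.get(self.p, self.p), mapping.get(self.q, self.q)
        )

    def __repr__(self):
        return f"tau({self.p},{self.q})"


class SpinFermion(Operator):
    __slots__ = ("p", "spin", "dagger", "_key")
    kind_rank = 2
    rank2 = 1

    def __init__(self, p: int, spin: int, dagger: bool):
        if spin not in (ALPHA, BETA):
            raise ValueError("spin must be ALPHA (0) or BETA (1)")
        self.p = p
        self.spin = spin
        self.dagger = bool(dagger)
        self._key = (2, p, spin, self.dagger)

    @property
    def key(self):
        return self._key

    @property
    def indices(self):
        return (self.p,)

    def substitute(self, mapping):
        return SpinFermion(mapping.get(self.p, self.p), self.spin, self.dagger)

    def __repr__(self):
        sp = "a" if self.spin == ALPHA else "b"
        return f"a{'+' if self.dagger else '-'}({self.p},{sp})"


class BosonOp(Operator):
    __slots__ = ("dagger", "_key")
    kind_rank = 3
    rank2 = 2  # b† raises the excitation rank by one; b never survives a ket

    def __init__(self, dagger: bool):
        self.dagger = bool(dagger)
        self._key = (3, self.dagger)

    @property
    def key(self):
        return self._key

    def __repr__(self):
        return "b+" if self.dagger else "b-"


class Frag(NamedTuple):
    """A bare expression fragment: scalar × Kronecker deltas × operators."""

    scalar: Fraction
    deltas: tuple[frozenset[int], ...]
    ops: tuple[Operator, ...]


def _d(i: int, j: int) -> frozenset[int]:
    return frozenset((i, j))


class MissingKernelError(NotImplementedError):
    """Raised for an operator-kind pair without a commutator kernel.

    New operator kinds must register a kernel against every existing kind;
    the message names the missing entry as the extension point.
    """


def gamma_pair(a: Operator, b: Operator) -> int:
    """Sign Γ of the rank-reducing commutator for a kind pair: ``+1``
    (anticommutator) iff both are elementary fermions, else ``-1``."""
    if isinstance(a, SpinFermion) and isinstance(b, SpinFermion):
        return 1
    return -1


def string_gamma(ops: tuple[Operator, ...], b: Operator) -> int:
    """Γ for the reductive commutator of an operator string with a single
    operator, composed pairwise via Γ = -Γ₁Γ₂ (empty string: Γ = -1)."""
    g = -1
    for a in ops:
        g = -g * gamma_pair(a, b)
    # Equivalent closed form: (-1)**(len(ops)+1) * prod(pair gammas)
    return g


def kernel(a: Operator, b: Operator) -> tuple[list[Frag], int]:
    """Reductive commutator ``[a, b]_Γ`` of two single operators.

    Returns the commutator as a list of fragments of strictly lower total
    operator count than ``ab``, together with the sign ``Γ``.
    """
    config.stats.kernel_invocations += 1
    return _kernel_dispatch(a, b)


def _kernel_dispatch(a: Operator, b: Operator) -> tuple[list[Frag], int]:
    ka, kb = type(a), type(b)
    fn = _KERNELS.get((ka, kb))
    if fn is not None:
        return fn(a, b)
    fn = _KERNELS.get((kb, ka))
    if fn is not None:
        # [B,A]_Γ = Γ·[A,B]_Γ
        frags, g = fn(b, a)
        if g == 1:
            return frags, g
        return [Frag(-f.scalar, f.deltas, f.ops) for f in frags], g
    raise MissingKernelError(
        f"no commutator kernel for operator kinds "
        f"({ka.__name__}, {kb.__name__}); register one in "
        f"spinsq.operators._KERNELS"
    )


def _k_EE(a: SingletExcitation, b: SingletExcitation):
    # [E_pq, E_rs] = δ_qr E_ps − δ_ps E_rq
    p, q, r, s = a.p, a.q, b.p, b.q
    return [
        Frag(_ONE, (_d(q, r),), (SingletExcitation(p, s),)),
        Frag(-_ONE, (_d(p, s),), (SingletExcitation(r, q),)),
    ], -1


def _k_ET(a: SingletExcitation, b: TripletExcitation):
    # [E_pq, τ_rs] = δ_qr τ_ps − δ_ps τ_rq
    p, q, r, s = a.p, a.q, b.p, b.q
    return [
        Frag(_ONE, (_d(q, r),), (TripletExcitation(p, s),)),
        Frag(-_ONE, (_d(p, s),), (TripletExcitation(r, q),)),
    ], -1


def _k_TT(a: TripletExcitation, b: TripletExcitation):
    # [τ_pq, τ_rs] = δ_qr E_ps − δ_ps E_rq
    p, q, r, s = a.p, a.q, b.p, b.q
    return [
        Frag(_ONE, (_d(q, r),), (SingletExcitation(p, s),)),
        Frag(-_ONE, (_d(p, s),), (SingletExcitation(r, q),)),
    ], -1


def _k_EF(a: SingletExcitation, b: SpinFermion):
    p, q = a.p, a.q
    if b.dagger:
        # [E_pq, a†_rσ] = δ_qr a†_pσ
        return [
            Frag(_ONE, (_d(q, b.p),), (SpinFermion(p, b.spin, True),))
        ], -1
    # [E_pq, a_rσ] = −δ_pr a_qσ
    return [Frag(-_ONE, (_d(p, b.p),), (SpinFermion(q, b.spin, False),))], -1


def _k_TF(a: TripletExcitation, b: SpinFermion):
    # Expand τ_pq into spin fermions and recommute: the α part carries +1,
    # the β part −1, so only the branch matching b's spin survives.
    sgn = _ONE if b.spin == ALPHA else -_ONE
    p, q = a.p, a.q
    if b.dagger:
        return [Frag(sgn, (_d(q, b.p),), (SpinFermion(p, b.spin, True),))], -1
    return [Frag(-sgn, (_d(p, b.p),), (SpinFermion(q, b.spin, False),))], -1


def _k_FF(a: SpinFermion, b: SpinFermion):
    # {a_Pσ, a†_Qτ} = δ_PQ δ_στ ; {a,a} = {a†,a†} = 0
    if a.dagger != b.dagger and a.spin == b.spin:
        return [Frag(_ONE, (_d(a.p, b.p),), ())], 1
    return [], 1


def _k_BB(a: BosonOp, b: BosonOp):
    if not a.dagger and b.dagger:
        return [Frag(_ONE, (), ())], -1  # [b, b†] = 1
    if a.dagger and not b.dagger:
        return [Frag(-_ONE, (), ())], -1
    return [], -1


def _k_electronic_boson(a: Operator, b: BosonOp):
    return [], -1


_KERNELS = {
    (SingletExcitation, SingletExcitation): _k_EE,
    (SingletExcitation, TripletExcitation): _k_ET,
    (TripletExcitation, TripletExcitation): _k_TT,
    (SingletExcitation, SpinFermion): _k_EF,
    (TripletExcitation, SpinFermion): _k_TF,
    (SpinFermion, SpinFermion): _k_FF,
    (BosonOp, BosonOp): _k_BB,
    (SingletExcitation, BosonOp): _k_electronic_boson,
    (TripletExcitation, BosonOp): _k_electronic_boson,
    (SpinFermion, BosonOp): _k_electronic_boson,
}


class KetBranch(NamedTuple):
    """One surviving branch of an operator acting on the reference ket."""

    scalar: Fraction
    deltas: tuple[frozenset[int], ...]
    op: Operator | None
    constraints: tuple[tuple[int, OrbitalSpace], ...]


def act_on_ket_base(op: Operator) -> list[KetBranch]:
    """Base cases of the ``act_on_ket`` recursion: the image of a single
    operator applied to the closed-shell HF ⊗ photon-vacuum reference.

    ``E_pq`` splits into ``2δ_pq`` (p, q occupied) plus ``E_pq``
    (p virtual, q occupied); ``τ_pq`` survives only as a pure excitation;
    elementary fermions survive with the annihilated (created) orbital
    constrained occupied (virtual); ``b`` annihilates the vacuum.
    """
    if isinstance(op, SingletExcitation):
        p, q = op.p, op.q
        return [
            KetBranch(
                _TWO, (_d(p, q),), None, ((p, OCCUPIED), (q, OCCUPIED))
            ),
            KetBranch(_ONE, (), op, ((p, VIRTUAL), (q, OCCUPIED))),
        ]
    if isinstance(op, TripletExcitation):
        return [
            KetBranch(_ONE, (), op, ((op.p, VIRTUAL), (op.q, OCCUPIED)))
        ]
    if isinstance(op, SpinFermion):
        space = VIRTUAL if op.dagger else OCCUPIED
        return [KetBranch(_ONE, (), op, ((op.p, space),))]
    if isinstance(op, BosonOp):
        if op.dagger:
            return [KetBranch(_ONE, (), op, ())]
        return []
    raise MissingKernelError(
        f"no act_on_ket base case for operator kind {type(op).__name__}"
    )


def excitation_rank2(ops) -> int:
    """Twice the total excitation rank of an operator or operator string."""
    if isinstance(ops, Operator):
        return ops.rank2
    return sum(o.rank2 for o in ops)


def excitation_rank(ops) -> Fraction:
    """Excitation rank of an operator or string (fermions count one half)."""
    return Fraction(excitation_rank2(ops), 2)
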