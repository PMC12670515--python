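"""Expression-level calculus: commutators, BCH, reference projections.

The workhorse is the *reductive commutator* ``[A,B]_Γ = AB + Γ·BA`` with
``Γ`` chosen per operator pair so the result always has lower operator
rank (``Γ = +1``, the anticommutator, only for pairs of elementary
fermions).  Commutators of operator strings reduce to single-operator
kernels through

    [AB, C]_Γ = A[B,C]_Γ₁ − Γ₁·[A,C]_Γ₂ B,   Γ = −Γ₁Γ₂
    [A, BC]_Γ = [A,B]_Γ₁ C − Γ₁·B[A,C]_Γ₂,   Γ = −Γ₁Γ₂

splitting off the last operator of the left string and the first of the
right — a fixed, deterministic recursion schedule.  A commutator between
strings of lengths m and n invokes exactly m·n kernels.

Projections on the reference never normal-order: ``act_on_ket`` moves the
rightmost operator past the rest of the string,

    A₁…Aₙ|ref⟩ = −Γ·Ãₙ (A₁…Aₙ₋₁|ref⟩) + [A₁…Aₙ₋₁, Ãₙ]_Γ |ref⟩,

where ``Ãₙ`` is the operator's simplified image on the closed-shell
HF ⊗ photon-vacuum ket.  Terms left with no operators are the reference
expectation value; terms with k surviving excitations are the k-fold
excited block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import permutations as _permutations
from math import factorial
from typing import Iterable, Sequence

from . import config
from .operators import (
    BosonOp,
    Frag,
    Operator,
    SingletExcitation,
    SpinFermion,
    act_on_ket_base,
    excitation_rank,
    string_gamma,
    kernel,
)
from .spaces import GENERAL, OCCUPIED, VIRTUAL
from .terms import (
    Expression,
    Term,
    _as_expression,
    _substitute,
    canonicalize,
    combine_spaces,
    fuse_terms,
    multiply_terms,
    relabel_apart,
)

__all__ = [
    "commutator",
    "reductive_commutator_string",
    "bch_expand",
    "act_on_ket",
    "classify_by_rank",
    "hf_expectation",
    "PermutationGroup",
    "ProjectionError",
    "project_biorthogonal",
    "symmetrize",
    "BiorthoScaled",
    "biorthonormal_rescale",
    "clear_commutator_cache",
]


# ---------------------------------------------------------------------
# reductive commutator on operator strings
# ---------------------------------------------------------------------


def _fuse_frags(frags: Iterable[Frag]) -> list[Frag]:
    acc: dict[tuple, Frag] = {}
    for f in frags:
        if f.scalar == 0:
            continue
        key = (tuple(sorted(tuple(sorted(d)) for d in f.deltas)), f.ops)
        prev = acc.get(key)
        if prev is None:
            acc[key] = f
        else:
            s = prev.scalar + f.scalar
            if s == 0:
                del acc[key]
            else:
                acc[key] = Frag(s, prev.deltas, prev.ops)
    return list(acc.values())


def reductive_commutator_string(
    a: Sequence[Operator], b: Sequence[Operator]
) -> tuple[list[Frag], int]:
    """``[a, b]_Γ`` for two operator strings, as expression fragments.

    Bottoms out at single-operator kernels; a call with strings of
    lengths m and n performs exactly m·n kernel invocations.
    """
    a = tuple(a)
    b = tuple(b)
    if not a or not b:
        return [], -1
    if len(a) == 1 and len(b) == 1:
        return kernel(a[0], b[0])
    if len(a) > 1:
        head, last = a[:-1], a[-1]
        e1, g1 = reductive_commutator_string((last,), b)
        e2, g2 = reductive_commutator_string(head, b)
        out = [Frag(f.scalar, f.deltas, head + f.ops) for f in e1]
        out += [Frag(-g1 * f.scalar, f.deltas, f.ops + (last,)) for f in e2]
        return _fuse_frags(out), -g1 * g2
    first, tail = b[0], b[1:]
    e1, g1 = reductive_commutator_string(a, (first,))
    e2, g2 = reductive_commutator_string(a, tail)
    out = [Frag(f.scalar, f.deltas, f.ops + tail) for f in e1]
    out += [Frag(-g1 * f.scalar, f.deltas, (first,) + f.ops) for f in e2]
    return _fuse_frags(out), -g1 * g2


def _graft(
    term: Term,
    ops: tuple[Operator, ...],
    scalar: Fraction,
    deltas,
    constraints,
) -> Term | None:
    """Replace a term's operator string and fold in a fragment's scalar,
    deltas and constraints; canonicalize."""
    cons = dict(term.constraints)
    for i, sp in constraints:
        cons[i] = cons.get(i, GENERAL) & sp
    return canonicalize(
        Term(
            term.scalar * scalar,
            term.deltas + tuple(deltas),
            term.tensors,
            ops,
            term.sum_indices,
            cons,
        )
    )


# ---------------------------------------------------------------------
# commutator and BCH on expressions
# ---------------------------------------------------------------------

_COMM_CACHE: dict[tuple, tuple[tuple[Term, ...], int]] = {}


def clear_commutator_cache() -> None:
    _COMM_CACHE.clear()


def _term_commutator_unit(a: Term, b: Term) -> tuple[tuple[Term, ...], int]:
    """Plain commutator [a, b] of two terms with their scalars set to 1.

    Returns the canonical result terms and the number of kernel
    invocations it took (for cache-transparent instrumentation).
    """
    if not a.operators or not b.operators:
        return (), 0
    if a.body_key > b.body_key:
        # The recursion schedule leaves residual operator strings in an
        # orientation-dependent (though mathematically equivalent) order.
        # Computing the canonically oriented pair and negating makes
        # [a,b] and [b,a] exact symbolic negations, so antisymmetry
        # cancels term by term (and the memo cache is shared).
        terms, k = _term_commutator_unit(b, a)
        return tuple(t.with_scalar(-t.scalar) for t in terms), k
    k0 = config.stats.kernel_invocations
    a2, b2 = relabel_apart(a.with_scalar(1), b.with_scalar(1))
    frags, gamma = reductive_commutator_string(a2.operators, b2.operators)
    cons = dict(a2.constraints)
    ok = True
    for i, sp in b2.constraints.items():
        merged = cons.get(i, GENERAL) & sp
        cons[i] = merged
        if merged.is_empty:
            ok = False
    out: list[Term] = []
    if ok:
        for f in frags:
            t = canonicalize(
                Term(
                    f.scalar,
                    a2.deltas + b2.deltas + f.deltas,
                    a2.tensors + b2.tensors,
                    f.ops,
                    a2.sum_indices + b2.sum_indices,
                    cons,
                )
            )
            if t is not None:
                out.append(t)
    if gamma == 1:
        # Both strings have odd fermion parity: the reductive commutator is
        # the anticommutator, so the plain commutator needs [A,B]_+ − 2BA.
        prod = multiply_terms(b2, a2)
        if prod is not None:
            out.append(prod.with_scalar(prod.scalar * -2))
    return fuse_terms(out), config.stats.kernel_invocations - k0


def commutator(a, b) -> Expression:
    """The plain commutator ``[a, b] = ab − ba`` of two expressions,
    evaluated by bilinear expansion and reductive rank-lowering."""
    a = _as_expression(a)
    b = _as_expression(b)
    memo = config.settings.memoize_commutators
    out: list[Term] = []
    for ta in a:
        for tb in b:
            if memo:
                key = (ta.body_key, tb.body_key)
                hit = _COMM_CACHE.get(key)
                if hit is None:
                    hit = _term_commutator_unit(ta, tb)
                    _COMM_CACHE[key] = hit
                else:
                    # count the kernels this commutator stands for
                    config.stats.kernel_invocations += hit[1]
                terms, _ = hit
            else:
                terms, _ = _term_commutator_unit(ta, tb)
            s = ta.scalar * tb.scalar
            out.extend(t.with_scalar(t.scalar * s) for t in terms)
    return Expression(combine_spaces(out), _canonical=True)


def bch_expand(a, b, order: int) -> Expression:
    """Baker–Campbell–Hausdorff expansion of ``e^{-b} a e^{b}`` through
    the given nesting order:

        a + [a,b] + 1/2 [[a,b],b] + ... + 1/order! [...[a,b],...,b]

    Stops early when a nested commutator vanishes identically.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    a = _as_expression(a)
    b = _as_expression(b)
    total = a
    nested = a
    for k in range(1, order + 1):
        nested = commutator(nested, b)
        if nested.is_zero:
            break
        total = total + nested.scale(Fraction(1, factorial(k)))
    return total


# ---------------------------------------------------------------------
# act_on_ket
# ---------------------------------------------------------------------


def act_on_ket(a, max_rank=None) -> Expression:
    """Apply an expression to the reference ket, recursively simplifying.

    Every term of the result is a string of reference-simplified operators
    (pure excitations, constrained fermions, photon creations) acting on
    the reference; branches whose surviving excitation rank exceeds
    ``max_rank`` are discarded at every intermediate step.
    """
    a = _as_expression(a)
    cap2 = None if max_rank is None else int(2 * Fraction(max_rank))
    out: list[Term] = []
    for t in a:
        out.extend(_act(t, len(t.operators), cap2))
    return Expression(combine_spaces(out), _canonical=True)


def _act(term: Term | None, n_pending: int, cap2) -> tuple[Term, ...]:
    if term is None:
        return ()
    if n_pending == 0:
        return (term,)
    ops = term.operators
    op = ops[n_pending - 1]
    prefix = ops[: n_pending - 1]
    emitted = ops[n_pending:]
    emitted_r2 = sum(x.rank2 for x in emitted)
    out: list[Term] = []
    for br in act_on_ket_base(op):
        if br.op is None:
            t2 = _graft(
                term, prefix + emitted, br.scalar, br.deltas, br.constraints
            )
            out.extend(_act(t2, n_pending - 1, cap2))
            continue
        if cap2 is None or emitted_r2 + br.op.rank2 <= cap2:
            g = string_gamma(prefix, br.op)
            t1 = _graft(
                term,
                prefix + (br.op,) + emitted,
                -g * br.scalar,
                br.deltas,
                br.constraints,
            )
            out.extend(_act(t1, n_pending - 1, cap2))
        if prefix:
            frags, _gamma = reductive_commutator_string(prefix, (br.op,))
            for f in frags:
                t2 = _graft(
                    term,
                    f.ops + emitted,
                    br.scalar * f.scalar,
                    br.deltas + f.deltas,
                    br.constraints,
                )
                out.extend(_act(t2, len(f.ops), cap2))
    return fuse_terms(out)


def classify_by_rank(a: Expression) -> dict[Fraction, Expression]:
    """Split an acted expression by surviving excitation rank.

    The rank-0 component is the reference expectation value of the input.
    """
    buckets: dict[Fraction, list[Term]] = {}
    for t in a:
        buckets.setdefault(excitation_rank(t.operators), []).append(t)
    return {
        r: Expression(fuse_terms(ts), _canonical=True)
        for r, ts in sorted(buckets.items())
    }


def hf_expectation(a) -> Expression:
    """Reference expectation value ⟨ref| a |ref⟩ (the rank-0 component of
    the acted expression)."""
    return act_on_ket(a, max_rank=0)


# ---------------------------------------------------------------------
# biorthogonal projection
# ---------------------------------------------------------------------


class ProjectionError(ValueError):
    pass


@dataclass(frozen=True)
class PermutationGroup:
    """The permutation group over excitation pairs (a₁,i₁)…(aₙ,iₙ) used by
    biorthogonal doubles/triples projections; order n!."""

    pair_list: tuple[tuple[int, int], ...]

    def __init__(self, pairs: Iterable[tuple[int, int]]):
        object.__setattr__(self, "pair_list", tuple(tuple(p) for p in pairs))

    @property
    def order(self) -> int:
        return factorial(len(self.pair_list))

    def mappings(self) -> list[dict[int, int]]:
        """Index substitutions realizing every permutation of the pairs
        (identity included)."""
        out = []
        for perm in _permutations(range(len(self.pair_list))):
            m: dict[int, int] = {}
            for k, j in enumerate(perm):
                (a1, i1), (a2, i2) = self.pair_list[k], self.pair_list[j]
                if a1 != a2:
                    m[a1] = a2
                if i1 != i2:
                    m[i1] = i2
            out.append(m)
        return out


def _template_pairs(template) -> tuple[tuple[int, int], ...]:
    if isinstance(template, Expression):
        if len(template) != 1:
            raise ProjectionError("template ket must be a single term")
        (t,) = template
        pairs = []
        for o in t.operators:
            if not isinstance(o, SingletExcitation):
                raise ProjectionError(
                    "template ket must be a product of E_ai operators"
                )
            pairs.append((o.p, o.q))
        return tuple(pairs)
    return tuple(tuple(p) for p in template)


def project_biorthogonal(a, template, n_bosons: int = 0) -> Expression:
    """Project an acted expression on the biorthogonal bra defined by a
    template ket of singlet excitations.

    Terms whose excitation structure does not match the template's rank or
    photon number belong to other blocks and are dropped.  Each selected
    term's k-th surviving excitation ``E_ck`` is contracted against the
    template's k-th pair (a, i) through the biorthogonality deltas
    ``δ_ac δ_ik``; for doubles and higher the caller applies
    :func:`symmetrize` over the template pairs to realize the permutation
    sum of the biorthogonality condition.
    """
    a = _as_expression(a)
    pairs = _template_pairs(template)
    if n_bosons > 1:
        raise ProjectionError(
            "photon-number projections are implemented for 0 and 1 photons"
        )
    out: list[Term] = []
    for t in a:
        exc = [o for o in t.operators if isinstance(o, SingletExcitation)]
        bosons = [o for o in t.operators if isinstance(o, BosonOp)]
        others = [
            o
            for o in t.operators
            if not isinstance(o, (SingletExcitation, BosonOp))
        ]
        if len(bosons) != n_bosons:
            continue
        rank = excitation_rank(
            [o for o in t.operators if not isinstance(o, BosonOp)]
        )
        if rank != len(pairs):
            continue
        if others:
            raise ProjectionError(
                "term of matching excitation rank carries operators that "
                "the E_ai template cannot contract"
            )
        # keep template ordinals free of the term's index ranges
        tmpl_idx = {i for p in pairs for i in p}
        top = max(t.all_indices() | tmpl_idx, default=0)
        shift = {s: top + 1 + k for k, s in enumerate(t.sum_indices)}
        t2 = _substitute(t, shift)
        exc2 = [o for o in t2.operators if isinstance(o, SingletExcitation)]
        deltas = list(t2.deltas)
        for (av, io), o in zip(pairs, exc2):
            deltas.append(frozenset((av, o.p)))
            deltas.append(frozenset((io, o.q)))
        cons = dict(t2.constraints)
        for av, io in pairs:
            cons[av] = cons.get(av, GENERAL) & VIRTUAL
            cons[io] = cons.get(io, GENERAL) & OCCUPIED
        res = canonicalize(
            Term(
                t2.scalar,
                tuple(deltas),
                t2.tensors,
                (),
                t2.sum_indices,
                cons,
            )
        )
        if res is not None:
            out.append(res)
    return Expression(combine_spaces(out), _canonical=True)


def symmetrize(a, group: PermutationGroup) -> Expression:
    """Sum an expression over all permutations of the group's index pairs.

    The pair indices must be free in every term.
    """
    a = _as_expression(a)
    idx = {i for p in group.pair_list for i in p}
    for t in a:
        summed = idx & set(t.sum_indices)
        if summed:
            raise ValueError(
                f"pair indices {sorted(summed)} are summation indices; "
                "symmetrize needs free indices"
            )
    out: list[Term] = []
    for m in group.mappings():
        for t in a:
            c = canonicalize(_substitute(t, m))
            if c is not None:
                out.append(c)
    return Expression(combine_spaces(out), _canonical=True)


@dataclass
class BiorthoScaled:
    """A biorthogonal-bra residual annotated with the diagonal
    biorthonormalization factor 1/(1 + δ_ij δ_ab).

    The factor is stored symbolically and applied numerically by the code
    generator; re-scaling an already scaled result is rejected.
    """

    expression: Expression
    group: PermutationGroup


def biorthonormal_rescale(a, group: PermutationGroup) -> BiorthoScaled:
    if isinstance(a, BiorthoScaled):
        raise ValueError("expression is already biorthonormally rescaled")
    if len(group.pair_list) != 2:
        raise ValueError(
            "the 1/(1+δδ) diagonal rescaling is defined for the doubles "
            "block (two excitation pairs)"
        )
    return BiorthoScaled(_as_expression(a), group)
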