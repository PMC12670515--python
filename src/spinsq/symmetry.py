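"""Tensor pattern replacements and permutation-symmetry splitting.

Two recurring simplifications of derived coupled-cluster expressions live
here:

* :func:`look_for_tensor_replacements` recognizes the ``2X − X^T``
  pattern and rewrites it with a combination tensor, e.g.
  ``L_pqrs = 2g_pqrs − g_psrq`` for two-electron integrals and
  ``u_aibj = 2t_aibj − t_ajbi`` for doubles amplitudes.
* :func:`desymmetrize` splits a pair-permutation-symmetric expression
  into a minimal representative set (to be re-symmetrized numerically),
  the terms that are themselves symmetric, and any leftovers that have
  neither a mirror partner nor self-symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .algebra import PermutationGroup
from .tensors import TensorRef, TensorSymmetry, canonical_sort_tensor, symmetry_orbit
from .terms import Expression, Term, _substitute, canonicalize, fuse_terms

__all__ = [
    "TensorSymmetry",
    "canonical_sort_tensor",
    "symmetry_orbit",
    "ReplacementRule",
    "L_RULE",
    "U_RULE",
    "look_for_tensor_replacements",
    "expand_replacements",
    "desymmetrize",
]


@dataclass(frozen=True)
class ReplacementRule:
    """Rewrite ``2·source_X − source_{T(X)}`` as ``target_X``.

    ``transposition`` permutes the source tensor's slots: slot ``k`` of
    the transposed tensor reads index ``transposition[k]`` of the
    original, e.g. ``(0, 3, 2, 1)`` swaps the second and fourth indices
    (``g_pqrs → g_psrq``).
    """

    target_name: str
    source_name: str
    transposition: tuple[int, ...]
    symmetry: TensorSymmetry = TensorSymmetry.PAIR_PERMUTATION

    @property
    def arity(self) -> int:
        return len(self.transposition)

    def transpose_indices(self, indices: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(indices[k] for k in self.transposition)


#: L_pqrs = 2 g_pqrs − g_psrq
L_RULE = ReplacementRule("L", "g", (0, 3, 2, 1))
#: u_aibj = 2 t_aibj − t_ajbi
U_RULE = ReplacementRule("u", "t", (0, 3, 2, 1))


def exchange_rule(n_pairs: int, source: str = "t") -> ReplacementRule:
    """The ``2X − X^T`` exchange combination for a 2n-index amplitude,
    transposing the occupied slots of the last two index pairs
    (``u_aibj = 2t_aibj − t_ajbi`` at n = 2 and its higher-rank
    analogues, e.g. ``2t_aibjck − t_aibkcj`` at n = 3).

    Under pair-permutation symmetry this one transposition captures every
    occupied-swap pattern, since any other pair choice is conjugate to it
    by a pure pair permutation."""
    arity = 2 * n_pairs
    perm = list(range(arity))
    perm[arity - 3], perm[arity - 1] = perm[arity - 1], perm[arity - 3]
    name = "u" if n_pairs == 2 else f"u{n_pairs}"
    return ReplacementRule(name, source, tuple(perm))


def _transposed_candidate(t: Term, pos: int, rule: ReplacementRule):
    """Term ``t`` with tensor ``pos`` index-transposed and scalar −s/2:
    what the mirror partner of a ``2:−1`` pair must look like."""
    src = t.tensors[pos]
    swapped = TensorRef(
        src.name, rule.transpose_indices(src.indices), src.symmetry
    )
    tensors = t.tensors[:pos] + (swapped,) + t.tensors[pos + 1 :]
    return canonicalize(
        Term(
            -t.scalar / 2,
            t.deltas,
            tensors,
            t.operators,
            t.sum_indices,
            t.constraints,
        )
    )


def _replaced(t: Term, pos: int, rule: ReplacementRule, scalar) -> Term:
    src = t.tensors[pos]
    tgt = TensorRef(rule.target_name, src.indices, rule.symmetry)
    tensors = t.tensors[:pos] + (tgt,) + t.tensors[pos + 1 :]
    return canonicalize(
        Term(scalar, t.deltas, tensors, t.operators, t.sum_indices, t.constraints)
    )


def look_for_tensor_replacements(a: Expression, rule: ReplacementRule) -> Expression:
    """Rewrite ``2:−1`` pairs (and exactly self-matching single terms)
    with the rule's combination tensor.

    The search is greedy over the canonically sorted term list: for each
    term, the first partner that is identical up to the stated index
    transposition and a ``2:−1`` scalar ratio is consumed.  Newly created
    terms re-enter the search, so chains of replacements resolve in one
    call.  Terms without a match pass through unchanged.
    """
    pool: dict[tuple, Term] = {t.body_key: t for t in a}

    def _add(term: Term | None) -> None:
        if term is None:
            return
        prev = pool.get(term.body_key)
        if prev is not None:
            s = prev.scalar + term.scalar
            if s == 0:
                del pool[term.body_key]
            else:
                pool[term.body_key] = prev.with_scalar(s)
        else:
            pool[term.body_key] = term

    changed = True
    while changed:
        changed = False
        for key in sorted(pool):
            t = pool.get(key)
            if t is None:
                continue
            for pos, ref in enumerate(t.tensors):
                if (
                    ref.name != rule.source_name
                    or len(ref.indices) != rule.arity
                ):
                    continue
                cand = _transposed_candidate(t, pos, rule)
                if cand is None:
                    continue
                if cand.body_key == t.body_key:
                    # Self-matching: Σ source_{T(X)}·R ≡ Σ source_X·R, so
                    # the combination tensor reproduces the term with an
                    # unchanged scalar (2X − X^T contracts back to X).
                    del pool[key]
                    _add(_replaced(t, pos, rule, t.scalar))
                    changed = True
                    break
                partner = pool.get(cand.body_key)
                if partner is None or partner.scalar != cand.scalar:
                    continue
                del pool[key]
                del pool[cand.body_key]
                _add(_replaced(t, pos, rule, t.scalar / 2))
                changed = True
                break
            if changed:
                break
    return Expression(fuse_terms(pool.values()), _canonical=True)


def expand_replacements(a: Expression, rule: ReplacementRule) -> Expression:
    """Inverse of :func:`look_for_tensor_replacements`: expand every
    target tensor back into ``2·source − source^T``."""
    out: list[Term] = []
    for t in a:
        stack = [t]
        while stack:
            cur = stack.pop()
            pos = next(
                (
                    k
                    for k, ref in enumerate(cur.tensors)
                    if ref.name == rule.target_name
                    and len(ref.indices) == rule.arity
                ),
                None,
            )
            if pos is None:
                out.append(cur)
                continue
            ref = cur.tensors[pos]
            # source and target share the rule's symmetry class
            direct = TensorRef(rule.source_name, ref.indices, rule.symmetry)
            swapped = TensorRef(
                rule.source_name, rule.transpose_indices(ref.indices), rule.symmetry
            )
            for scal, new_ref in ((2 * cur.scalar, direct), (-cur.scalar, swapped)):
                nt = canonicalize(
                    Term(
                        scal,
                        cur.deltas,
                        cur.tensors[:pos] + (new_ref,) + cur.tensors[pos + 1 :],
                        cur.operators,
                        cur.sum_indices,
                        cur.constraints,
                    )
                )
                if nt is not None:
                    stack.append(nt)
    return Expression(fuse_terms(out), _canonical=True)


def desymmetrize(
    a: Expression, group: PermutationGroup
) -> tuple[Expression, Expression, Expression]:
    """Split a (nominally) pair-permutation-symmetric expression into
    ``(redundant, self_symmetric, leftover)``.

    * ``redundant``: one representative per mirror orbit, scaled so that
      ``symmetrize(redundant, group)`` restores the orbit;
    * ``self_symmetric``: terms invariant under every permutation;
    * ``leftover``: terms with neither a partner nor invariance (ideally
      empty for a truly symmetric input, but replacement tensors can hide
      the symmetry).

    Reconstruction identity:
    ``symmetrize(redundant) + self_symmetric + leftover == a``.
    """
    mappings = group.mappings()
    idx = {i for p in group.pair_list for i in p}
    for t in a:
        summed = idx & set(t.sum_indices)
        if summed:
            raise ValueError(
                f"pair indices {sorted(summed)} are summation indices; "
                "desymmetrize needs free indices"
            )
    pool: dict[tuple, Term] = {t.body_key: t for t in a}
    order = [t.body_key for t in a]
    red: list[Term] = []
    selfsym: list[Term] = []
    leftover: list[Term] = []
    for key in order:
        t = pool.pop(key, None)
        if t is None:
            continue
        images: dict[tuple, Term] = {}
        for m in mappings:
            c = canonicalize(_substitute(t, m))
            images[c.body_key] = c
        if set(images) == {t.body_key}:
            selfsym.append(t)
            continue
        stab = group.order // len(images)
        partners = []
        complete = True
        for bk in images:
            if bk == t.body_key:
                continue
            p = pool.get(bk)
            if p is None or p.scalar != t.scalar:
                complete = False
                break
            partners.append(bk)
        if complete:
            for bk in partners:
                del pool[bk]
            rep_key = min(images)
            red.append(
                images[rep_key].with_scalar(t.scalar * Fraction(1, stab))
            )
        else:
            leftover.append(t)
    return (
        Expression(fuse_terms(red), _canonical=True),
        Expression(fuse_terms(selfsym), _canonical=True),
        Expression(fuse_terms(leftover), _canonical=True),
    )
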