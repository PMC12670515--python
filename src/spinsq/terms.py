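"""Terms, expressions and canonical simplification.

A :class:`Term` is ``scalar × (Kronecker deltas) × (tensors) × (ordered
operator string)``, together with the list of summed indices and a map of
index-space constraints.  An :class:`Expression` is a sorted, fused
collection of terms; the empty expression represents zero.

Scalars are exact rationals throughout — floating point is rejected so
that equal terms cancel exactly.

Canonicalization is the heart of the module.  ``canonicalize`` drives a
term to a unique normal form through

1. merging overlapping deltas (equality is transitive),
2. resolving deltas against summation indices (substituting the index
   through the term and intersecting space constraints; a delta over
   disjoint spaces annihilates the term),
3. renaming free indices that share a delta to the delta's lowest index,
4. relabelling summation indices to the lowest unused ordinals, and
5. choosing, among the permutations of interchangeable summation indices,
   the labelling that minimizes the term's lexicographic key (tensor
   symmetries are re-applied for every candidate).

Step 5 scales factorially, so indices are first partitioned into
*interchangeability cells* by iterated structural refinement (a
Weisfeiler–Lehman-style colouring over the tensors, deltas and operator
slots an index occupies).  Indices in different cells cannot be confused
by any relabelling, so only permutations within cells are enumerated.
Above the configured cap a deterministic first-occurrence fallback is used
and a warning is emitted.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from itertools import permutations, product
from math import factorial
from typing import Iterable, Iterator

from . import config
from .operators import Operator
from .spaces import GENERAL, OrbitalSpace
from .tensors import TensorRef

Scalar = Fraction


class PermutationCapExceeded(UserWarning):
    """Permutation search hit the cap; a greedy non-canonical labelling
    was used for one term."""


def as_scalar(value) -> Fraction:
    """Coerce a scalar to an exact rational, rejecting floats."""
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        raise TypeError(
            "floating-point scalars are not supported: round-off breaks "
            "exact cancellation of terms; use fractions.Fraction or int"
        )
    raise TypeError(f"unsupported scalar type {type(value).__name__}")


class Term:
    """One term of an expression.  Instances are immutable; use
    :func:`canonicalize` (or the Expression layer, which applies it) after
    any structural edit."""

    __slots__ = (
        "scalar",
        "deltas",
        "tensors",
        "operators",
        "sum_indices",
        "constraints",
        "_body_key",
        "_hash",
    )

    def __init__(
        self,
        scalar,
        deltas: Iterable[frozenset[int]] = (),
        tensors: Iterable[TensorRef] = (),
        operators: Iterable[Operator] = (),
        sum_indices: Iterable[int] = (),
        constraints: dict[int, OrbitalSpace] | None = None,
    ):
        self.scalar = as_scalar(scalar)
        # a delta whose indices coincide is trivially true and dropped
        self.deltas = tuple(
            fs for fs in (frozenset(d) for d in deltas) if len(fs) >= 2
        )
        self.tensors = tuple(tensors)
        self.operators = tuple(operators)
        self.sum_indices = tuple(sorted(set(sum_indices)))
        cons = {}
        if constraints:
            for i, sp in constraints.items():
                # Constraints to the general space are implicit and dropped;
                # an empty space is kept so canonicalization can report the
                # term as zero.
                if sp is not GENERAL:
                    cons[i] = sp
        self.constraints = cons
        self._body_key = None
        self._hash = None

    # -- structure ----------------------------------------------------

    def body_indices(self) -> set[int]:
        """All indices occurring in deltas, tensors or operators."""
        out: set[int] = set()
        for d in self.deltas:
            out |= d
        for t in self.tensors:
            out.update(t.indices)
        for o in self.operators:
            out.update(o.indices)
        return out

    def all_indices(self) -> set[int]:
        return self.body_indices() | set(self.sum_indices) | set(self.constraints)

    def free_indices(self) -> set[int]:
        return self.all_indices() - set(self.sum_indices)

    def space_of(self, index: int) -> OrbitalSpace:
        return self.constraints.get(index, GENERAL)

    @property
    def body_key(self) -> tuple:
        """Total-order key over everything but the scalar: (operator
        string, tensors, deltas, constraints, summation indices)."""
        key = self._body_key
        if key is None:
            key = _body_key(
                self.operators,
                self.tensors,
                self.deltas,
                self.constraints,
                self.sum_indices,
            )
            self._body_key = key
        return key

    def with_scalar(self, scalar) -> "Term":
        t = Term.__new__(Term)
        t.scalar = as_scalar(scalar)
        t.deltas = self.deltas
        t.tensors = self.tensors
        t.operators = self.operators
        t.sum_indices = self.sum_indices
        t.constraints = self.constraints
        t._body_key = self._body_key
        t._hash = None
        return t

    def substitute_free(self, mapping: dict[int, int]) -> "Term":
        """Simultaneously rename free indices (canonicalizing afterwards).

        Raises if a renamed index is a summation index of the term.
        """
        bad = set(mapping) & set(self.sum_indices)
        if bad:
            raise ValueError(f"indices {sorted(bad)} are summed, not free")
        return canonicalize(_substitute(self, mapping))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Term)
            and self.scalar == other.scalar
            and self.body_key == other.body_key
        )

    def __hash__(self) -> int:
        h = self._hash
        if h is None:
            h = hash((self.scalar, self.body_key))
            self._hash = h
        return h

    def __repr__(self) -> str:
        from .render import render_term

        return f"Term[{render_term(self)}]"


def _body_key(operators, tensors, deltas, constraints, sum_indices) -> tuple:
    return (
        tuple(o.key for o in operators),
        tuple(t.key for t in tensors),
        tuple(sorted(tuple(sorted(d)) for d in deltas)),
        tuple(sorted((i, sp.mask) for i, sp in constraints.items())),
        len(sum_indices),
        tuple(sum_indices),
    )


def _substitute(term: Term, mapping: dict[int, int]) -> Term:
    """Raw simultaneous index substitution (no canonicalization)."""
    if not mapping:
        return term
    cons: dict[int, OrbitalSpace] = {}
    for i, sp in term.constraints.items():
        j = mapping.get(i, i)
        prev = cons.get(j, GENERAL)
        cons[j] = prev & sp
    return Term(
        term.scalar,
        tuple(frozenset(mapping.get(i, i) for i in d) for d in term.deltas),
        tuple(t.substitute(mapping) for t in term.tensors),
        tuple(o.substitute(mapping) for o in term.operators),
        tuple(mapping.get(i, i) for i in term.sum_indices),
        cons,
    )


# ---------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------


def _merge_deltas(
    deltas: tuple[frozenset[int], ...]
) -> list[set[int]]:
    """Union-find merge of overlapping deltas (equality is transitive)."""
    groups: list[set[int]] = []
    for d in deltas:
        d = set(d)
        hits = [g for g in groups if g & d]
        for g in hits:
            d |= g
            groups.remove(g)
        groups.append(d)
    return groups


def resolve_deltas(term: Term) -> Term | None:
    """Substitute summation indices appearing in deltas through the term.

    Returns ``None`` for the zero term (a delta over indices whose
    constrained spaces have empty intersection).  Surviving delta members
    carry the intersected space constraint.
    """
    groups = _merge_deltas(term.deltas)
    if not groups:
        return term
    sums = set(term.sum_indices)
    mapping: dict[int, int] = {}
    new_deltas: list[frozenset[int]] = []
    new_cons = dict(term.constraints)
    for g in groups:
        space = GENERAL
        for i in g:
            space = space & term.constraints.get(i, GENERAL)
        if space.is_empty:
            return None
        free = g - sums
        rep = min(free) if free else min(g)
        for i in g:
            if i in sums and i != rep:
                mapping[i] = rep
        survivors = free if free else {rep}
        for i in survivors:
            if space is GENERAL:
                new_cons.pop(i, None)
            else:
                new_cons[i] = space
        if len(survivors) >= 2:
            new_deltas.append(frozenset(survivors))
        # constraints of substituted-away members are folded into `space`
        for i in g - survivors:
            new_cons.pop(i, None)
    # apply the substitution everywhere
    t = Term(
        term.scalar,
        tuple(new_deltas),
        term.tensors,
        term.operators,
        tuple(i for i in term.sum_indices if i not in mapping),
        new_cons,
    )
    return _substitute(t, mapping) if mapping else t


def rename_delta_indices(term: Term) -> Term:
    """Rename, outside the delta itself, every index sharing a (free)
    delta to the delta's lowest index."""
    if not term.deltas:
        return term
    mapping: dict[int, int] = {}
    for d in term.deltas:
        rep = min(d)
        for i in d:
            if i != rep:
                mapping[i] = rep
    if not mapping:
        return term
    # substitute in tensors/operators only; deltas and constraints keep
    # their members (the constraint of a renamed index also applies to the
    # representative via the delta, so fold it in).
    cons: dict[int, OrbitalSpace] = {}
    for i, sp in term.constraints.items():
        cons[i] = cons.get(i, GENERAL) & sp
        j = mapping.get(i)
        if j is not None:
            cons[j] = cons.get(j, GENERAL) & sp
    return Term(
        term.scalar,
        term.deltas,
        tuple(t.substitute(mapping) for t in term.tensors),
        tuple(o.substitute(mapping) for o in term.operators),
        term.sum_indices,
        cons,
    )


def _occurrence_colors(term: Term) -> dict[int, tuple]:
    """Initial structural colour of every index: its space plus the
    multiset of symmetry-invariant slots it occupies."""
    occ: dict[int, list] = {i: [] for i in term.all_indices()}
    for t in term.tensors:
        n = len(t.indices)
        for slot, i in enumerate(t.indices):
            if t.symmetry == 0:
                slot_cls = slot
            elif t.symmetry == 1:
                slot_cls = slot % 2
            else:
                slot_cls = -1
            occ[i].append(("T", t.name, n, int(t.symmetry), slot_cls))
    for d in term.deltas:
        for i in d:
            occ[i].append(("D", len(d)))
    for pos, o in enumerate(term.operators):
        for slot, i in enumerate(o.indices):
            occ[i].append(("O", pos, o.key[0], slot))
    sums = set(term.sum_indices)
    colors: dict[int, tuple] = {}
    for i, lst in occ.items():
        base = ("S", term.space_of(i).mask) if i in sums else ("F", i)
        colors[i] = (base, tuple(sorted(lst)))
    return colors


def _refine_colors(term: Term, colors: dict[int, tuple]) -> dict[int, tuple]:
    """One round of colour refinement over shared tensors/deltas/operators."""
    new: dict[int, list] = {i: [] for i in colors}
    for t in term.tensors:
        cs = tuple(sorted(repr(colors[j]) for j in t.indices))
        for i in t.indices:
            new[i].append(("T", t.name, cs))
    for d in term.deltas:
        cs = tuple(sorted(repr(colors[j]) for j in d))
        for i in d:
            new[i].append(("D", cs))
    for pos, o in enumerate(term.operators):
        cs = tuple(repr(colors[j]) for j in o.indices)
        for i in o.indices:
            new[i].append(("O", pos, cs))
    return {i: (colors[i], tuple(sorted(new[i]))) for i in colors}


def _interchangeability_cells(term: Term) -> list[list[int]]:
    """Partition summation indices into cells that structural invariants
    cannot distinguish; cells are canonically ordered."""
    sums = set(term.sum_indices)
    if not sums:
        return []
    colors = _occurrence_colors(term)
    prev_partition = None
    for _ in range(4):
        partition = frozenset(
            frozenset(g)
            for g in _group_by_color(sums, colors).values()
        )
        if all(len(g) == 1 for g in partition) or partition == prev_partition:
            break
        prev_partition = partition
        colors = _refine_colors(term, colors)
    groups = _group_by_color(sums, colors)
    return [sorted(g) for _, g in sorted(groups.items())]


def _group_by_color(sums, colors) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i in sums:
        groups.setdefault(repr(colors[i]), []).append(i)
    return groups


def _candidate_key(term: Term, mapping: dict[int, int]) -> tuple:
    """Body key of the term under an index relabelling (tensor symmetry
    re-applied, lists re-sorted)."""
    tensors = tuple(
        sorted((t.substitute(mapping) for t in term.tensors), key=lambda t: t.key)
    )
    deltas = tuple(frozenset(mapping.get(i, i) for i in d) for d in term.deltas)
    ops = tuple(o.substitute(mapping) for o in term.operators)
    cons = {}
    for i, sp in term.constraints.items():
        cons[mapping.get(i, i)] = sp
    sums = tuple(sorted(mapping.get(i, i) for i in term.sum_indices))
    return _body_key(ops, tensors, deltas, cons, sums)


def reorder_summation_indices(term: Term) -> Term:
    """Relabel summation indices to the lowest unused ordinals, choosing
    among interchangeable indices the permutation that minimizes the
    term's lexicographic key.

    Ties are broken by the first permutation found in lexicographic
    enumeration order.  Above the configured permutation cap, a greedy
    first-occurrence ordering is used and a warning is emitted.
    """
    sums = term.sum_indices
    if not sums:
        return _rebuild_sorted(term, {})
    free = term.free_indices()
    targets: list[int] = []
    n = 1
    while len(targets) < len(sums):
        if n not in free:
            targets.append(n)
        n += 1
    # Tier 1: full enumeration within each orbital-space group gives the
    # true lexicographic minimum; used whenever small enough.
    space_groups: dict[int, list[int]] = {}
    for i in sums:
        space_groups.setdefault(term.space_of(i).mask, []).append(i)
    full_count = 1
    for g in space_groups.values():
        full_count *= factorial(len(g))
    if full_count <= config.settings.exact_permutation_cap:
        cells = [sorted(g) for _, g in sorted(space_groups.items())]
    else:
        # Tier 2: only permutations within structural interchangeability
        # cells can affect the key's minimum candidates meaningfully;
        # deterministic and invariant under relabelling.
        cells = _interchangeability_cells(term)
    # assign a contiguous block of target ordinals to each cell
    blocks: list[list[int]] = []
    k = 0
    for cell in cells:
        blocks.append(targets[k : k + len(cell)])
        k += len(cell)
    n_candidates = 1
    for cell in cells:
        n_candidates *= factorial(len(cell))
    if n_candidates > config.settings.permutation_cap:
        config.stats.permutation_cap_hits += 1
        warnings.warn(
            f"permutation search cap exceeded ({n_candidates} candidates); "
            "using greedy first-occurrence ordering (term flagged "
            "non-canonical)",
            PermutationCapExceeded,
            stacklevel=2,
        )
        mapping = _greedy_mapping(term, cells, blocks)
        return _rebuild_sorted(term, mapping)
    best_key = None
    best_mapping = None
    for combo in product(*(permutations(cell) for cell in cells)):
        config.stats.permutations_enumerated += 1
        mapping = {}
        for perm, block in zip(combo, blocks):
            for old, new in zip(perm, block):
                mapping[old] = new
        key = _candidate_key(term, mapping)
        if best_key is None or key < best_key:
            best_key = key
            best_mapping = mapping
    return _rebuild_sorted(term, best_mapping)


def _greedy_mapping(term, cells, blocks) -> dict[int, int]:
    """Deterministic fallback: order each cell by first occurrence in the
    term body scan (operators, then tensors, then deltas)."""
    order: dict[int, int] = {}
    pos = 0
    for o in term.operators:
        for i in o.indices:
            order.setdefault(i, pos)
            pos += 1
    for t in term.tensors:
        for i in t.indices:
            order.setdefault(i, pos)
            pos += 1
    for d in term.deltas:
        for i in sorted(d):
            order.setdefault(i, pos)
            pos += 1
    mapping = {}
    for cell, block in zip(cells, blocks):
        for old, new in zip(
            sorted(cell, key=lambda i: (order.get(i, 1 << 30), i)), block
        ):
            mapping[old] = new
    return mapping


def _rebuild_sorted(term: Term, mapping: dict[int, int]) -> Term:
    cons = {}
    for i, sp in term.constraints.items():
        j = mapping.get(i, i)
        cons[j] = cons.get(j, GENERAL) & sp
    return Term(
        term.scalar,
        tuple(
            sorted(
                (frozenset(mapping.get(i, i) for i in d) for d in term.deltas),
                key=lambda d: tuple(sorted(d)),
            )
        ),
        tuple(
            sorted(
                (t.substitute(mapping) for t in term.tensors),
                key=lambda t: t.key,
            )
        ),
        tuple(o.substitute(mapping) for o in term.operators),
        tuple(mapping.get(i, i) for i in term.sum_indices),
        cons,
    )


def canonicalize(term: Term) -> Term | None:
    """Drive a term to its canonical form; returns ``None`` for zero.

    Idempotent: ``canonicalize(canonicalize(t)) == canonicalize(t)``.
    """
    if term.scalar == 0:
        return None
    if any(sp.is_empty for sp in term.constraints.values()):
        return None
    t = resolve_deltas(term)
    if t is None:
        return None
    t = rename_delta_indices(t)
    if any(sp.is_empty for sp in t.constraints.values()):
        return None
    # A constraint-only index (e.g. an explicitly created electron whose
    # operators contracted away) is legitimate and kept.
    return reorder_summation_indices(t)


# ---------------------------------------------------------------------
# expressions
# ---------------------------------------------------------------------


def fuse_terms(terms: Iterable[Term]) -> tuple[Term, ...]:
    """Merge terms equal up to scalar; drop zeros; sort canonically."""
    acc: dict[tuple, Term] = {}
    for t in terms:
        k = t.body_key
        prev = acc.get(k)
        if prev is None:
            acc[k] = t
        else:
            s = prev.scalar + t.scalar
            if s == 0:
                del acc[k]
            else:
                acc[k] = prev.with_scalar(s)
    return tuple(acc[k] for k in sorted(acc))


def combine_spaces(terms: Iterable[Term]) -> tuple[Term, ...]:
    """Fuse terms across the occupied ⊎ virtual = general decomposition.

    Two patterns are rewritten, each replacing a pair of terms by one:

    * ``s·Σ_{k∈occ} X + s·Σ_{k∈vir} X → s·Σ_k X`` (merge a split sum);
    * ``s·Σ_k X − s·Σ_{k∈S} X → s·Σ_{k∈S̄} X`` for a subspace S (restrict
      a general sum by its cancelled part).

    Applied to fixed point; needed for derived expressions to reach the
    familiar fully-fused forms (e.g. the Fock-matrix cancellation in the
    singles residual).
    """
    from .spaces import OCCUPIED, VIRTUAL

    pool: dict[tuple, Term] = {}
    for t in fuse_terms(terms):
        pool[t.body_key] = t

    def _variant(t: Term, k: int, space) -> Term | None:
        cons = dict(t.constraints)
        if space is GENERAL:
            cons.pop(k, None)
        else:
            cons[k] = space
        return canonicalize(
            Term(t.scalar, t.deltas, t.tensors, t.operators, t.sum_indices, cons)
        )

    changed = True
    while changed:
        changed = False
        for key in list(pool):
            t = pool.get(key)
            if t is None:
                continue
            for k in t.sum_indices:
                sp = t.space_of(k)
                if sp is OCCUPIED or sp is VIRTUAL:
                    comp = VIRTUAL if sp is OCCUPIED else OCCUPIED
                    # merge: s·Σ_occ + s·Σ_vir → s·Σ_gen
                    other = _variant(t, k, comp)
                    if other is not None:
                        partner = pool.get(other.body_key)
                        if partner is not None and partner.scalar == t.scalar:
                            merged = _variant(t, k, GENERAL)
                            del pool[key]
                            del pool[other.body_key]
                            if merged is not None:
                                prev = pool.get(merged.body_key)
                                if prev is not None:
                                    s = prev.scalar + merged.scalar
                                    if s == 0:
                                        del pool[merged.body_key]
                                    else:
                                        pool[merged.body_key] = prev.with_scalar(s)
                                else:
                                    pool[merged.body_key] = merged
                            changed = True
                            break
                    # restrict: the general version with opposite scalar
                    gen = _variant(t, k, GENERAL)
                    if gen is not None:
                        partner = pool.get(gen.body_key)
                        if partner is not None and partner.scalar == -t.scalar:
                            # s·Σ_gen − s·Σ_sp = s·Σ_comp, built from t's
                            # own labelling (partner may label differently)
                            restricted = _variant(
                                t.with_scalar(-t.scalar), k, comp
                            )
                            del pool[key]
                            del pool[gen.body_key]
                            if restricted is not None:
                                prev = pool.get(restricted.body_key)
                                if prev is not None:
                                    s = prev.scalar + restricted.scalar
                                    if s == 0:
                                        del pool[restricted.body_key]
                                    else:
                                        pool[restricted.body_key] = prev.with_scalar(s)
                                else:
                                    pool[restricted.body_key] = restricted
                            changed = True
                            break
            if changed:
                break
    return fuse_terms(pool.values())


class Expression:
    """A canonically sorted, fused collection of terms (zero = empty)."""

    __slots__ = ("terms",)

    def __init__(self, terms: Iterable[Term] = (), *, _canonical: bool = False):
        if _canonical:
            self.terms = tuple(terms)
            return
        canon = []
        for t in terms:
            c = canonicalize(t)
            if c is not None:
                canon.append(c)
        self.terms = fuse_terms(canon)

    @classmethod
    def zero(cls) -> "Expression":
        return cls((), _canonical=True)

    @classmethod
    def from_scalar(cls, value) -> "Expression":
        s = as_scalar(value)
        if s == 0:
            return cls.zero()
        return cls((Term(s),), _canonical=True)

    @property
    def is_zero(self) -> bool:
        return not self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[Term]:
        return iter(self.terms)

    def __eq__(self, other) -> bool:
        if isinstance(other, (int, Fraction)):
            other = Expression.from_scalar(other)
        return isinstance(other, Expression) and self.terms == other.terms

    def __hash__(self) -> int:
        return hash(self.terms)

    # -- algebra -------------------------------------------------------

    def __add__(self, other) -> "Expression":
        other = _as_expression(other)
        return Expression(
            fuse_terms(self.terms + other.terms), _canonical=True
        )

    __radd__ = __add__

    def __neg__(self) -> "Expression":
        return Expression(
            tuple(t.with_scalar(-t.scalar) for t in self.terms),
            _canonical=True,
        )

    def __sub__(self, other) -> "Expression":
        return self + (-_as_expression(other))

    def __rsub__(self, other) -> "Expression":
        return _as_expression(other) + (-self)

    def __mul__(self, other) -> "Expression":
        if isinstance(other, (int, Fraction)):
            return self.scale(other)
        if isinstance(other, float):
            as_scalar(other)  # raises with guidance
        other = _as_expression(other)
        out = []
        for a in self.terms:
            for b in other.terms:
                t = multiply_terms(a, b)
                if t is not None:
                    out.append(t)
        return Expression(out)

    def __rmul__(self, other) -> "Expression":
        if isinstance(other, (int, Fraction)):
            return self.scale(other)
        if isinstance(other, float):
            as_scalar(other)
        return _as_expression(other) * self

    def scale(self, c) -> "Expression":
        c = as_scalar(c)
        if c == 0:
            return Expression.zero()
        return Expression(
            tuple(t.with_scalar(t.scalar * c) for t in self.terms),
            _canonical=True,
        )

    def sum_over(self, *indices: int) -> "Expression":
        """Mark ``indices`` as summation indices in every term."""
        out = []
        for t in self.terms:
            out.append(
                Term(
                    t.scalar,
                    t.deltas,
                    t.tensors,
                    t.operators,
                    tuple(t.sum_indices) + tuple(indices),
                    t.constraints,
                )
            )
        return Expression(out)

    def __repr__(self) -> str:
        from .render import render_expression

        return f"Expression[\n{render_expression(self)}\n]"


def _as_expression(x) -> Expression:
    if isinstance(x, Expression):
        return x
    if isinstance(x, (int, Fraction)):
        return Expression.from_scalar(x)
    raise TypeError(f"cannot interpret {type(x).__name__} as Expression")


def relabel_apart(a: Term, b: Term) -> tuple[Term, Term]:
    """Relabel both terms' summation indices into fresh, disjoint ordinal
    ranges so the pair can be combined without capture."""
    top = max(a.all_indices() | b.all_indices(), default=0)
    map_a = {i: top + 1 + k for k, i in enumerate(a.sum_indices)}
    top_b = top + len(map_a)
    map_b = {i: top_b + 1 + k for k, i in enumerate(b.sum_indices)}
    return _substitute(a, map_a), _substitute(b, map_b)


def multiply_terms(a: Term, b: Term) -> Term | None:
    """Distributive product of two terms: operator strings concatenate in
    operand order; shared free indices intersect their constraints."""
    a, b = relabel_apart(a, b)
    cons: dict[int, OrbitalSpace] = dict(a.constraints)
    for i, sp in b.constraints.items():
        merged = cons.get(i, GENERAL) & sp
        if merged.is_empty:
            return None
        cons[i] = merged
    t = Term(
        a.scalar * b.scalar,
        a.deltas + b.deltas,
        a.tensors + b.tensors,
        a.operators + b.operators,
        a.sum_indices + b.sum_indices,
        cons,
    )
    return canonicalize(t)
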