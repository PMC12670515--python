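"""Canonical simplification of single terms and expression algebra."""

import warnings
from fractions import Fraction
from itertools import permutations

import pytest

import spinsq as sq
from spinsq import config
from spinsq.randexpr import random_term
from spinsq.terms import (
    Expression,
    PermutationCapExceeded,
    Term,
    canonicalize,
    combine_spaces,
    rename_delta_indices,
    resolve_deltas,
    _rebuild_sorted,
)
from spinsq.tensors import TensorRef, TensorSymmetry


def expr_of(*pieces):
    out = pieces[0]
    for p in pieces[1:]:
        out = out * p
    return out


class TestDeltaResolution:
    def test_summed_delta_index_is_substituted_and_dropped(self):
        # Σ_pqrs g_pqrs δ_qr E_ps loses one summation index and the delta
        x = (
            sq.psym_tensor("g", 1, 2, 3, 4) * sq.delta(2, 3) * sq.E(1, 4)
        ).sum_over(1, 2, 3, 4)
        (t,) = x
        assert not t.deltas
        assert len(t.sum_indices) == 3
        # repeated index inside g reflects the substitution
        (g,) = t.tensors
        assert len(set(g.indices)) == 3

    def test_term_without_deltas_unchanged(self):
        x = (sq.real_tensor("h", 1, 2) * sq.E(1, 2)).sum_over(1, 2)
        (t,) = x
        assert resolve_deltas(t) == t

    def test_disjoint_space_delta_annihilates(self):
        # δ_ia with i occupied, a virtual (free indices) is zero
        x = sq.delta(1, 2) * sq.real_tensor("h", 1) * sq.occupied(1) * sq.virtual(2)
        assert x.is_zero

    def test_overlapping_deltas_merge_transitively(self):
        x = sq.delta(1, 2) * sq.delta(2, 3) * sq.real_tensor("h", 1, 3)
        (t,) = x
        assert len(t.deltas) == 1
        assert len(t.deltas[0]) == 3

    def test_delta_intersects_constraints_onto_survivors(self):
        # δ_pq with q summed and constrained occupied restricts p
        x = (sq.delta(1, 2) * sq.real_tensor("h", 2) * sq.occupied(2)).sum_over(2)
        (t,) = x
        assert t.space_of(1) is sq.OCCUPIED


class TestRenaming:
    def test_free_delta_renames_to_lowest(self):
        # δ_pq E_pq → δ_pq E_pp
        x = sq.delta(1, 2) * sq.E(1, 2)
        (t,) = x
        (op,) = t.operators
        assert op.p == op.q == 1
        assert t.deltas == (frozenset((1, 2)),)

    def test_free_delta_renames_tensor_indices(self):
        x = sq.delta(1, 2) * sq.real_tensor("h", 2, 2)
        (t,) = x
        (h,) = t.tensors
        assert h.indices == (1, 1)

    def test_no_delta_identity(self):
        x = sq.real_tensor("h", 1, 2)
        (t,) = x
        assert rename_delta_indices(t) == t


class TestSummationReordering:
    def test_lexicographic_lowering(self):
        # Σ_pq h_qp E_qp → Σ_pq h_pq E_pq
        x = (sq.real_tensor("h", 2, 1) * sq.E(2, 1)).sum_over(1, 2)
        y = (sq.real_tensor("h", 1, 2) * sq.E(1, 2)).sum_over(1, 2)
        assert x == y

    def test_symmetric_tensor_forces_both_permutations(self):
        # with symmetric h, Σ h_pq E_qp must canonicalize consistently
        x = (sq.rsym_tensor("h", 1, 2) * sq.E(2, 1)).sum_over(1, 2)
        y = (sq.rsym_tensor("h", 2, 1) * sq.E(1, 2)).sum_over(1, 2)
        assert x == y
        assert config.stats.permutations_enumerated >= 4

    def test_eight_same_space_indices_enumerate_40320(self):
        idx = tuple(range(1, 9))
        x = Expression(
            (
                Term(
                    1,
                    tensors=(TensorRef("w", idx, TensorSymmetry.FULL_REAL),),
                    sum_indices=idx,
                ),
            )
        )
        assert not x.is_zero
        assert config.stats.permutations_enumerated == 40320

    def test_cap_triggers_greedy_fallback_with_warning(self):
        old = config.settings.permutation_cap
        config.settings.permutation_cap = 10
        try:
            idx = tuple(range(1, 9))
            with pytest.warns(PermutationCapExceeded):
                Expression(
                    (
                        Term(
                            1,
                            tensors=(
                                TensorRef("w", idx, TensorSymmetry.FULL_REAL),
                            ),
                            sum_indices=idx,
                        ),
                    )
                )
            assert config.stats.permutation_cap_hits == 1
        finally:
            config.settings.permutation_cap = old


class TestCanonicalizeProperties:
    def test_idempotent_on_random_terms(self, rng):
        for _ in range(300):
            t = random_term(rng, allow_fermions=True, allow_bosons=True)
            c = canonicalize(t)
            if c is None:
                continue
            c2 = canonicalize(c)
            assert c2 == c

    def test_agrees_with_exhaustive_relabeling(self, rng):
        """Against a brute-force oracle: the canonical key equals the
        minimum over every permutation of summation indices within
        compatible spaces (cross-space swaps would change constraints)."""
        from itertools import product as iproduct

        for _ in range(200):
            t = random_term(rng, max_indices=4)
            c = canonicalize(t)
            if c is None or not c.sum_indices:
                continue
            groups: dict[int, list[int]] = {}
            for i in c.sum_indices:
                groups.setdefault(c.space_of(i).mask, []).append(i)
            ordered = [sorted(g) for _, g in sorted(groups.items())]
            best = None
            for combo in iproduct(*(permutations(g) for g in ordered)):
                mapping = {}
                for orig, perm in zip(ordered, combo):
                    mapping.update(zip(orig, perm))
                key = _rebuild_sorted(c, mapping).body_key
                if best is None or key < best:
                    best = key
            assert c.body_key == best


class TestFuseAndAlgebra:
    def test_cancellation_gives_zero(self):
        x = 2 * sq.real_tensor("h", 1, 2)
        y = (-2) * sq.real_tensor("h", 1, 2)
        assert (x + y).is_zero

    def test_equal_terms_fuse(self):
        x = sq.real_tensor("h", 1, 2)
        assert (x + x) == 2 * x

    def test_multiply_by_one_is_identity(self):
        x = (sq.real_tensor("h", 1, 2) * sq.E(1, 2)).sum_over(1, 2)
        assert (1 * x) == x
        assert (x * 1) == x

    def test_operator_order_is_preserved(self):
        ab = sq.E(1, 2) * sq.E(3, 4)
        ba = sq.E(3, 4) * sq.E(1, 2)
        (t_ab,) = ab
        assert [o.key[1:] for o in t_ab.operators] == [(1, 2), (3, 4)]
        assert ab != ba

    def test_float_scalars_are_rejected_with_guidance(self):
        with pytest.raises(TypeError, match="[Ff]loat"):
            sq.real_tensor("h", 1, 2) * 0.5
        with pytest.raises(TypeError):
            Term(0.5)

    def test_summed_collision_is_relabelled_apart(self):
        # both factors sum over ordinal 1; the product must keep them apart
        x = sq.real_tensor("h", 1).sum_over(1)
        y = sq.real_tensor("f", 1, 1).sum_over(1)
        (t,) = x * y
        assert len(t.sum_indices) == 2


class TestCombineSpaces:
    def test_occ_plus_vir_merges_to_general(self):
        occ = (sq.real_tensor("h", 1, 1) * sq.occupied(1)).sum_over(1)
        vir = (sq.real_tensor("h", 1, 1) * sq.virtual(1)).sum_over(1)
        gen = (sq.real_tensor("h", 1, 1)).sum_over(1)
        merged = Expression(combine_spaces((occ + vir).terms), _canonical=True)
        assert merged == gen

    def test_general_minus_subspace_restricts(self):
        gen = (sq.real_tensor("h", 1, 1)).sum_over(1)
        vir = (sq.real_tensor("h", 1, 1) * sq.virtual(1)).sum_over(1)
        occ = (sq.real_tensor("h", 1, 1) * sq.occupied(1)).sum_over(1)
        out = Expression(combine_spaces((gen - vir).terms), _canonical=True)
        assert out == occ


class TestSpaces:
    def test_lattice(self):
        assert (sq.OCCUPIED & sq.VIRTUAL).is_empty
        assert (sq.GENERAL & sq.OCCUPIED) is sq.OCCUPIED
        assert sq.OCCUPIED in sq.GENERAL
        assert sq.OCCUPIED.parent is sq.GENERAL
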