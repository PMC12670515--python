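"""Expression calculus: commutators, BCH, ket projection, biorthogonality."""

from fractions import Fraction

import numpy as np
import pytest
import scipy.linalg

import spinsq as sq
from spinsq import config
from spinsq.algebra import (
    BiorthoScaled,
    PermutationGroup,
    ProjectionError,
    biorthonormal_rescale,
    classify_by_rank,
    clear_commutator_cache,
)
from spinsq.operators import SpinFermion, ALPHA
from spinsq.oracle import FockSpaceSpec, dense_operator, hf_vector, oracle_value, random_assignment
from spinsq.randexpr import random_expression
from spinsq.tensors import TensorSymmetry
from spinsq.terms import Term, Expression


class TestCommutator:
    def test_self_commutator_vanishes(self):
        x = (sq.real_tensor("h", 1, 2) * sq.E(1, 2)).sum_over(1, 2)
        assert sq.commutator(x, x).is_zero

    def test_antisymmetry_on_random_expressions(self, rng):
        for _ in range(25):
            a = random_expression(rng, allow_fermions=True, allow_bosons=True)
            b = random_expression(rng, allow_fermions=True, allow_bosons=True)
            assert (sq.commutator(a, b) + sq.commutator(b, a)).is_zero

    def test_jacobi_identity_on_singlet_excitations(self):
        e1 = sq.E(1, 2)
        e2 = sq.E(3, 4)
        e3 = sq.E(5, 6)
        total = (
            sq.commutator(sq.commutator(e1, e2), e3)
            + sq.commutator(sq.commutator(e2, e3), e1)
            + sq.commutator(sq.commutator(e3, e1), e2)
        )
        assert total.is_zero

    def test_equals_ab_minus_ba(self, rng, nprng):
        """Brute-force equivalence [a,b] = ab − ba (dense-matrix oracle:
        the commutator's rank-reduced form and the raw product difference
        are different operator strings, so the referee is numeric),
        including odd-fermion strings (anticommutator bookkeeping)."""
        spec = FockSpaceSpec(2, 1, boson_cutoff=3)
        assign = random_assignment(
            nprng,
            spec,
            [("h", 1, TensorSymmetry.NONE), ("h", 2, TensorSymmetry.NONE),
             ("h", 3, TensorSymmetry.NONE), ("f", 2, TensorSymmetry.NONE),
             ("g", 2, TensorSymmetry.PAIR_PERMUTATION),
             ("g", 4, TensorSymmetry.PAIR_PERMUTATION),
             ("t", 4, TensorSymmetry.PAIR_PERMUTATION),
             ("w", 2, TensorSymmetry.FULL_REAL),
             ("w", 4, TensorSymmetry.FULL_REAL)],
        )
        # compare on photon numbers ≤ 1 so the truncated boson ladder is
        # exact for every product of the generated strings
        pb = np.zeros((spec.boson_dim, spec.boson_dim))
        pb[0, 0] = pb[1, 1] = 1.0
        proj = np.kron(np.eye(spec.fermion_dim), pb)
        checked = 0
        for _ in range(40):
            a = random_expression(
                rng, allow_fermions=True, allow_bosons=True, sum_probability=1.0
            )
            b = random_expression(
                rng, allow_fermions=True, allow_bosons=True, sum_probability=1.0
            )
            if any(t.free_indices() for t in list(a) + list(b)):
                continue
            comm = sq.commutator(a, b)
            dim = spec.dim
            def mat(x):
                v = oracle_value(x, assign, spec)
                return v * np.eye(dim) if np.ndim(v) == 0 else v
            ma, mb = mat(a), mat(b)
            assert np.allclose(
                proj @ mat(comm) @ proj,
                proj @ (ma @ mb - mb @ ma) @ proj,
                atol=1e-9,
            )
            checked += 1
        assert checked >= 10

    def test_kernel_invocation_count_matches_bilinear_formula(self):
        """N_comm = Σ_IJ m_I n_J: operator-string lengths (2,3) against a
        single length-2 term give exactly 2·2 + 3·2 = 10 kernels."""
        clear_commutator_cache()
        a = sq.E(1, 2) * sq.E(3, 4) + sq.E(1, 2) * sq.E(3, 4) * sq.E(5, 6)
        b = sq.E(7, 8) * sq.E(9, 10)
        assert sorted(len(t.operators) for t in a) == [2, 3]
        config.reset_stats()
        sq.commutator(a, b)
        assert config.stats.kernel_invocations == 10

    def test_memoized_commutators_still_count_kernels(self):
        clear_commutator_cache()
        a = sq.E(1, 2) * sq.E(3, 4)
        b = sq.E(5, 6)
        config.reset_stats()
        sq.commutator(a, b)
        first = config.stats.kernel_invocations
        assert first == 2
        sq.commutator(a, b)  # cache hit must still account its kernels
        assert config.stats.kernel_invocations == 2 * first


class TestBCH:
    def test_order_zero_is_identity(self):
        h = sq.build_hamiltonian("h_g")
        assert sq.bch_expand(h, sq.build_cluster(2, include_t1=False), 0) == h

    def test_matches_matrix_similarity_transform(self, nprng):
        """e^{-B} A e^{B} against dense matrix exponentials for a
        nilpotent doubles cluster operator on two orbitals."""
        spec = FockSpaceSpec(2, 1)
        a = (sq.real_tensor("h", 1, 2) * sq.E(1, 2)).sum_over(1, 2)
        b = (
            Fraction(1, 2)
            * sq.psym_tensor("t", 1, 2, 3, 4)
            * sq.E(1, 2)
            * sq.E(3, 4)
            * sq.virtual(1, 3)
            * sq.occupied(2, 4)
        ).sum_over(1, 2, 3, 4)
        bch = sq.bch_expand(a, b, 8)
        assign = random_assignment(
            nprng,
            spec,
            [("h", 2, TensorSymmetry.NONE),
             ("t", 4, TensorSymmetry.PAIR_PERMUTATION)],
        )
        ma = oracle_value(a, assign, spec)
        mb = oracle_value(b, assign, spec)
        dense = scipy.linalg.expm(-mb) @ ma @ scipy.linalg.expm(mb)
        assert np.allclose(oracle_value(bch, assign, spec), dense, atol=1e-9)


class TestActOnKet:
    def test_singlet_excitation_worked_example(self):
        acted = sq.act_on_ket(sq.E(1, 2))
        by_rank = classify_by_rank(acted)
        zero_block = by_rank[Fraction(0)]
        (t0,) = zero_block
        assert t0.scalar == 2
        assert t0.deltas == (frozenset((1, 2)),)
        assert t0.space_of(1) is sq.OCCUPIED
        one_block = by_rank[Fraction(1)]
        (t1,) = one_block
        assert t1.space_of(1) is sq.VIRTUAL
        assert t1.space_of(2) is sq.OCCUPIED

    def test_empty_operator_string_unchanged(self):
        x = sq.real_tensor("h", 1, 2)
        assert sq.act_on_ket(x) == x

    def test_preserves_action_on_reference(self, rng, nprng):
        """act_on_ket(X)|HF⟩ == X|HF⟩ as dense vectors, for random
        operator strings."""
        spec = FockSpaceSpec(3, 1, boson_cutoff=2)
        assign = random_assignment(
            nprng,
            spec,
            [("h", 2, TensorSymmetry.NONE), ("h", 1, TensorSymmetry.NONE),
             ("h", 3, TensorSymmetry.NONE), ("f", 2, TensorSymmetry.NONE),
             ("g", 2, TensorSymmetry.PAIR_PERMUTATION),
             ("g", 4, TensorSymmetry.PAIR_PERMUTATION),
             ("t", 4, TensorSymmetry.PAIR_PERMUTATION),
             ("w", 2, TensorSymmetry.FULL_REAL),
             ("w", 4, TensorSymmetry.FULL_REAL)],
        )
        hf = hf_vector(spec)
        checked = 0
        for _ in range(40):
            x = random_expression(
                rng, allow_fermions=True, allow_bosons=True, sum_probability=1.0
            )
            if any(t.free_indices() for t in x):
                continue
            acted = sq.act_on_ket(x)
            lhs = oracle_value(x, assign, spec)
            rhs = oracle_value(acted, assign, spec)
            if np.ndim(lhs) == 0 or np.ndim(rhs) == 0:
                continue
            assert np.allclose(lhs @ hf, rhs @ hf, atol=1e-9)
            checked += 1
        assert checked >= 10

    def test_two_excitations_dense_check(self, nprng):
        spec = FockSpaceSpec(2, 1)
        x = sq.E(1, 2) * sq.E(3, 4)
        acted = sq.act_on_ket(x)
        hf = hf_vector(spec)
        for vals in ((0, 0, 1, 0), (1, 0, 1, 0), (0, 1, 1, 0)):
            fv = dict(zip((1, 2, 3, 4), vals))
            lhs = oracle_value(x, {}, spec, free_values=fv) @ hf
            rhs_terms = oracle_value(acted, {}, spec, free_values=fv)
            rhs = (rhs_terms @ hf if np.ndim(rhs_terms) else rhs_terms * hf)
            assert np.allclose(lhs, rhs, atol=1e-12)

    def test_rank_cap_discards_high_branches(self):
        x = sq.E(1, 2) * sq.E(3, 4)
        acted = sq.act_on_ket(x, max_rank=1)
        assert all(
            sq.excitation_rank(t.operators) <= 1 for t in acted
        )


class TestHFExpectation:
    def test_one_electron_part(self):
        h = (sq.real_tensor("h", 1, 2) * sq.E(1, 2)).sum_over(1, 2)
        expected = 2 * (sq.real_tensor("h", 1, 1) * sq.occupied(1)).sum_over(1)
        assert sq.hf_expectation(h) == expected

    def test_full_hamiltonian_against_dense_reference(self, nprng):
        spec = FockSpaceSpec(3, 2)
        h = sq.build_hamiltonian("h_g")
        energy = sq.hf_expectation(h)
        hf = hf_vector(spec)
        for _ in range(10):
            assign = random_assignment(
                nprng, spec,
                [("h", 2, TensorSymmetry.NONE),
                 ("g", 4, TensorSymmetry.PAIR_PERMUTATION),
                 ("h_nuc", 0, TensorSymmetry.NONE)],
            )
            dense = hf @ (oracle_value(h, assign, spec) @ hf)
            assert oracle_value(energy, assign, spec) == pytest.approx(dense)

    def test_pure_excitation_has_no_expectation(self):
        x = sq.E(1, 2) * sq.virtual(1) * sq.occupied(2)
        assert sq.hf_expectation(x).is_zero


class TestBiorthogonalProjection:
    def test_singles_template_equals_explicit_bra(self):
        """Template-ket projection reproduces ⟨HF|½E_ia H̄|HF⟩."""
        h = sq.build_hamiltonian("fock_g")
        t2 = sq.build_cluster(2, include_t1=False)
        hbar = sq.bch_expand(h, t2, 4)
        acted = sq.act_on_ket(hbar, max_rank=1)
        by_rank = classify_by_rank(acted)
        templ = sq.project_biorthogonal(by_rank[Fraction(1)], [(1, 2)])
        bra = Fraction(1, 2) * sq.E(2, 1) * sq.virtual(1) * sq.occupied(2)
        explicit = sq.hf_expectation(bra * acted)
        assert templ == explicit

    def test_doubles_template_equals_explicit_biorthogonal_bra(self):
        """Symmetrized template projection equals the explicit bra
        ⟨HF|(1/3 E_ia E_jb + 1/6 E_ja E_ib)."""
        h = sq.build_hamiltonian("fock_g")
        t2 = sq.build_cluster(2, include_t1=False)
        hbar = sq.bch_expand(h, t2, 4)
        acted = sq.act_on_ket(hbar, max_rank=2)
        by_rank = classify_by_rank(acted)
        a, i, b, j = 1, 2, 3, 4
        group = PermutationGroup([(a, i), (b, j)])
        templ = sq.symmetrize(
            sq.project_biorthogonal(by_rank[Fraction(2)], [(a, i), (b, j)]),
            group,
        )
        cons = sq.virtual(a, b) * sq.occupied(i, j)
        bra = (
            Fraction(1, 3) * sq.E(i, a) * sq.E(j, b)
            + Fraction(1, 6) * sq.E(j, a) * sq.E(i, b)
        ) * cons
        explicit = sq.hf_expectation(bra * acted)
        assert templ == explicit

    def test_zero_input_projects_to_zero(self):
        assert sq.project_biorthogonal(Expression.zero(), [(1, 2)]).is_zero

    def test_non_excitation_operators_raise(self):
        x = Expression(
            (Term(1, operators=(SpinFermion(1, ALPHA, True),
                                SpinFermion(2, ALPHA, False))),)
        )
        with pytest.raises(ProjectionError):
            sq.project_biorthogonal(x, [(3, 4)])


class TestSymmetrize:
    def test_identity_group(self):
        x = sq.real_tensor("X", 1, 2, 3, 4)
        g = PermutationGroup([(1, 2)])
        assert sq.symmetrize(x, g) == x

    def test_two_pair_expansion(self):
        x = sq.real_tensor("X", 1, 2, 3, 4) * sq.virtual(1, 3) * sq.occupied(2, 4)
        g = PermutationGroup([(1, 2), (3, 4)])
        out = sq.symmetrize(x, g)
        swapped = (
            sq.real_tensor("X", 3, 4, 1, 2) * sq.virtual(1, 3) * sq.occupied(2, 4)
        )
        assert out == x + swapped

    def test_summed_pair_index_rejected(self):
        x = (sq.real_tensor("X", 1, 2) * sq.virtual(1)).sum_over(1)
        with pytest.raises(ValueError, match="free"):
            sq.symmetrize(x, PermutationGroup([(1, 2)]))


class TestBiorthonormalRescale:
    def test_double_rescale_rejected(self):
        x = sq.real_tensor("X", 1, 2, 3, 4)
        g = PermutationGroup([(1, 2), (3, 4)])
        scaled = biorthonormal_rescale(x, g)
        assert isinstance(scaled, BiorthoScaled)
        with pytest.raises(ValueError, match="already"):
            biorthonormal_rescale(scaled, g)

    def test_requires_doubles_group(self):
        x = sq.real_tensor("X", 1, 2)
        with pytest.raises(ValueError, match="doubles"):
            biorthonormal_rescale(x, PermutationGroup([(1, 2)]))
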