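"""Einsum code emission: spec mapping, golden text, numeric equivalence."""

import itertools
import random
from fractions import Fraction

import numpy as np
import pytest

import spinsq as sq
from spinsq.algebra import PermutationGroup, biorthonormal_rescale
from spinsq.codegen import CodegenConfig, emit_function, to_contraction_spec
from spinsq.spaces import GENERAL, OCCUPIED, VIRTUAL
from spinsq.tensors import TensorRef, TensorSymmetry
from spinsq.terms import Expression, Term

NO, NV = 2, 3
NM = NO + NV


def run_generated(src, name, **arrays):
    ns = {}
    exec(compile(src, "<generated>", "exec"), ns)
    return ns[name](NO, NV, **arrays)


def brute_force(term, arrays):
    """Direct loop evaluation of an operator-free term over the orbital
    blocks (independent of the einsum path)."""
    ranges = {OCCUPIED.mask: range(NO), VIRTUAL.mask: range(NO, NM),
              GENERAL.mask: range(NM)}
    free = sorted(term.free_indices())
    shape = tuple(len(ranges[term.space_of(i).mask]) for i in free)
    out = np.zeros(shape if shape else ())
    for fvals in itertools.product(*(ranges[term.space_of(i).mask] for i in free)):
        val = dict(zip(free, fvals))
        acc = 0.0
        for svals in itertools.product(
            *(ranges[term.space_of(i).mask] for i in term.sum_indices)
        ):
            val.update(zip(term.sum_indices, svals))
            prod = float(term.scalar)
            for ref in term.tensors:
                prod *= arrays[ref.name][tuple(val[i] for i in ref.indices)]
            acc += prod
        pos = tuple(
            v - (NO if term.space_of(i).mask == VIRTUAL.mask else 0)
            for i, v in zip(free, fvals)
        )
        out[pos] += acc
    return out


class TestContractionSpec:
    def test_fock_amplitude_term(self):
        # Σ_c F_ac t_bjci with a,b,c virtual and i,j occupied
        a, i, b, j, c = 1, 2, 3, 4, 5
        x = (
            sq.real_tensor("F", a, c)
            * sq.psym_tensor("t", b, j, c, i)
            * sq.virtual(a, b, c)
            * sq.occupied(i, j)
        ).sum_over(c)
        (t,) = x
        spec = to_contraction_spec(t)
        assert spec.factor == 1
        assert spec.output_indices == "aibj"
        assert spec.output_blocks == "vovo"
        names = sorted(op[0] for op in spec.operands)
        assert names == ["F", "t"]
        for name, blocks, letters in spec.operands:
            if name == "F":
                assert blocks == "vv"

    def test_scalar_constant_term(self):
        (t,) = sq.real_tensor("h_nuc")
        spec = to_contraction_spec(t)
        assert spec.output_indices == ""
        assert spec.operands == (("h_nuc", "", ""),)

    def test_operator_term_rejected(self):
        (t,) = sq.E(1, 2)
        with pytest.raises(ValueError, match="operator"):
            to_contraction_spec(t)

    def test_delta_term_rejected(self):
        (t,) = sq.delta(1, 2) * sq.real_tensor("h", 1, 2)
        with pytest.raises(ValueError, match="[Kk]ronecker"):
            to_contraction_spec(t)


class TestEmission:
    def test_golden_source(self):
        a, i, b, j, c = 1, 2, 3, 4, 5
        x = (
            sq.real_tensor("F", a, c)
            * sq.psym_tensor("t", b, j, c, i)
            * sq.virtual(a, b, c)
            * sq.occupied(i, j)
        ).sum_over(c)
        cfg = CodegenConfig(
            function_name="omega_term", explicit_block_tensors={"t"}
        )
        src = emit_function(x, cfg)
        expected = '''"""Auto-generated tensor-contraction code. Do not edit."""
import numpy as np


def omega_term(no, nv, *, F, t_vovo):
    nm = no + nv
    o = slice(0, no)
    v = slice(no, nm)
    out = np.zeros((nv, no, nv, no))
    out += 1 * np.einsum("ac,bjci->aibj", F[v, v], t_vovo, optimize=True)
    return out
'''
        assert src == expected

    def test_empty_expression_returns_zero_array(self):
        src = emit_function(Expression.zero(), CodegenConfig(function_name="f0"))
        out = run_generated(src, "f0")
        assert out.shape == ()
        assert out == 0.0

    def test_reserved_name_collision_rejected(self):
        x = sq.real_tensor("out", 1, 2) * sq.occupied(1, 2)
        with pytest.raises(ValueError, match="reserved"):
            emit_function(x, CodegenConfig())

    def test_numeric_equivalence_many_random_expressions(self, nprng):
        """Generated code equals brute-force evaluation for ≥ 50 random
        operator-free terms."""
        pyrng = random.Random(7)
        checked = 0
        while checked < 50:
            # random term over free (a,i) with up to two summed indices
            n_extra = pyrng.randint(0, 2)
            extra = list(range(3, 3 + n_extra))
            spaces = {1: VIRTUAL, 2: OCCUPIED}
            cons = {}
            for k in extra:
                cons[k] = pyrng.choice((OCCUPIED, VIRTUAL, GENERAL))
            pool = [1, 2] + extra
            tensors = []
            arrays = {}
            for nth in range(pyrng.randint(1, 3)):
                arity = pyrng.choice((1, 2, 2, 4))
                name = f"x{nth}"
                idx = [pyrng.choice(pool) for _ in range(arity)]
                # ensure free indices appear somewhere
                if nth == 0:
                    idx[:2] = [1, 2] if arity >= 2 else [1]
                tensors.append(TensorRef(name, tuple(idx), TensorSymmetry.NONE))
                arrays[name] = nprng.integers(-3, 4, size=(NM,) * arity).astype(float)
            constraints = {1: VIRTUAL, 2: OCCUPIED, **cons}
            term = Term(
                Fraction(pyrng.randint(-3, 3) or 1, pyrng.randint(1, 2)),
                (),
                tensors,
                (),
                extra,
                constraints,
            )
            x = Expression((term,))
            if x.is_zero or len(x) != 1:
                continue
            (canon,) = x
            if sorted(canon.free_indices()) != [1, 2]:
                continue
            cfg = CodegenConfig(function_name="fn")
            src = emit_function(x, cfg)
            got = run_generated(src, "fn", **arrays)
            want = brute_force(canon, arrays)
            assert np.allclose(got, want, rtol=1e-12, atol=1e-12), src
            checked += 1

    def test_biorthonormal_diagonal_scaling(self):
        # a constant symmetric doubles-like output scaled by 1/(1+δδ)
        a, i, b, j = 1, 2, 3, 4
        x = (
            sq.real_tensor("Y", a, i)
            * sq.real_tensor("Y", b, j)
            * sq.virtual(a, b)
            * sq.occupied(i, j)
        )
        g = PermutationGroup([(a, i), (b, j)])
        plain_src = emit_function(x, CodegenConfig(function_name="plain"))
        scaled_src = emit_function(
            biorthonormal_rescale(x, g), CodegenConfig(function_name="scaled")
        )
        Y = np.arange(NM * NM, dtype=float).reshape(NM, NM)
        plain = run_generated(plain_src, "plain", Y=Y)
        scaled = run_generated(scaled_src, "scaled", Y=Y)
        for ai in range(NV):
            for ii in range(NO):
                for bi in range(NV):
                    for ji in range(NO):
                        factor = 0.5 if (ai == bi and ii == ji) else 1.0
                        assert scaled[ai, ii, bi, ji] == pytest.approx(
                            factor * plain[ai, ii, bi, ji]
                        )

    def test_determinism(self, ccsd_report):
        red, _, _ = ccsd_report.blocks["doubles"]
        cfg = CodegenConfig(
            function_name="omega_doubles_redundant",
            explicit_block_tensors={"t", "u"},
        )
        assert emit_function(red, cfg) == emit_function(red, cfg)

    def test_ccsd_redundant_doubles_compiles_and_runs(self, ccsd_report, nprng):
        red, _, _ = ccsd_report.blocks["doubles"]
        cfg = CodegenConfig(
            function_name="omega_doubles_redundant",
            explicit_block_tensors={"t", "u"},
        )
        src = emit_function(red, cfg)
        t_full = nprng.standard_normal((NM,) * 4)
        t_full = 0.5 * (t_full + t_full.transpose(2, 3, 0, 1))
        u_full = 2.0 * t_full - t_full.transpose(0, 3, 2, 1)
        arrays = {
            "F": nprng.standard_normal((NM, NM)),
            "g": nprng.standard_normal((NM,) * 4),
            "t_vovo": t_full[NO:, :NO, NO:, :NO],
            "u_vovo": u_full[NO:, :NO, NO:, :NO],
        }
        arrays["g"] = 0.5 * (arrays["g"] + arrays["g"].transpose(2, 3, 0, 1))
        out = run_generated(src, "omega_doubles_redundant", **arrays)
        assert out.shape == (NV, NO, NV, NO)
        assert np.isfinite(out).all()
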