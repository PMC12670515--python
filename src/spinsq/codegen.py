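"""Translate operator-free expressions into runnable einsum contraction code.

A finalized amplitude or energy expression is a sum of scalar terms —
tensor products with constrained, partially summed indices.  Each term
maps onto one einsum contraction (:class:`ContractionSpec`), and
:func:`emit_function` assembles a runnable numpy function that accumulates
one contraction per term into the output array.  Per-term contraction
order is delegated to ``np.einsum(..., optimize=True)``; common
intermediates are deliberately not shared across terms.

Orbital blocks are half-open, 0-based ranges of the molecular-orbital
dimension: occupied ``[0, no)`` and virtual ``[no, no+nv)``.  Tensors
listed as *explicit-block* inputs are passed pre-sliced (``t_vovo``),
everything else is passed whole and sliced inside the generated function.

Terms containing Kronecker deltas are rejected — a documented limitation
of the emitter (delta-bearing contractions need index-coincidence logic
that plain einsum does not express).
"""

from __future__ import annotations

import keyword
from dataclasses import dataclass, field
from fractions import Fraction

from .algebra import BiorthoScaled
from .spaces import GENERAL, OCCUPIED, VIRTUAL
from .terms import Expression, Term, _as_expression

__all__ = ["ContractionSpec", "CodegenConfig", "to_contraction_spec", "emit_function"]

_BLOCK = {OCCUPIED.mask: "o", VIRTUAL.mask: "v", GENERAL.mask: "g"}
_SLICE = {"o": "o", "v": "v", "g": ":"}
_DIM = {"o": "no", "v": "nv", "g": "nm"}

_RESERVED = {"no", "nv", "nm", "o", "v", "out", "np", "slice"}


@dataclass(frozen=True)
class ContractionSpec:
    """Language-neutral description of one scalar term as a contraction."""

    factor: Fraction
    output_indices: str
    output_blocks: str
    operands: tuple[tuple[str, str, str], ...]  # (tensor name, blocks, letters)
    #: block labels of summation indices absent from every operand (a
    #: "free sum" just multiplies by the block dimension)
    dangling_sums: tuple[str, ...] = ()


@dataclass
class CodegenConfig:
    function_name: str = "generated_contraction"
    #: tensors whose used sub-blocks are explicit pre-sliced inputs
    explicit_block_tensors: set[str] = field(default_factory=set)
    #: tensors passed whole, sliced inside the generated function
    full_tensors: set[str] = field(default_factory=set)

    def __post_init__(self):
        overlap = self.explicit_block_tensors & self.full_tensors
        if overlap:
            raise ValueError(
                f"tensors {sorted(overlap)} listed both as explicit-block "
                "and full inputs"
            )


_POOL = "abcdefghijklmnopqrstuvwxyz"


def _letters_for(term: Term) -> dict[int, str]:
    """Distinct single-letter einsum labels, drawn from each index's
    space sequence where possible."""
    used: set[str] = set()
    out: dict[int, str] = {}
    for i in sorted(term.all_indices()):
        sp = term.space_of(i)
        letter = next((c for c in sp.letters if c not in used), None)
        if letter is None:
            letter = next(c for c in _POOL if c not in used)
        used.add(letter)
        out[i] = letter
    return out


def to_contraction_spec(term: Term) -> ContractionSpec:
    """Deterministically map an operator-free, delta-free term to a
    contraction spec.  Free indices (sorted by ordinal) become output
    indices; constraints become block labels (occupied → o, virtual → v,
    unconstrained → g)."""
    if term.operators:
        raise ValueError("cannot generate code for a term with operators")
    if term.deltas:
        raise ValueError(
            "terms containing Kronecker deltas are not supported by the "
            "code generator"
        )
    lm = _letters_for(term)
    free = sorted(term.free_indices())
    out_idx = "".join(lm[i] for i in free)
    out_blk = "".join(_BLOCK[term.space_of(i).mask] for i in free)
    operands = tuple(
        (
            t.name,
            "".join(_BLOCK[term.space_of(i).mask] for i in t.indices),
            "".join(lm[i] for i in t.indices),
        )
        for t in term.tensors
    )
    body = {i for t in term.tensors for i in t.indices}
    dangling = tuple(
        _BLOCK[term.space_of(i).mask]
        for i in term.sum_indices
        if i not in body
    )
    return ContractionSpec(term.scalar, out_idx, out_blk, operands, dangling)


def _factor_src(f: Fraction) -> str:
    if f.denominator == 1:
        return str(f.numerator)
    return f"({f.numerator}/{f.denominator})"


def _operand_src(name: str, blocks: str, cfg: CodegenConfig) -> str:
    if name in cfg.explicit_block_tensors:
        return f"{name}_{blocks}" if blocks else name
    if not blocks:
        return name
    if set(blocks) == {"g"}:
        return name
    return f"{name}[{', '.join(_SLICE[b] for b in blocks)}]"


def emit_function(a, cfg: CodegenConfig) -> str:
    """Emit a runnable numpy function accumulating one einsum per term.

    Accepts an :class:`~spinsq.terms.Expression` or a
    :class:`~spinsq.algebra.BiorthoScaled` result, in which case the
    diagonal 1/(1+δ_ij δ_ab) biorthonormalization factor is applied to the
    accumulated output.
    """
    scaled_pairs = None
    if isinstance(a, BiorthoScaled):
        scaled_pairs = a.group.pair_list
        a = a.expression
    a = _as_expression(a)
    specs = [to_contraction_spec(t) for t in a]
    if specs:
        out_idx = specs[0].output_indices
        out_blk = specs[0].output_blocks
        for s in specs[1:]:
            if (s.output_indices, s.output_blocks) != (out_idx, out_blk):
                raise ValueError(
                    "terms disagree on output indices; cannot emit a single "
                    "function"
                )
    else:
        out_idx = out_blk = ""

    params: list[str] = []
    seen: set[str] = set()
    for s in specs:
        for name, blocks, _letters in s.operands:
            if keyword.iskeyword(name) or name in _RESERVED:
                raise ValueError(
                    f"tensor name {name!r} collides with a reserved word"
                )
            if name in cfg.explicit_block_tensors:
                pname = f"{name}_{blocks}" if blocks else name
            else:
                pname = name
            if pname not in seen:
                seen.add(pname)
                params.append(pname)

    lines: list[str] = []
    lines.append('"""Auto-generated tensor-contraction code. Do not edit."""')
    lines.append("import numpy as np")
    lines.append("")
    lines.append("")
    sig = ", ".join(["no", "nv"] + (["*"] + sorted(params) if params else []))
    lines.append(f"def {cfg.function_name}({sig}):")
    lines.append("    nm = no + nv")
    lines.append("    o = slice(0, no)")
    lines.append("    v = slice(no, nm)")
    if out_idx:
        shape = ", ".join(_DIM[b] for b in out_blk)
        if len(out_blk) == 1:
            shape += ","
        lines.append(f"    out = np.zeros(({shape}))")
    else:
        lines.append("    out = np.zeros(())")
    for s in specs:
        factor = _factor_src(s.factor)
        if not s.operands:
            lines.append(f"    out += {factor}")
            continue
        arr_ops = [op for op in s.operands if op[2]]
        scalar_ops = [op for op in s.operands if not op[2]]
        prefix = " * ".join(
            [factor]
            + [_DIM[b] for b in s.dangling_sums]
            + [_operand_src(name, blocks, cfg) for name, blocks, _ in scalar_ops]
        )
        if arr_ops:
            subs = ",".join(letters for _, _, letters in arr_ops)
            args = ", ".join(
                _operand_src(name, blocks, cfg) for name, blocks, _ in arr_ops
            )
            # free indices absent from every operand broadcast along ones
            present = {c for _, _, letters in arr_ops for c in letters}
            for c, b in zip(s.output_indices, s.output_blocks):
                if c not in present:
                    subs += f",{c}"
                    args += f", np.ones(({_DIM[b]},))"
            lines.append(
                f"    out += {prefix} * np.einsum("
                f'"{subs}->{s.output_indices}", {args}, optimize=True)'
            )
        else:  # pure scalar term
            lines.append(f"    out += {prefix}")
    if scaled_pairs is not None:
        if len(scaled_pairs) != 2:
            raise ValueError(
                "diagonal biorthonormal rescaling is defined for doubles"
            )
        # locate the pair letters in the output string
        free_order = out_idx
        if len(free_order) != 4:
            raise ValueError("doubles rescaling expects a 4-index output")
        a1, i1, a2, i2 = free_order
        lines.append("    _ev = np.eye(nv, dtype=bool)")
        lines.append("    _eo = np.eye(no, dtype=bool)")
        lines.append(
            f'    _diag = np.einsum("{a1}{a2},{i1}{i2}->{free_order}", '
            "_ev, _eo)"
        )
        lines.append("    out = out / (1.0 + _diag)")
    lines.append("    return out")
    return "\n".join(lines) + "\n"
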