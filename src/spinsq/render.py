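"""Plain-text rendering of terms and expressions, and a matching parser.

Grammar (one term per line)::

    <sign><rational> ∑_{<indices>}( <deltas> <tensors> <operators> ) <constraints>

with deltas as ``δ_pq``, tensors as ``name_pqrs``, operators as ``E_pq``,
``τ_pq``, ``a†_pα``, ``b†`` and constraints as ``C(a∈v)``.  Index letters
encode the orbital space (``i``–``n`` occupied, ``a``–``h`` virtual,
``p``–``w`` general); an explicit constraint clause is printed only for an
index that appears nowhere else in the term.  The ``ascii`` dialect writes
``sum_{..}``, ``d_pq`` → ``delta_pq``, ``τ`` → ``tau``, ``a†_pα`` →
``a+_pA`` and ``C(a in v)``.

The parser exists to support golden-file round-trip tests (render → parse
→ render is a fixed point); it is not a general input language.  Tensor
symmetry classes are not part of the printed form, so the parser takes an
optional ``symmetries`` map from tensor name to class.
"""

from __future__ import annotations

import re
from fractions import Fraction

from .operators import (
    ALPHA,
    BETA,
    BosonOp,
    Operator,
    SingletExcitation,
    SpinFermion,
    TripletExcitation,
)
from .spaces import GENERAL, OCCUPIED, VIRTUAL, OrbitalSpace, space_from_letter
from .tensors import TensorRef, TensorSymmetry
from .terms import Expression, Term, _as_expression

__all__ = ["render_term", "render_expression", "parse_expression"]

_SHORT_TO_SPACE = {"o": OCCUPIED, "v": VIRTUAL, "g": GENERAL}


def _letter_map(term: Term) -> dict[int, str]:
    """Assign printable letters: indices in ordinal order draw successive
    glyphs from their space's sequence (with numeric suffixes past the
    end)."""
    counters: dict[int, int] = {}
    out: dict[int, str] = {}
    for i in sorted(term.all_indices()):
        sp = term.space_of(i)
        k = counters.get(sp.mask, 0)
        counters[sp.mask] = k + 1
        if k < len(sp.letters):
            out[i] = sp.letters[k]
        else:
            out[i] = sp.letters[0] + str(k)
    return out


def _spin_glyph(spin: int, unicode_ok: bool) -> str:
    if unicode_ok:
        return "α" if spin == ALPHA else "β"
    return "A" if spin == ALPHA else "B"


def _render_op(o: Operator, lm: dict[int, str], uni: bool) -> str:
    if isinstance(o, SingletExcitation):
        return f"E_{lm[o.p]}{lm[o.q]}"
    if isinstance(o, TripletExcitation):
        return (f"τ_{lm[o.p]}{lm[o.q]}" if uni else f"tau_{lm[o.p]}{lm[o.q]}")
    if isinstance(o, SpinFermion):
        dag = ("†" if uni else "+") if o.dagger else ("" if uni else "-")
        return f"a{dag}_{lm[o.p]}{_spin_glyph(o.spin, uni)}"
    if isinstance(o, BosonOp):
        if uni:
            return "b†" if o.dagger else "b"
        return "b+" if o.dagger else "b-"
    raise TypeError(f"cannot render {type(o).__name__}")


def render_term(term: Term, dialect: str | None = None) -> str:
    from . import config

    dialect = dialect or config.settings.render_dialect
    uni = dialect == "unicode"
    lm = _letter_map(term)
    s = term.scalar
    sign = "+" if s > 0 else "-"
    rat = str(abs(s))
    parts: list[str] = []
    for d in sorted(term.deltas, key=lambda d: tuple(sorted(d))):
        sub = "".join(lm[i] for i in sorted(d))
        parts.append((f"δ_{sub}" if uni else f"delta_{sub}"))
    for t in term.tensors:
        sub = "".join(lm[i] for i in t.indices)
        parts.append(f"{t.name}_{sub}" if sub else t.name)
    for o in term.operators:
        parts.append(_render_op(o, lm, uni))
    body = " ".join(parts)
    if term.sum_indices:
        sub = "".join(lm[i] for i in term.sum_indices)
        head = (f"∑_{{{sub}}}" if uni else f"sum_{{{sub}}}")
    else:
        head = ""
    present = term.body_indices() | set(term.sum_indices)
    cons = []
    for i in sorted(term.constraints):
        if i not in present:
            rel = "∈" if uni else " in "
            cons.append(f"C({lm[i]}{rel}{term.constraints[i].short})")
    tail = (" " + " ".join(cons)) if cons else ""
    return f"{sign}{rat} {head}( {body} ){tail}"


def render_expression(a, dialect: str | None = None) -> str:
    a = _as_expression(a)
    if a.is_zero:
        return "0"
    return "\n".join(render_term(t, dialect) for t in a)


# ---------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------

_TERM_RE = re.compile(
    r"^([+-])(\d+(?:/\d+)?)\s*"
    r"(?:(?:∑|sum)_\{([^}]*)\})?"
    r"\(\s*(.*?)\s*\)\s*(.*)$"
)
_CONS_RE = re.compile(r"C\((\w+)(?:∈| in )(\w)\)")
_IDX_RE = re.compile(r"[a-w]\d*")


class ParseError(ValueError):
    pass


def _parse_indices(sub: str) -> list[str]:
    out = _IDX_RE.findall(sub)
    if "".join(out) != sub:
        raise ParseError(f"cannot tokenize index subscript {sub!r}")
    return out


def parse_expression(
    text: str,
    symmetries: dict[str, TensorSymmetry] | None = None,
) -> Expression:
    """Parse the rendering grammar back into an expression (both
    dialects)."""
    symmetries = symmetries or {}
    text = text.strip()
    if text in ("", "0"):
        return Expression.zero()
    terms = []
    for line in text.splitlines():
        line = line.strip()
        if line:
            terms.append(_parse_term(line, symmetries))
    return Expression(terms)


def _op_from_token(tok: str, ords) -> Operator | None:
    if tok in ("b†", "b+"):
        return BosonOp(True)
    if tok in ("b", "b-"):
        return BosonOp(False)
    m = re.fullmatch(r"E_(\w+)", tok)
    if m:
        p, q = _parse_indices(m.group(1))
        return SingletExcitation(ords(p), ords(q))
    m = re.fullmatch(r"(?:τ|tau)_(\w+)", tok)
    if m:
        p, q = _parse_indices(m.group(1))
        return TripletExcitation(ords(p), ords(q))
    m = re.fullmatch(r"a(†|\+|-)?_(\w+?)(α|β|A|B)", tok)
    if m:
        dag = m.group(1) in ("†", "+")
        (p,) = _parse_indices(m.group(2))
        spin = ALPHA if m.group(3) in ("α", "A") else BETA
        return SpinFermion(ords(p), spin, dag)
    return None


def _parse_term(line: str, symmetries) -> Term:
    m = _TERM_RE.match(line)
    if not m:
        raise ParseError(f"cannot parse term {line!r}")
    sign, rat, sums, body, tail = m.groups()
    scalar = Fraction(rat)
    if sign == "-":
        scalar = -scalar

    letters: dict[str, int] = {}
    spaces: dict[str, OrbitalSpace] = {}

    def ords(letter: str) -> int:
        if letter not in letters:
            letters[letter] = 0  # placeholder, numbered later
            spaces[letter] = space_from_letter(letter)
        return letter  # temporarily keyed by letter

    deltas = []
    tensors = []
    operators = []
    for tok in body.split():
        if not tok:
            continue
        dm = re.fullmatch(r"(?:δ|delta)_(\w+)", tok)
        if dm:
            deltas.append(frozenset(ords(x) for x in _parse_indices(dm.group(1))))
            continue
        op = _op_from_token(tok, ords)
        if op is not None:
            operators.append(op)
            continue
        tm = re.fullmatch(r"([A-Za-z_][A-Za-z0-9_]*?)(?:_(\w+))?", tok)
        if not tm:
            raise ParseError(f"cannot parse token {tok!r}")
        name, sub = tm.group(1), tm.group(2)
        idx = _parse_indices(sub) if sub else []
        tensors.append(
            (name, tuple(ords(x) for x in idx), symmetries.get(name, TensorSymmetry.NONE))
        )
    sum_letters = _parse_indices(sums) if sums else []
    for x in sum_letters:
        ords(x)
    cons_extra = {}
    for cm in _CONS_RE.finditer(tail):
        letter, short = cm.groups()
        ords(letter)
        cons_extra[letter] = _SHORT_TO_SPACE[short]

    # Ordinal assignment.  The raw ordinal interleaving across spaces is
    # not part of the printed form, so the parser normalizes: free
    # indices follow the excitation-template convention — virtual and
    # occupied letters alternate pairwise (a,i,b,j,…), then general —
    # and summation indices come after (canonicalization relabels them
    # anyway).  This makes rendering printed derivation output an exact
    # fixed point of parse ∘ render.
    def _letter_rank(x: str):
        base = x.rstrip("0123456789")
        suffix = x[len(base):]
        if suffix:  # overflow glyphs like "p8" come after plain letters
            return (1, int(suffix))
        return (0, spaces[x].letters.index(base))

    sum_set = set(sum_letters)
    free = [x for x in letters if x not in sum_set]
    vir = sorted((x for x in free if spaces[x] is VIRTUAL), key=_letter_rank)
    occ = sorted((x for x in free if spaces[x] is OCCUPIED), key=_letter_rank)
    gen = sorted((x for x in free if spaces[x] is GENERAL), key=_letter_rank)
    ordered: list[str] = []
    for k in range(max(len(vir), len(occ))):
        if k < len(vir):
            ordered.append(vir[k])
        if k < len(occ):
            ordered.append(occ[k])
    ordered += gen
    ordered += sorted(
        sum_set, key=lambda x: (spaces[x].mask, _letter_rank(x))
    )
    final = {x: k + 1 for k, x in enumerate(ordered)}

    def fin(v):
        return final[v]

    constraints = {final[x]: spaces[x] for x in letters}
    for x, sp in cons_extra.items():
        constraints[final[x]] = sp
    return Term(
        scalar,
        tuple(frozenset(fin(x) for x in d) for d in deltas),
        tuple(
            TensorRef(name, tuple(fin(x) for x in idx), sym)
            for name, idx, sym in tensors
        ),
        tuple(_finalize_op(o, final) for o in operators),
        tuple(final[x] for x in sum_letters),
        constraints,
    )


def _finalize_op(o: Operator, final: dict[str, int]) -> Operator:
    if isinstance(o, SingletExcitation):
        return SingletExcitation(final[o.p], final[o.q])
    if isinstance(o, TripletExcitation):
        return TripletExcitation(final[o.p], final[o.q])
    if isinstance(o, SpinFermion):
        return SpinFermion(final[o.p], o.spin, o.dagger)
    return o
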