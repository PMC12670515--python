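"""Random term/expression generation for property-based testing.

Seeded generators producing well-formed random terms: small rational
scalars, tensors of the three symmetry classes, optional deltas, operator
strings and partially summed, partially constrained indices.  Used by the
test suite's canonicalization, oracle-equivalence and codegen properties.
"""

from __future__ import annotations

import random
from fractions import Fraction

from .operators import (
    ALPHA,
    BETA,
    BosonOp,
    SingletExcitation,
    SpinFermion,
    TripletExcitation,
)
from .spaces import GENERAL, OCCUPIED, VIRTUAL
from .tensors import TensorRef, TensorSymmetry
from .terms import Expression, Term

_SPACES = (GENERAL, OCCUPIED, VIRTUAL)


def random_term(
    rng: random.Random,
    max_indices: int = 4,
    n_tensors: tuple[int, int] = (1, 2),
    allow_deltas: bool = True,
    allow_operators: bool = True,
    allow_fermions: bool = False,
    allow_bosons: bool = False,
    sum_probability: float = 0.6,
) -> Term:
    n_idx = rng.randint(1, max_indices)
    indices = list(range(1, n_idx + 1))
    constraints = {}
    for i in indices:
        sp = rng.choice(_SPACES)
        if sp is not GENERAL:
            constraints[i] = sp

    def pick() -> int:
        return rng.choice(indices)

    tensors = []
    # tensor names are tied to a symmetry class so rendered expressions
    # can be re-parsed with a fixed symmetry map
    choices = [
        ("h", TensorSymmetry.NONE, (1, 2, 3)),
        ("f", TensorSymmetry.NONE, (2,)),
        ("g", TensorSymmetry.PAIR_PERMUTATION, (2, 4)),
        ("t", TensorSymmetry.PAIR_PERMUTATION, (4,)),
        ("w", TensorSymmetry.FULL_REAL, (2, 4)),
    ]
    for _ in range(rng.randint(*n_tensors)):
        name, sym, arities = rng.choice(choices)
        arity = rng.choice(arities)
        tensors.append(
            TensorRef(name, tuple(pick() for _ in range(arity)), sym)
        )
    deltas = []
    if allow_deltas and rng.random() < 0.4:
        i, j = pick(), pick()
        if i != j:
            deltas.append(frozenset((i, j)))
    operators = []
    if allow_operators:
        for _ in range(rng.randint(0, 2)):
            kinds = ["E", "tau"]
            if allow_fermions:
                kinds += ["fermion"]
            if allow_bosons:
                kinds += ["boson"]
            kind = rng.choice(kinds)
            if kind == "E":
                operators.append(SingletExcitation(pick(), pick()))
            elif kind == "tau":
                operators.append(TripletExcitation(pick(), pick()))
            elif kind == "fermion":
                operators.append(
                    SpinFermion(pick(), rng.choice((ALPHA, BETA)), rng.random() < 0.5)
                )
            else:
                operators.append(BosonOp(rng.random() < 0.5))
    sums = [i for i in indices if rng.random() < sum_probability]
    scalar = Fraction(rng.randint(-4, 4) or 1, rng.randint(1, 3))
    return Term(scalar, deltas, tensors, operators, sums, constraints)


def random_expression(rng: random.Random, n_terms: int = 3, **kwargs) -> Expression:
    return Expression(
        [random_term(rng, **kwargs) for _ in range(rng.randint(1, n_terms))]
    )


#: symmetry classes of the generator's tensor names (for re-parsing)
SYMMETRY_MAP = {
    "h": TensorSymmetry.NONE,
    "f": TensorSymmetry.NONE,
    "g": TensorSymmetry.PAIR_PERMUTATION,
    "t": TensorSymmetry.PAIR_PERMUTATION,
    "w": TensorSymmetry.FULL_REAL,
}
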