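"""Brute-force numeric verification backend.

Every symbolic identity in the package can be checked against dense matrix
representations of the operators on a tiny Fock space: a Jordan–Wigner
ladder construction for fermions over ≤ 4 spatial orbitals, a truncated
ladder for the photon mode, and explicit summation of symbolic terms over
all concrete index instantiations under random tensor assignments.

Spin-orbital ordering for the ladder construction is fixed as spatial
index major with α before β (spin orbital ``2p + σ``); all sign strings
follow from that order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .operators import (
    ALPHA,
    BETA,
    BosonOp,
    Operator,
    SingletExcitation,
    SpinFermion,
    TripletExcitation,
)
from .spaces import GENERAL, OCCUPIED, VIRTUAL, OrbitalSpace
from .tensors import TensorSymmetry, symmetry_orbit
from .terms import Expression, Term, _as_expression

__all__ = [
    "FockSpaceSpec",
    "dense_operator",
    "hf_vector",
    "oracle_value",
    "random_assignment",
    "fock_matrix_from",
    "u_from_t",
    "L_from_g",
]


@dataclass(frozen=True)
class FockSpaceSpec:
    """A tiny electron ⊗ photon Fock space for dense verification."""

    n_spatial: int
    n_occ: int
    boson_cutoff: int = 0

    def __post_init__(self):
        if self.n_spatial > 4:
            raise ValueError("dense oracle is capped at 4 spatial orbitals")
        if self.n_occ > self.n_spatial:
            raise ValueError("n_occ exceeds n_spatial")

    @property
    def n_spin(self) -> int:
        return 2 * self.n_spatial

    @property
    def fermion_dim(self) -> int:
        return 1 << self.n_spin

    @property
    def boson_dim(self) -> int:
        return self.boson_cutoff + 1

    @property
    def dim(self) -> int:
        return self.fermion_dim * self.boson_dim

    def range_of(self, space: OrbitalSpace) -> range:
        if space is OCCUPIED:
            return range(self.n_occ)
        if space is VIRTUAL:
            return range(self.n_occ, self.n_spatial)
        if space is GENERAL:
            return range(self.n_spatial)
        raise ValueError(f"no concrete range for space {space.name}")


def _creation_matrix(spin_orbital: int, spec: FockSpaceSpec) -> np.ndarray:
    dim = spec.fermion_dim
    mat = np.zeros((dim, dim))
    bit = 1 << spin_orbital
    for state in range(dim):
        if state & bit:
            continue
        sign = 1.0 if bin(state & (bit - 1)).count("1") % 2 == 0 else -1.0
        mat[state | bit, state] = sign
    return mat


def _boson_creation(spec: FockSpaceSpec) -> np.ndarray:
    n = spec.boson_dim
    mat = np.zeros((n, n))
    for m in range(n - 1):
        mat[m + 1, m] = np.sqrt(m + 1.0)
    return mat


class _MatrixCache:
    def __init__(self):
        self._cache: dict[tuple, np.ndarray] = {}

    def get(self, key, build):
        m = self._cache.get(key)
        if m is None:
            m = build()
            self._cache[key] = m
        return m


_cache = _MatrixCache()


def _fermion_matrix(p: int, spin: int, dagger: bool, spec: FockSpaceSpec):
    key = ("a", spec.n_spatial, p, spin, dagger)

    def build():
        c = _creation_matrix(2 * p + spin, spec)
        return c if dagger else c.T

    return _cache.get(key, build)


def _embed(fermion_part, boson_part, spec: FockSpaceSpec) -> np.ndarray:
    return np.kron(fermion_part, boson_part)


def dense_operator(op: Operator, spec: FockSpaceSpec, values=None) -> np.ndarray:
    """Dense matrix of a single operator on the full electron ⊗ photon
    space.  ``values`` maps symbolic index ordinals to concrete 0-based
    spatial orbitals (unneeded when the operator's indices are already
    concrete integers ≥ 0 — operators built for the oracle use concrete
    indices directly)."""
    values = values or {}

    def conc(i: int) -> int:
        return values.get(i, i)

    eye_b = np.eye(spec.boson_dim)
    if isinstance(op, SingletExcitation):
        p, q = conc(op.p), conc(op.q)
        key = ("E", spec.n_spatial, p, q)

        def build():
            m = np.zeros((spec.fermion_dim, spec.fermion_dim))
            for s in (ALPHA, BETA):
                m += _fermion_matrix(p, s, True, spec) @ _fermion_matrix(
                    q, s, False, spec
                )
            return m

        return _embed(_cache.get(key, build), eye_b, spec)
    if isinstance(op, TripletExcitation):
        p, q = conc(op.p), conc(op.q)
        key = ("tau", spec.n_spatial, p, q)

        def build():
            return _fermion_matrix(p, ALPHA, True, spec) @ _fermion_matrix(
                q, ALPHA, False, spec
            ) - _fermion_matrix(p, BETA, True, spec) @ _fermion_matrix(
                q, BETA, False, spec
            )

        return _embed(_cache.get(key, build), eye_b, spec)
    if isinstance(op, SpinFermion):
        return _embed(
            _fermion_matrix(conc(op.p), op.spin, op.dagger, spec), eye_b, spec
        )
    if isinstance(op, BosonOp):
        b = _boson_creation(spec)
        return _embed(
            np.eye(spec.fermion_dim), b if op.dagger else b.T, spec
        )
    raise TypeError(f"no dense representation for {type(op).__name__}")


def hf_vector(spec: FockSpaceSpec) -> np.ndarray:
    """The closed-shell HF ⊗ photon-vacuum reference vector, built by
    applying the creation operators of the occupied spin orbitals to the
    vacuum (so its global sign is convention-consistent)."""
    vac = np.zeros(spec.dim)
    vac[0] = 1.0
    vec = vac
    for i in range(spec.n_occ):
        for spin in (BETA, ALPHA):
            vec = dense_operator(SpinFermion(i, spin, True), spec) @ vec
    return vec


# ---------------------------------------------------------------------
# numeric evaluation of symbolic expressions
# ---------------------------------------------------------------------


def _tensor_entry(assignment, name, idx):
    arr = assignment[(name, len(idx))]
    if len(idx) == 0:
        return float(arr)
    return arr[idx]


def oracle_value(
    a,
    assignment: dict,
    spec: FockSpaceSpec,
    free_values: dict[int, int] | None = None,
):
    """Evaluate a symbolic expression numerically.

    Sums each term over all concrete instantiations of its summation
    indices within their constrained spaces, multiplying tensor entries
    (from ``assignment``, keyed ``(name, arity)``) and dense operator
    matrices.  Free indices take the concrete values in ``free_values``.
    Returns a scalar for operator-free expressions, else a dense matrix.
    """
    a = _as_expression(a)
    free_values = dict(free_values or {})
    has_ops = any(t.operators for t in a)
    total = np.zeros((spec.dim, spec.dim)) if has_ops else 0.0
    for t in a:
        n_bdag = sum(
            1 for o in t.operators if isinstance(o, BosonOp) and o.dagger
        )
        if n_bdag > spec.boson_cutoff:
            raise ValueError(
                f"boson cutoff {spec.boson_cutoff} too small for a string "
                f"with {n_bdag} photon creations (norm would leak)"
            )
        free = t.free_indices()
        missing = free - set(free_values)
        if missing:
            raise ValueError(f"no concrete values for free indices {sorted(missing)}")
        # skip instantiations where a free index violates its constraint
        if any(
            free_values[i] not in spec.range_of(t.space_of(i)) for i in free
        ):
            continue
        sums = t.sum_indices
        ranges = [spec.range_of(t.space_of(i)) for i in sums]
        for combo in itertools.product(*ranges):
            val = dict(free_values)
            val.update(zip(sums, combo))
            if any(len({val[i] for i in d}) != 1 for d in t.deltas):
                continue
            coeff = float(t.scalar)
            for ref in t.tensors:
                coeff *= _tensor_entry(
                    assignment, ref.name, tuple(val[i] for i in ref.indices)
                )
                if coeff == 0.0:
                    break
            if coeff == 0.0:
                continue
            if t.operators:
                mat = np.eye(spec.dim)
                for o in t.operators:
                    mat = mat @ dense_operator(o, spec, val)
                total = total + coeff * mat
            elif has_ops:
                # an operator-free term acts as a multiple of the identity
                total = total + coeff * np.eye(spec.dim)
            else:
                total += coeff
    return total


# ---------------------------------------------------------------------
# random tensor assignments
# ---------------------------------------------------------------------


def _symmetrize_array(arr: np.ndarray, symmetry: TensorSymmetry) -> np.ndarray:
    if symmetry == TensorSymmetry.NONE or arr.ndim == 0:
        return arr
    n = arr.ndim
    slots = tuple(range(n))
    out = np.zeros_like(arr)
    count = 0
    for perm in symmetry_orbit(slots, symmetry):
        out = out + arr.transpose(perm)
        count += 1
    # summing over the orbit (not averaging) keeps integer entries exact
    return out


def random_assignment(
    rng: np.random.Generator,
    spec: FockSpaceSpec,
    tensors: list[tuple[str, int, TensorSymmetry]],
    low: int = -3,
    high: int = 4,
) -> dict:
    """Random small-integer tensors respecting their symmetry classes."""
    out = {}
    n = spec.n_spatial
    for name, arity, sym in tensors:
        if arity == 0:
            out[(name, 0)] = float(rng.integers(low, high))
            continue
        arr = rng.integers(low, high, size=(n,) * arity).astype(float)
        out[(name, arity)] = _symmetrize_array(arr, sym)
    return out


def fock_matrix_from(assignment: dict, spec: FockSpaceSpec) -> np.ndarray:
    """The Fock matrix consistent with an (h, g) assignment:
    ``F_pq = h_pq + Σ_i (2 g_pqii − g_piiq)``."""
    h = assignment[("h", 2)]
    g = assignment[("g", 4)]
    occ = range(spec.n_occ)
    f = h.copy()
    for i in occ:
        f += 2.0 * g[:, :, i, i] - g[:, i, i, :]
    return f


def u_from_t(t: np.ndarray) -> np.ndarray:
    """``u_aibj = 2 t_aibj − t_ajbi`` (slots 1 and 3 swapped)."""
    return 2.0 * t - t.transpose(0, 3, 2, 1)


def L_from_g(g: np.ndarray) -> np.ndarray:
    """``L_pqrs = 2 g_pqrs − g_psrq``."""
    return 2.0 * g - g.transpose(0, 3, 2, 1)
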