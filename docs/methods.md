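# Methods

## Model and scope

`spinsq` implements a term algebra over second-quantization operators
for a closed-shell electronic reference, optionally coupled to a single
bosonic (cavity-photon) mode.  A **Term** is

    scalar × (Kronecker deltas) × (tensors) × (ordered operator string),

together with the list of summed indices and a map from index to
orbital space; an **Expression** is a canonically sorted collection of
terms fused up to their scalars.  Scalars are exact rationals
(`fractions.Fraction`); floating-point scalars are rejected because
round-off would break the exact cancellations the whole calculus
depends on.

Indices are abstract positive integers.  Which orbitals an index runs
over lives in the per-term constraint map over three built-in spaces:
`general`, with the disjoint subspaces `occupied` and `virtual`.
Constraints to the general space are implicit and never stored.
Printing maps (space, within-space rank) to the conventional letters
(p, q, r, … general; i, j, … occupied; a, b, … virtual).

Operator kinds: the singlet excitation `E_pq = Σ_σ a†_pσ a_qσ`, the
m_l = 0 triplet `τ_pq = a†_pα a_qα − a†_pβ a_qβ`, elementary spin-orbital
fermions `a†_pσ / a_pσ`, and photon ladder operators `b† / b`.  The
two-electron operator `e_pqrs = E_pq E_rs − δ_qr E_ps` is an alias
expansion, not a kind of its own.

## Commutator calculus

All projections and similarity transforms reduce to the *reductive
commutator* `[A,B]_Γ = AB + Γ·BA`.  The sign is `Γ = +1` (the
anticommutator) exactly when both operators are elementary fermions and
`Γ = −1` otherwise — the choice that always lowers the operator rank.
String commutators are reduced with

    [AB,C]_Γ = A[B,C]_Γ₁ − Γ₁·[A,C]_Γ₂ B,   Γ = −Γ₁Γ₂
    [A,BC]_Γ = [A,B]_Γ₁ C − Γ₁·B[A,C]_Γ₂,   Γ = −Γ₁Γ₂

using a fixed schedule (split the last operator of the left string, the
first of the right), so a commutator between strings of lengths m and n
performs exactly m·n single-operator kernel evaluations — an invariant
the test suite asserts with an instrumented counter that remains exact
under commutator memoization (cache hits add their stored kernel
count).

Two details are worth calling out:

* **Plain commutators of odd-fermion strings.**  When both strings have
  odd fermion parity the reductive commutator is the anticommutator, and
  the plain commutator needs an uncontracted product correction,
  `[A,B] = [A,B]₊ − 2BA`.  The pair is first oriented by its canonical
  term order so that `[a,b]` and `[b,a]` are built as exact symbolic
  negations; without this, antisymmetry would hold only numerically,
  because the recursion leaves residual operator strings in an
  orientation-dependent (though equivalent) order.
* **BCH expansion** `e^{−B}Ae^{B} = Σ_k (1/k!)·[…[A,B],…,B]` stops early
  when a nested commutator vanishes; for the electronic Hamiltonian
  with excitation cluster operators the series has exactly five nonzero
  orders.

`act_on_ket` implements the recursion

    A₁…Aₙ|ref⟩ = −Γ·Ãₙ(A₁…Aₙ₋₁|ref⟩) + [A₁…Aₙ₋₁, Ãₙ]_Γ|ref⟩

with per-kind base cases on the closed-shell HF ⊗ photon-vacuum
reference (`E_pq → 2δ_pq` occupied-diagonal plus a constrained
excitation; `τ_pq` survives only as a pure excitation; `a/a†` survive
with occupied/virtual constraints; `b` annihilates the vacuum).  A rank
cap discards every intermediate branch whose already-emitted operators
exceed the target excitation level.  Open-shell references are built by
multiplying explicit `a†`/`a` operators into the string, not by
changing the reference.

## Canonicalization

`canonicalize` drives each term to a unique normal form:

1. overlapping deltas merge (equality is transitive); a delta whose
   members' constrained spaces have empty intersection annihilates the
   term; deltas with coincident indices are trivially true and dropped;
2. summed delta members are substituted through the term (free members
   are preferred as representatives) and removed from the sum list,
   with the intersected space constraint attached to the survivors;
3. free indices sharing a delta are renamed, outside the delta itself,
   to the delta's lowest index;
4. summation indices are relabelled to the lowest unused ordinals;
5. among the permutations of summation indices *within compatible
   spaces*, the labelling minimizing the term's lexicographic key is
   chosen (tensor-symmetry index sorting re-applied per candidate; ties
   break to the first permutation in enumeration order).

Step 5 scales factorially, so it is tiered.  Below
`exact_permutation_cap` (default 24 candidates) all within-space
permutations are enumerated, giving the true lexicographic minimum —
the regime in which the exhaustive-relabelling test oracle operates.
Above it, indices are first partitioned into *interchangeability cells*
by an iterated structural colouring (a Weisfeiler–Lehman-style
refinement over the tensor slots, deltas and operator positions an
index occupies, with slot descriptors reduced to what the tensor's
symmetry class leaves invariant), and only within-cell permutations are
enumerated.  Cell-based labelling is deterministic and invariant under
relabelling — which is all that term fusion requires — though not
guaranteed to be the global key minimum.  Both tiers depend only on the
term itself, so equal terms always take the same path.  Above
`permutation_cap` (default 10!) a greedy first-occurrence ordering is
used and a warning flags the term as non-canonical.

Expression fusing additionally applies a disjoint-subspace pass:
`s·Σ_occ X + s·Σ_vir X → s·Σ X` and `s·Σ X − s·Σ_S X → s·Σ_S̄ X`.
Without it, derived expressions retain split general-space sums and
neither the exchange-pattern recognition nor the familiar fused forms
(e.g. the Fock cancellation that collapses the CCS singles residual to
`F_ai`) are reachable.

Total term order for sorting: (operator-string key, tensor key, delta
key, constraint key, summation arity).  Any total order would do; this
one groups like operator structures.

## Tensor symmetries and transforms

Three signless symmetry classes: none; pair-permutation (2n-index
tensors whose neighbouring index pairs permute as blocks, n!
orderings — two-electron integrals, cluster amplitudes); full-real
(additionally each pair flips, n!·2ⁿ orderings).  Canonical storage
sorts pairs (and pair members, for full-real) ascending.

`look_for_tensor_replacements` rewrites the recurring `2X − X^T`
pattern with a combination tensor (`L_pqrs = 2g_pqrs − g_psrq`,
`u_aibj = 2t_aibj − t_ajbi`, and the higher-rank analogues produced by
`exchange_rule(n)`, which transpose the occupied slots of the last two
pairs — under pair-permutation symmetry any other pair choice is
conjugate to that one).  The search is a greedy fixed-point scan over
the canonically sorted pool; a term whose transposed image
canonicalizes onto its own body is rewritten with an *unchanged*
scalar, since in that case `Σ L X = Σ (2g − g^T) X = Σ g X` — the
choice fixed by requiring that expanding a replacement restores the
original expression exactly (a tested invariant).

`desymmetrize` splits a block into one representative per mirror orbit
(scaled by 1/|stabilizer| so that re-symmetrizing restores the orbit),
the terms invariant under every pair permutation, and leftovers with
neither partner nor invariance.  The reconstruction identity
`symmetrize(redundant) + self_symmetric + leftover = input` is tested
on random symmetric inputs.

## Biorthogonal projection

Amplitude residuals are extracted by projecting the acted expression on
biorthogonal bras defined through a template ket of singlet
excitations: the k-th surviving excitation `E_ck` of a matching-rank
term is contracted through `δ_ac δ_ik` against the template's k-th pair,
and `symmetrize` over the template pairs realizes the permutation sum
of the biorthogonality condition.  For singles and doubles this is
verified against the explicit bras `⟨HF|½E_ia` and
`⟨HF|(⅓E_ia E_jb + ⅙E_ja E_ib)`; for triples and beyond the explicit
bra cannot be written with singlet excitations, so the template route
is the only implemented path.  The diagonal biorthonormalization factor
`1/(1+δ_ij δ_ab)` is kept as an annotation applied numerically by the
code generator rather than folded into the symbolic result.

## The coupled-cluster pipeline

`derive_cc_ground_state(level)` uses the Fock-form Hamiltonian
(`h_pq = F_pq − Σ_i(2g_pqii − g_piiq)`, unsymmetric one-electron tensor
and pair-permutation two-electron integrals, as appropriate for
T₁-transformed quantities) and a cluster operator without single
excitations.  Pipeline: BCH to fourth order → `act_on_ket` capped at
the truncation level → per-block biorthogonal projection →
symmetrization → desymmetrization → exchange-combination replacement.

Applying the replacements *after* desymmetrization is the default: it
yields the fully fused per-block counts, and the totals then grow by
1, 21 and 40 finalized terms at the singles, doubles and triples
truncations.  The opposite order (`finalize_order="u_then_desym"`) is
kept as a switch; it leaves a nonzero "nonsymmetric" leftover in the
doubles block because the replacement tensors hide the pair symmetry —
the leftover is verified to be symmetric once re-expanded in the bare
amplitudes.  At the quadruples stretch level the shipped rule family
stops short: patterns involving more than one occupied-pair swap are
not recognized, and the count comes out correspondingly higher;
automatic detection of such hidden symmetries is out of scope.

Two exact-result optimizations keep the derivation fast (CCSDT in well
under a minute on one core): commutator memoization between canonical
terms, and a rank lower bound (`_rank_bound2`) used to drop terms
between BCH nestings as well as before the ket projection.  The bound
counts constrained pure excitations and `b†` as necessarily surviving
and lets every other operator de-excite by at most its own rank; it
never decreases under further commutators with a T₁-free cluster
operator, which is what makes inter-nesting pruning sound.  The pruned
and unpruned pipelines are asserted identical at CCSD in the tests.

## Numeric oracle

Every kernel, base case and derived quantity is checked against dense
matrices on tiny Fock spaces (≤ 4 spatial orbitals; 2–3 in the tests,
so occupied/virtual blocks of size 1–2): Jordan–Wigner ladder matrices
with spatial-major, α-before-β spin-orbital ordering, a truncated
photon ladder, and exhaustive index summation of symbolic terms under
random small-integer tensor assignments (symmetrized by summing over
the class orbit, which keeps entries integral).  Checks involving
photon operators either project out the top ladder level, where a
truncated `[b,b†] = 1` cannot hold, or choose the cutoff so that every
photon-number path contributing to the projected element stays inside
the truncated space — the projected QED matrix elements are then exact,
not approximate.  Similarity transforms are cross-checked against
`expm(−T)·H·expm(T)` built with SciPy's matrix exponential.

These fixtures exercise every algebraic path (all space combinations
and contraction patterns appear already at 1 occupied + 2 virtual
orbitals), but they are not stand-ins for real molecular data: no
statement about basis sets, convergence or the numerical behaviour of
the generated code at realistic dimensions follows from them.

## Code generation

Finalized, operator- and delta-free expressions map term-by-term onto
`np.einsum` contractions: occupied/virtual constraints become 0-based
half-open slices `[0, no)` and `[no, no+nv)` of the molecular-orbital
dimension; amplitudes are passed as pre-sliced blocks (`t_vovo`) while
integral tensors are passed whole and sliced inside; summed indices
absent from every tensor multiply by their block dimension; free
indices absent from every tensor broadcast along ones.  Exact rational
prefactors are emitted as integer ratios.  Per-term contraction order
is delegated to einsum's optimizer; common intermediates are
deliberately not shared across terms, and delta-bearing terms are
rejected — both documented limitations.  Emission follows the canonical
term order, so generated text is reproducible.

## Rendering

Terms print as
`<sign><rational> ∑_{indices}( deltas tensors operators ) constraints`
with an ASCII dialect mirroring every glyph.  A constraint clause
`C(a∈v)` is printed only for an index that appears nowhere else in the
term (the letter itself encodes the space otherwise).  A small parser
exists solely to support round-trip tests; tensor symmetry classes are
not part of the printed form and are supplied to the parser as a map.
The raw ordinal interleaving of free indices across spaces is likewise
not printable, so the parser normalizes free indices to the
excitation-template convention (virtual/occupied letters alternating
pairwise); rendered derivation output is then an exact fixed point of
parse ∘ render, and arbitrary expressions reach the fixed point after
one normalizing pass.

## Defaults worth knowing

| Parameter | Default | Meaning |
|---|---|---|
| `permutation_cap` | 10! | candidates before the greedy fallback |
| `exact_permutation_cap` | 24 | candidates below which the search is exhaustive |
| `memoize_commutators` | on | cache term-pair commutators (kernel counts preserved) |
| `term_limit` | 10⁶ | abort guard for runaway derivations |
| BCH order | 4 | last nonzero order for the electronic Hamiltonian |
| boson cutoff (oracle) | 0–3 | photon-number truncation of the dense ladder |

## Known limitations

* No Wick's-theorem normal ordering; projection goes exclusively
  through the commutator/`act_on_ket` route.
* Code generation handles neither Kronecker deltas nor cross-term
  intermediate reuse.
* Hidden symmetries created by replacement tensors are surfaced (as
  desymmetrization leftovers), not solved.
* The dense oracle is capped at 4 spatial orbitals and one boson mode.
* Cell-based canonicalization above the exact tier is
  relabelling-consistent but not provably key-minimal; the greedy
  fallback above the cap is flagged non-canonical via a warning.
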