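# spinsq

Symbolic second quantization for electronic-structure theory, working
directly with **spin-adapted** operators.

Deriving the working equations of wave-function methods — coupled
cluster above all — by hand means evaluating long chains of commutators
between second-quantization operators and projecting them on reference
and excited states.  `spinsq` automates exactly that calculus, staying
close to the pen-and-paper route instead of normal-ordering through
Wick's theorem: expressions are sums of terms
`scalar × δ's × tensors × operator string`, commutators are evaluated
with a *reductive commutator* `[A,B]_Γ = AB + Γ·BA` whose sign `Γ` is
chosen per operator pair so the result always has lower operator rank,
and projections use an `act_on_ket` recursion

    A₁…Aₙ|HF⟩ = −Γ·Ãₙ(A₁…Aₙ₋₁|HF⟩) + [A₁…Aₙ₋₁, Ãₙ]_Γ|HF⟩

that replaces each operator by its simplified image on the closed-shell
Hartree–Fock ⊗ photon-vacuum reference (for the singlet excitation
operator, `E_pq|HF⟩ = 2δ_pq|HF⟩` for p,q occupied plus `E_pq|HF⟩` for
p virtual, q occupied).  Because everything is spin-summed from the
start — `E_pq`, the triplet `τ_pq`, two-electron `e_pqrs` — derived
equations come out directly over spatial-orbital tensors, with exact
rational coefficients throughout.

The package is aimed at method developers who want to derive, inspect
and numerically verify electronic-structure equations (Hartree–Fock
energy, CC amplitude equations up to arbitrary truncation,
electron–photon QED-CC contributions, open-shell references built from
explicit `a†`/`a` operators) and to turn finalized scalar expressions
into runnable numpy einsum code.

## Worked example: CCSD in a few lines

```python
import spinsq as sq

# similarity-transformed Hamiltonian, Fock-matrix form, T = T2
h    = sq.build_hamiltonian("fock_g")
t2   = sq.build_cluster(2, include_t1=False)
hbar = sq.bch_expand(h, t2, 4)           # BCH truncates after 5 terms

acted = sq.act_on_ket(hbar, max_rank=2)  # project on the reference ket
corr  = sq.hf_expectation(hbar) - sq.hf_expectation(h)
print(sq.render_expression(
    sq.look_for_tensor_replacements(corr, sq.U_RULE)))
```

prints the closed-shell correlation energy in its familiar one-term
form (`u_aibj = 2t_aibj − t_ajbi`):

```
+1 ∑_{ijab}( g_iajb u_aibj )
```

The full derivation pipeline — biorthogonal projection through template
kets (`⟨ijãb|klcd⟩ = P^{ab}_{ij} δ_ac δ_bd δ_ik δ_jl`), symmetrization
over excitation pairs, desymmetrization into redundant /
self-symmetric / leftover parts and exchange-combination recognition —
is packaged as one call:

```python
rep = sq.derive_cc_ground_state(2)
print(rep.counts)        # {'energy': 1, 'singles': 4, 'doubles': 17}
print(sq.render_expression(rep.blocks["singles"]))
```

```
+1 ( F_ai )
+1 ∑_{jb}( F_jb u_aibj )
+1 ∑_{jbc}( g_abjc u_bicj )
-1 ∑_{jkb}( g_jikb u_ajbk )
```

Counting finalized terms across all blocks, each truncation level adds
**1** new term at CCS, **21** at CCSD and **40** at CCSDT (cluster
operator without T₁, whose effect is absorbed into the integrals).

The same machinery is exposed on the command line:

```
spinsq derive cc --level 2 --report
spinsq derive hf-energy
spinsq codegen --block doubles-redundant --explicit t,u --out omega.py
```

The generated `omega.py` is a plain numpy function, one einsum per
term, with occupied/virtual sub-blocks sliced from the full
molecular-orbital tensors (amplitudes are passed pre-sliced, e.g.
`t_vovo`).

Every symbolic identity in the package is backed by a dense brute-force
oracle (`spinsq.oracle`): operators as explicit matrices over a tiny
Fock space (≤ 4 spatial orbitals, truncated photon ladder), expressions
evaluated by exhaustive index summation under random tensor
assignments — including a full check of the CCSD residuals and the
QED bilinear singles against `e^{-T} H e^{T}` built with matrix
exponentials.

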