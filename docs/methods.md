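# Methods

This note documents the model implemented by `symkron`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## Problem and data model

The observed data are a bipartite network: a binary adjacency
`A (nd × nm)` of experimentally verified disease–miRNA associations, a
disease hierarchy given as child→parent edges (MeSH-like; each disease's
DAG is its ancestor closure), and optionally a precomputed miRNA
functional-similarity matrix. All matrices are labeled; diseases index
rows, miRNAs index columns, and `vec(·)` is column-stacking throughout.
Scores are computed for *every* pair, so the output is a dense `nd × nm`
real matrix ranking unobserved pairs.

## Similarity layer

**Semantic similarity (diseases).** Model 1 assigns each node `t` of the
disease's DAG a contribution `D_d(t)`: 1 at the disease itself, otherwise
`max{Δ·D_d(c)}` over `t`'s children inside the DAG, so the contribution is
`Δ^depth` along the best path. Model 2 replaces the depth decay by an
information-content weight `−log(n_t/nd)` where `n_t` counts the modeled
diseases whose DAG contains `t` — a parent shared by every disease carries
no information. Both models score a pair by the shared-ancestor mass
normalized by the two semantic values, and the final `SS` is their plain
average. Δ defaults to 0.5 (the value conventional in this similarity
family; it is exposed as a parameter). The model-2 logarithm base is
irrelevant (numerator and denominator scale together); natural log is
used. Two deliberate totalizations:

* a 0/0 pair (both semantic values zero, possible in model 2 when both
  diseases occur in every DAG) is defined as 1 on the diagonal and 0 off
  it, preserving the unit-diagonal convention of the average;
* diseases absent from the hierarchy keep a unit diagonal and zero
  off-diagonal semantic similarity; the integration step still averages
  with the Gaussian kernel, which is the reason the kernel exists — it
  covers diseases the ontology does not.

**Functional similarity (miRNAs).** The group-max rule over the two
miRNAs' associated-disease sets `D1, D2`:
`(Σ_{d∈D1} max_{e∈D2} SS(d,e) + Σ_{d∈D2} max_{e∈D1} SS(d,e)) / (|D1|+|D2|)`,
computed against the combined `SS`. A supplied precomputed matrix takes
precedence; miRNAs with no association get zero off-diagonal similarity.

**Gaussian interaction-profile kernels.** `exp(−γ‖IP_i−IP_j‖²)` on rows
(KD) and columns (KM) of `A`, with `γ = γ′ / mean(‖IP‖²)` over the axis
and `γ′ = 1` by default. An all-zero adjacency leaves the bandwidth
undefined and is rejected. The kernels are exactly 1 on the diagonal and
symmetrized against rounding.

**Integration.** `SD = (SS+KD)/2`, `SM = (FS+KM)/2`, entrywise.

## SymNMF interpolation

`SD ≈ PPᵀ` with `P ≥ 0`. Starting from a positive random `P⁰`, each
iteration forms `R = (SD·P) ⊘ (P PᵀP)` (denominator floored at 1e−12) and
the damped candidate `P ∘ (1−α+α·R)` with α = 0.999; the candidate is kept
only if it lowers the squared Frobenius residual `E = ‖SD − PPᵀ‖²_F`,
otherwise the cube-root update `P ∘ R^{1/3}` — the classical monotone
multiplicative update for this objective — is taken. The run stops at
`max_iter` (default 500) or when the relative residual change drops below
`tol` (default 1e−6). The residual compared at each step is of course
`‖SD − P_new P_newᵀ‖²_F`; the fallback is accepted unconditionally, per
the scheme's control flow. Numerical notes:

* **Rank.** Default is full rank (square `P`), the configuration the
  method is normally run in; low-rank overrides exist and are used by the
  synthetic tests where an exact factorization is planted.
* **Initialization.** Entries uniform on `(0, √(mean(SD)/r)]` so the
  initial residual is scale-matched. Each row's random stream is keyed by
  (seed, CRC32 of the row's id) rather than drawn flat: this makes the
  whole interpolation equivariant under relabeling/reordering of the
  input — permuting the inputs permutes `PPᵀ` (up to float summation
  order) — while remaining exactly reproducible from the seed.
* **Convergence speed.** Near a fixed point the damped candidate
  contracts the error oscillation by only `≈ 2α−1` per step, so with
  α = 0.999 tight convergence takes thousands of iterations; at the
  default 500 iterations the factorization is an approximation
  (relative residual ~0.3 % on the benchmark's `SD`), which is the
  denoising behaviour wanted here, not an exact recovery. Tests that
  check the exact scalar fixed point use a larger iteration budget.

The product `PPᵀ` — symmetric and PSD by construction — replaces the raw
integrated similarity downstream and is *not* renormalized to a unit
diagonal.

## Kronecker RLS

The pairwise kernel is `K = SD* ⊗ SM*` over all `nd·nm` pairs, and the
scores solve the kernel ridge problem `vec(S) = K(K+λI)⁻¹vec(A)` with
λ = 1 by default. With the side eigendecompositions
`SD* = V_d Λ_d V_dᵀ`, `SM* = V_m Λ_m V_mᵀ`, the solution is computed as
`C = V_mᵀ Aᵀ V_d`, `Z = W ∘ C` with the `nm × nd` shrinkage table
`W_ij = λm_i λd_j/(λm_i λd_j + λ)`, and `S = V_d Zᵀ V_mᵀ`. `K` itself is
never formed; a dense solver that does form it exists purely as a
small-problem test oracle (≤ 2000 pairs) and the two agree to ~1e−15 on
random instances. Side-kernel eigenvalues are clipped at zero (SymNMF
output is PSD up to rounding); if interpolation is bypassed and an
indefinite similarity supplied, negative eigenvalues are used as-is with
a warning. With both kernels PSD every spectral coefficient of the map
`A ↦ S` lies in `[0, 1)`, so `‖S‖_F ≤ ‖A‖_F` and coefficients shrink
monotonically in λ (individual *entries* of `S` need not — eigenbasis
mixing can raise one locally, which is why the tests assert monotonicity
of the spectral coefficients and of the norm).

## Cross-validation protocols

Global LOOCV removes each known association in turn and ranks its score
against all pairs with no verified association; local LOOCV restricts the
pool to the studied disease's unverified pairs; repeated k-fold shuffles
the positives (per-repeat seed = base seed + repeat index), masks each of
k near-equal parts in turn, and reports mean ± std of the per-repeat AUC.
Each test sample is reduced to its percentile within its own fold's pool
(midrank ties); the pooled AUC is the mean percentile — exactly the
Mann–Whitney statistic per fold — and the ROC curve sweeps a shared
percentile threshold grid. Pools never contain the test pair or any
training positive.

**Leakage.** Whether the adjacency-dependent quantities (KD, KM, internal
FS, SD, SM, SymNMF) are recomputed with the test associations removed is a
protocol choice with a large effect. Both modes are first-class:

* `refresh_kernels = refresh_symnmf = True` (default) recomputes
  everything per fold — the leakage-free protocol. On the synthetic
  benchmark it yields global LOOCV AUC ≈ 0.73 with a shuffled-null AUC of
  ≈ 0.47 (slightly *below* 0.5: deleting the test edge shrinks the test
  pair's own kernel profiles, a known removal bias).
* Both flags `False` freezes the similarity layer at its full-data values
  — the cheaper protocol common in this literature. It inflates AUC
  dramatically (≈ 0.96 on the benchmark, and ≈ 0.95 even on the shuffled
  null) because the held-out association remains embedded in the kernels.
  Numbers from this mode measure reconstruction, not prediction.

Semantic similarity depends only on the disease list, never on `A`'s
values, and is computed once.

The new-disease protocol zeroes the studied disease's entire row of `A`,
recomputes every `A`-dependent stage, and ranks that disease's miRNAs.

## Synthetic benchmark

The generator plants the structure the model assumes: diseases and miRNAs
are assigned (balanced, seeded) to `n_blocks` latent communities; a true
association appears with `within_block_prob` when the blocks match and
`background_prob` otherwise; `mask_fraction` of the truth is withheld
uniformly, and the observed network is truth minus mask. The hierarchy is
a rooted forest with one tree per block whose *nodes are the diseases*,
filled level-by-level with the given branching and depth — so semantic
similarity is informative about blocks (zero across blocks, decaying
within). The frozen benchmark uses 30 diseases × 40 miRNAs, 3 blocks,
within/background 0.35/0.02, depth 3, branching 3, mask 0.2 — small
enough that the full leakage-free LOOCV battery runs in seconds per
dataset on one CPU, which is the problem size the shipped evaluation
scripts use.

What it does not emulate: real MeSH topology (multiple parents, deep
unbalanced trees), the heavy-tailed degree distribution of curated
association databases, literature-driven ascertainment bias, and
similarity noise uncorrelated with the association process. Passing the
benchmark therefore shows the pipeline recovers the structure it assumes
when that structure is present — not that it attains any particular
accuracy on curated human data.

## Known limitations

* Dense eigendecomposition limits problem sizes to a few thousand per
  side; no iterative KronRLS backend is provided.
* The SymNMF objective is non-convex; different seeds give different
  (equally valid) factors. All shipped entry points are seeded.
* Scores are relative ranks, not calibrated probabilities, and diseases
  or miRNAs with many known associations tend to receive systematically
  higher scores — a property of the kernel construction itself.
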