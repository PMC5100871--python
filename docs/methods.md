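# Methods

## Model

`gendom` simulates constant viability selection at one autosomal diploid
locus in a randomly mating population.  Genotype `A_iA_j` has viability

    w_ij = α_ij (X_i + X_j) + (1 − 2 α_ij) Y_ij

built from per-allele primary effects `X_i`, genotype-specific
interaction effects `Y_ij = Y_ji`, and a weighting `α_ij ∈ [0, ½]`.  All
sampled effects are i.i.d. uniform on [0, 1], which bounds every `w_ij`
in [0, 1].  The weighting controls how strongly fitness is determined by
the alleles themselves: at `α = 0` genotype fitnesses are mutually
independent, at `α = ½` they are exactly additive in the primary
effects.  Two genotypes sharing one allele have fitness correlation
`α²/(1 − 4α + 6α²)` (0 at independence, ½ at additivity); the Monte-Carlo
test suite verifies this against direct sampling of the construction.

Allele frequencies follow the deterministic recurrence
`p_i' = p_i (Σ_j w_ij p_j)/w̄`.  Under constant viabilities mean fitness
`w̄` is non-decreasing along trajectories and any fully polymorphic
equilibrium is globally stable; both facts are exploited below and
asserted as properties in the tests.

**Homozygote interactions.**  The fitness expression needs `Y_ii` for
homozygotes.  We sample `Y_ii ~ U[0,1]` exactly like the off-diagonal
interactions, so `w_ii = 2αX_i + (1 − 2α)Y_ii` spans [0, 1].  The
alternative (no interaction term for homozygotes) would cap every
homozygote fitness at `2α`, a severe and unmotivated asymmetry;
moreover the random-α analyses need a homozygote weighting `α_ii` to
exist.  This is a deliberate modeling choice.

## Parameter-space approach (potential for polymorphism)

For fixed `n` and `α`, `estimate_potential` draws random fitness sets
(`X`, `Y` uniform), one broken-stick initial frequency vector per set
(uniform on the simplex: sorted `U[0,1]` breakpoints, successive
differences), and iterates the recurrence.  Termination rules, applied
in this order each generation:

* **allele lost** — any frequency `< 10⁻⁵` (also checked on the initial
  vector);
* **full polymorphism** — L1 frequency change `< 10⁻⁸` with all alleles
  at or above the extinction tolerance;
* **cap reached** — after 10⁶ generations (counted as *not*
  polymorphic).

One start per fitness set suffices because interior equilibria of this
system are globally stable.  An independent linear-algebra route
(`internal_equilibrium_oracle`) cross-checks the classification: the
interior equilibrium candidate is `p ∝ W⁻¹1` (equal marginal fitnesses),
admissible iff strictly positive, stable iff `W` has exactly one
positive eigenvalue (negative definiteness on the simplex tangent
space).  Matrices with condition number above 10¹² are reported as
singular with no interior equilibrium — exactly additive matrices with
`n ≥ 3` fall here.  Iteration and oracle agree on 500/500 random 2–4
allele matrices in the acceptance suite.

**Sensitivity at the additive limit.**  At `α = ½` a two-allele set is
directional (the fitter homozygote fixes), but when the two primary
effects are nearly tied selection is extremely weak and the convergence
criterion can fire before the losing allele crosses the extinction
threshold.  Near the boundary the per-generation L1 change is
`≈ p_rare · |X₁ − X₂| / max(X₁, X₂)`, so with the extinction threshold
at 10⁻⁵ the criterion (10⁻⁸) is met whenever the relative primary-effect
gap is below ~10⁻³ — about 10⁻³ of all sets, i.e. on the order of 90–100
"apparent equilibria" per 10⁵ sets, which is what the acceptance run
measures.  This count is an artifact of finite thresholds, not true
polymorphism, and it depends strongly on the iteration budget: with a
cap near 2×10⁴ generations most of these slow near-ties would be cut off
and only single digits would remain.  We keep the generous 10⁶ cap and
report the count as measured, flagging cap-limited runs separately.

## Constructionist approach

Each replicate starts monomorphic: founder allele `A_1` at frequency 1
with `X₁ = Y₁₁ = ½`, which pins the founder homozygote fitness at ½ for
*every* weighting and mode (any other founder pair satisfying
`w₁₁ = ½` would have to be re-solved per α).  Per generation, in order:

1. **mutation** — a novel allele enters at frequency 10⁻⁴ (or `1/(2N)`
   with drift), its `X`, `Y` column and (in random-α mode) `α` column
   freshly drawn; one resident allele, chosen with probability
   proportional to its frequency, donates that frequency.  If the donor
   holds less than the mutation frequency (a rare transient), the
   transfer is clamped to the donor's entire holding so the frequency
   simplex is preserved exactly; clamps are counted on the replicate
   record.
2. **selection** — the deterministic recurrence, with a defensive
   renormalization (float drift only, ~10⁻¹⁶ per generation).
3. **drift** (finite `N` only) — multinomial resampling of `2N` gene
   copies with post-selection frequencies as probabilities.
4. **extinction** — alleles strictly below the threshold (10⁻⁴, or
   `1/(2N)` with drift) are removed, with their rows/columns of the
   effect matrices, and the survivors are renormalized.

Mutation-before-selection lets every mutant experience one round of
selection before facing the extinction filter; since the entry frequency
equals the threshold, the filter is a strict `<` (equality survives), so
a neutral-entry mutant is not removed by a tie.  Allele labels are
birth-ordered and never reused; in random-α mode each genotype's
weighting is drawn once, when the genotype first becomes possible, and
kept for the lifetime of the pair.

Defaults are the study conditions: 10⁴ generations, 2000 replicates,
mutation frequency and extinction threshold 10⁻⁴ (infinite N), common
allele cutoff 0.01.  Replicate `r` of a run with base seed `s` uses a
stream derived via `SeedSequence(s, spawn_key=(r,))`, so replicates are
independent, reproducible and order-insensitive (parallelism does not
change results).

### Implementation and verification

The inner loops are numba-compiled.  The compiled kernels use the legacy
Mersenne-Twister generator and consume draws in a documented order that
is stream-identical to `numpy.random.RandomState`; a pure-NumPy
reference implementation composed from the public operations
(`introduce_mutation`, `selection_step`, `drift_step`, `prune_extinct`)
consumes the same stream, and the test suite asserts trajectory-level
agreement between the two backends (exact for integer series and allele
ids, 1e-9 relative for fitness series) in all modes including drift.
The multinomial drift draw is written as the conditional-binomial chain
so it matches `RandomState.multinomial` draw for draw.

## Summary statistics

* **Common alleles**: frequency strictly above 0.01.  Rare alleles
  (often doomed but slow to die, especially at large α) would otherwise
  dominate allele counts and make them threshold-sensitive.
* **Centrality** `I = Σ(p_i − 1/n_c)²` over common alleles, computed on
  the *raw* common frequencies (primary, even though they need not sum
  to 1) and on renormalized frequencies (secondary, labeled as such in
  outputs).  The broken-stick null distribution for `I` uses proper
  simplex vectors; the raw/renormalized asymmetry is intentional and
  both variants are emitted so either comparison can be made.
* **Heterozygote advantage**: among common alleles, the mean fitness of
  heterozygote genotypes versus homozygote genotypes.  The summary
  reports genotype-frequency-weighted means (random-mating weights
  `p_i p_j`, restricted and renormalized) as the primary contrast and
  simple unweighted genotype means as secondary.  The *universal*
  emergence claim (every polymorphic replicate at `α = ⅓`) is asserted
  on the unweighted contrast: the weighted version can fail in a small
  fraction (~0.3%) of replicates caught mid-turnover, where a fitter
  homozygote transiently carries almost all frequency weight.
* **Ensemble mode** of `n_c` breaks ties toward the smaller count and
  sets an explicit tie flag.
* **Random-α dumps** restrict to genotypes whose component alleles are
  all common at the final generation, pooled across replicates.

## What the simulations do and do not emulate

The generator *is* the study system: all inputs are drawn from the
stated uniform distributions, so passing tests certify the dynamics and
bookkeeping of this model, not its realism.  Known idealizations: a
single locus with no linkage or background selection; constant
(frequency-independent) viabilities; exactly one mutant per generation
with fitness effects drawn anew from U[0,1] rather than centered on a
parent allele; no back-mutation or recurrent mutation to existing
alleles; drift only via Wright–Fisher multinomial sampling; dioecy,
random mating and Hardy–Weinberg proportions assumed.  The uniform
mutational-fitness assumption in particular caps fitness at 1 and makes
late successful invasions increasingly rare.

## Numerical choices

* Simplex tolerance 10⁻¹² enforced after every public operation.
* Convergence 10⁻⁸ (L1), extinction 10⁻⁵ (parameter-space) / 10⁻⁴
  (constructionist), iteration cap 10⁶ — see the sensitivity note above.
* Degenerate `w̄ = 0` raises rather than renormalizing silently
  (measure-zero under uniform sampling).
* Oracle singularity guard: condition number > 10¹², eigenvalue
  positivity tolerance 10⁻¹⁰ relative to the spectral radius.
* Acceptance-scale runs use 2000 replicates (≈10–25 s per configuration
  per CPU with the compiled kernels) and 10⁵ fitness sets for the
  additive-limit count; the modal `n_c` at `α = ⅓` is a close race
  between 3 and 4 (≈0.30 vs ≈0.29 of replicates), so modest replicate
  counts can flip it by sampling error.
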