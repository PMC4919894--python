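# Methods

## Model

For a gene measured in `t` tissues on `n` subjects, stack the observed
expression cells as `Y` and write

    Y = Jα + Gβ + Zu + Xv + ξ,
    u ~ N(0, τ·ZZᵀ),  v ~ N(0, γ·XXᵀ),  ξ ~ N(0, ε·I)

where `J` maps cells to tissue intercepts, `Z` to subjects, `G` stacks the
dosage g_i ∈ {0,1,2} across subject i's observed tissues, and `X` is the
nt×t design whose subject-i block is g_i·I_t.  Marginally
`Σ = εI + τZZᵀ + γXXᵀ`.  Under H₀: β = γ = 0 each subject's covariance
block is the compound-symmetry matrix `εI + τ11ᵀ`; missing subject-tissue
cells simply restrict the block to the observed tissues, which preserves
the compound-symmetry form, so no imputation is needed and the
observed-data likelihood is exact.

## Null fit (once per gene)

The intercepts α are profiled out in closed form (GLS), leaving a smooth
2-parameter problem in (τ, ε):

* **Balanced complete data.** Along the eigenspaces of `εI + τ11ᵀ`
  (eigenvalue `ε + tτ` on the equal-weight direction, `ε` on its
  complement) the likelihood separates, giving exact closed-form MLEs.
* **Missing data.** Bounded L-BFGS-B on (log τ, log ε) with the analytic
  gradient of the profiled likelihood (the α̂ dependence drops out by the
  envelope theorem).  Convergence is declared at a relative log-likelihood
  change of 1e-8 (the optimiser runs a few orders tighter internally so the
  variance components are accurate to ~1e-6); the cap is 200 iterations,
  beyond which a `ConvergenceError` carries the iteration trace.
* **Boundary.** The log parametrisation cannot reach τ = 0, so a
  closed-form τ = 0 candidate (per-tissue means, ε̂ = RSS/N) is always
  evaluated and τ̂ < 1e-8·ε̂ is snapped to exactly 0 — the boundary must be
  explicit for the score test.

ML rather than REML is used throughout.  The fit depends only on the
expression phenotype, so it is computed once per gene and shared by every
SNP tested against that gene (this is the source of the method's speed; a
scan-pipeline test instruments the call count).

## Scores, weighting, calibration

With `r = Y − Jα̂` and `w = Σ̂⁻¹r` computed blockwise (Woodbury:
`Σ_i⁻¹ = (1/ε)(I − τ/(ε + t_iτ)·11ᵀ)`),

    U_β = Σ_i (g_i − ḡ)·(1ᵀw_i),      U_γ = ½·Σ_s (Σ_i g_i w_is)².

Both are (quadratic) forms in `r`, whose null covariance is the projected
`V = Σ̂ − J(JᵀΣ̂⁻¹J)⁻¹Jᵀ` — using V rather than Σ̂ accounts for intercept
estimation and measurably improves small-sample type-I error.  Means,
variances and the U_β²–U_γ covariance follow from Gaussian quadratic-form
identities (E = tr(AV), Var = 2tr(AVAV)) and reduce to t×t matrix algebra;
no nt×nt matrix is ever assembled, so one SNP costs O(n·t).

The components are combined as `U_ψ = a_β U_β² + a_γ U_γ` with
inverse-null-SD weights `a_β = 1/√Var(U_β²)`, `a_γ = 1/√Var(U_γ)`, which
standardises the two parts so neither dominates; the weight rule is a
configuration point of `joint_test` should an alternative variance-
minimising rule be preferred.  Calibration is Satterthwaite: `U_ψ ≈ κχ²_ν`
with `κ = Var/(2E)` and `ν = 2E²/Var` (the unique moment-matching
solution), p-values floored at the smallest positive double.

Degenerate SNPs (fewer than two distinct observed dosages) are flagged
`monomorphic`, given p = 1, and excluded from multiplicity counts.
Subjects with a missing dosage are dropped for that SNP only, with ḡ
recomputed over the retained subjects.

## Permutation adjustment

A gene's min-p over its candidate SNPs is calibrated by permuting the
genotype subject labels — one shared permutation per iteration across all
SNPs, preserving LD and the cross-tissue expression correlation — and
recomputing min-p against the unpermuted null fit.  The adjusted p-value
uses the add-one rule `(1 + k)/(B + 1)` (configurable off), so it is never
zero and is conservative by construction; B defaults to 10,000 in the scan
pipeline.  BH FDR (via statsmodels) and Bonferroni thresholds
(`α / Π counts`) cover set-level control.

## Synthetic data

`simulate_gene` draws `y_is = α_s + β·g_i + u_i + g_i·v_s + e_is` with
genotypes from Hardy–Weinberg equilibrium at the chosen MAF.  The
interaction strength is parameterised as `PVE_γ = γ/(τ+γ+ε)`; since only
this ratio is identified by the published protocol, the generator
normalises the total variance to 1 with `τ = ε = (1−γ)/2`, making β = 0.5
a half-SD additive effect.  Tissue intercepts default to 0 (the test is
invariant to them; property-tested).  `v` is drawn once per gene and shared
across subjects, matching the `γXXᵀ` covariance; note the components of
`v` are independent across tissues, so the interaction contributes to
per-cell variance (τ + g²γ + ε at dosage g) but not to cross-tissue
covariance (which is τ) — both identities are asserted in tests.
Per-replicate RNG streams are seeded as (base_seed, replicate), so results
are reproducible and independent of execution order.

What the generator does *not* emulate: LD between SNPs beyond duplicated
columns, covariate structure, platform/batch effects, non-Gaussian
expression noise, and informative (non-random) missingness.  Passing
simulation benchmarks therefore validates the statistic's calibration and
power under its own model, not robustness to real-data artefacts — on real
data, the permutation-adjusted gene p-values are the robust summary.

## Experiment sizes

Type-I error uses 5,000 null replicates per (t, MAF) cell at n = 100 and
α = 0.05; power uses 1,000 replicates per cell; null-p calibration uses
10,000 replicates (KS distance vs U(0,1)); permutation uniformity uses 500
single-SNP genes at B = 199.  These match the published simulation
protocol (the type-I table states 5,000 simulations) and keep the full
study under a minute of CPU.

## Numerical choices and edge cases

* Woodbury/closed-form determinants: `|εI + τ11ᵀ| = ε^(t_i−1)(ε + t_iτ)`.
* Fully masked subjects contribute nothing (their likelihood, GLS and
  score terms vanish identically), so a fit with such a subject equals the
  fit with it removed.
* τ is unidentifiable with fewer than 2 subjects having ≥2 observed
  tissues; constant expression makes the model degenerate — both raise
  `DegenerateDataError`.
* cis windows are 1-based, inclusive at exactly ±window ("not exceeding"
  100 kb), strand ignored for the distance.
* The winsorized mean (probe-aggregation utility) replaces the lowest and
  highest ⌊fraction·n⌋ values symmetrically with the nearest retained
  order statistics, matching `scipy.stats.mstats.winsorize`.
* Bonferroni denominators follow the published designs verbatim:
  #tissues × #pairs for TBT-cis, #genes × #SNPs for the joint genome-wide
  scan.

## Known limitations

* Only compound-symmetry covariance (no kinship/relatedness, no REML).
* Satterthwaite matches two moments; extreme-tail p-values (far beyond the
  5 % operating range validated here) would benefit from an exact
  mixture-of-chi-square tail method, which is left as a hook.
* The inverse-SD weight rule standardises rather than exactly minimises
  Var(U_ψ); at t = 10 the test runs very slightly liberal (empirical
  type-I ≈ 0.051–0.052 at nominal 0.05, still within 3 binomial SEs at
  5,000 replicates).
* The adaptive early-stopping permutation scheme is not implemented;
  permutation counts are fixed.
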