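# tissueqtl

Joint score test for mapping expression quantitative trait loci (eQTL)
across multiple tissues.

Expression studies that measure the same subjects in several tissues (or
brain regions) are usually analysed tissue by tissue, which wastes shared
signal and multiplies hypotheses.  `tissueqtl` instead models one gene's
expression across all tissues jointly with a linear mixed model and tests,
for each SNP, both an overall shift in expression and tissue-specific
effects — in a single test that needs no model fitting under the
alternative, so genome-wide scans stay cheap.

## Model and test

For subject *i* with genotype dosage *g*ᵢ ∈ {0,1,2} (minor-allele count)
and expression vector *y*ᵢ across *t* tissues:

    y_i = α + 1·β·g_i + 1·u_i + g_i·v + ξ_i,
    u_i ~ N(0, τ),   v ~ N_t(0, γ·I),   ξ_i ~ N_t(0, ε·I)

* **α** — tissue intercepts; **β** — fixed cross-tissue genotype effect;
* **v** — random tissue-by-genotype interaction with variance **γ**;
* **τ** — subject random intercept; **ε** — residual noise.

The null hypothesis "this SNP is not an eQTL in any tissue" is
H₀: β = 0 and γ = 0.  The null model (compound-symmetry covariance
Σ = εI + τZZᵀ) is fitted once per gene by maximum likelihood; each SNP is
then scored with the efficient scores

    U_β = (G − Ḡ)ᵀ Σ̂⁻¹ (Y − Jα̂),
    U_γ = ½ (Y − Jα̂)ᵀ Σ̂⁻¹ XXᵀ Σ̂⁻¹ (Y − Jα̂),

combined as U_ψ = a_β·U_β² + a_γ·U_γ with inverse-standard-deviation
weights, and calibrated against a Satterthwaite scaled chi-square
(κχ²_ν with κν = E[U_ψ], 2κ²ν = Var[U_ψ]) using the exact null moments of
the α̂-projected residuals.  All linear algebra goes through the Woodbury
form of the per-subject blocks, so a SNP costs O(n·t) and missing
subject–tissue cells are handled by the observed-data likelihood without
imputation.

Also included: gene-level permutation min-p adjustment (genotype labels
permuted, LD preserved), Benjamini–Hochberg and Bonferroni control, a
tissue-by-tissue (TBT) baseline, a synthetic-data generator, and cis /
genome-wide scan pipelines with a CLI.

## Worked example

```python
import numpy as np
from tissueqtl import (SimulationConfig, genotypes_hwe, simulate_gene,
                       fit_null, joint_test, tbt_test)

rng = np.random.default_rng(0)
cfg = SimulationConfig(n=100, t=5, maf=0.3, beta=0.5, pve_gamma=0.10)
g = genotypes_hwe(cfg.n, cfg.maf, rng)      # HWE dosages at MAF 0.30
expr = simulate_gene(cfg, g, rng)           # 100 subjects x 5 tissues

fit = fit_null(expr)                        # once per gene
res = joint_test(fit, g)                    # per SNP
print(f"null fit: tau_hat={fit.cov.tau:.3f}  eps_hat={fit.cov.epsilon:.3f}")
print(f"U_beta={res.u_beta:.2f}  U_gamma={res.u_gamma:.2f}  U_psi={res.u_psi:.3f}")
print(f"Satterthwaite: kappa={res.kappa:.3f}  nu={res.nu:.2f}  p={res.p_value:.3g}")
print(f"TBT min-p = {tbt_test(expr, g)[1]:.3g}")
```

prints

```
null fit: tau_hat=0.386  eps_hat=0.458
U_beta=31.45  U_gamma=608.48  U_psi=10.347
Satterthwaite: kappa=0.502  nu=4.35  p=0.00053
TBT min-p = 0.000379
```

The simulated SNP carries both a half-SD additive effect (β = 0.5) and a
tissue-specific interaction (10 % of variance), and the joint test flags it
at p ≈ 5×10⁻⁴; the fitted variance components recover the generative
τ = ε = 0.45 within sampling error.  On file-based data the same analysis
runs from the shell:

```sh
tissueqtl scan --expression CRBLM=crblm.tsv --expression FCTX=fctx.tsv \
    --genotypes dosages.tsv --annotations genes.bed \
    --mode cis --window 100000 --permutations 10000 --seed 1 --out hits.tsv
```

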