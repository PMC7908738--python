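# Methods

## Model

Phenotypes are modelled as

    y = F b + u + Σᵢ Iᵢ xᵢ sᵢ + e ,

with one record per genotyped individual. `F` is the one-hot design of
breed×sex classes; `u ~ N(0, G σ²ᵤ)` is the polygenic vector; each SNP
has an inclusion indicator `Iᵢ ~ Bernoulli(π)` and, conditional on
inclusion, an effect `sᵢ ~ N(0, σ²ₛ)` on the *centered* genotype
`xᵢ = x̃ᵢ − x̄ᵢ1` (weighted mean `x̄ᵢ = 1'R⁻¹x̃ᵢ/1'R⁻¹1`); residuals are
heteroscedastic, `Var(e) = Rσ²ₑ` with `R⁻¹ = diag(w)` holding record
weights (progeny-test records get large weights, own-performance records
weight ≈ 1). The model is deliberately over-parameterized — both terms
can explain all genetic variance — and relies on the sampled balance
between σ²ᵤ and σ²ₛ to split it; centering the SNP term keeps the
population-mean breeding value at 0 regardless of allele frequencies.

Assumptions worth stating: σ²ₑ is **known input**, not estimated (in
practice it comes from a larger evaluation); π is fixed, on the logic
that only a narrow range of values is useful and the fit is insensitive
within it; genotypes are biallelic codes 0/1/2 with no dosage
uncertainty; one record per individual (the record→individual map is the
extension point for repeated records).

## Sampling scheme

Each cycle:

1. **Fixed effects** — per class Gibbs draw
   `bᵢ ~ N(Fᵢ'R⁻¹y*/Fᵢ'R⁻¹Fᵢ, σ²ₑ/Fᵢ'R⁻¹Fᵢ)`; y* always denotes the data
   corrected for every effect currently in the model, and each update adds
   its own term back before drawing.
2. **Polygenic block** — `u ~ N[(R⁻¹+κG⁻¹)⁻¹R⁻¹y*, (R⁻¹+κG⁻¹)⁻¹σ²ₑ]`,
   κ = σ²ₑ/σ²ᵤ. Because κ changes every cycle, the coefficient matrix is
   diagonalized once up front: `R½G⁻¹R½ = E'DE`, giving
   `(R⁻¹+κG⁻¹)⁻¹ = R½E'(I+κD)⁻¹ER½`. The mean is computed by applying the
   factors right-to-left to `R⁻¹y*` (matrix–vector only); the draw adds
   `σₑ·R½E'(I+κD)^{-1/2}z`, which reproduces the stated covariance
   exactly. Eigenvalues are clipped at 0 against round-off.
3. **Variances** — `σ²ₛ ~ s's/χ²(ΣIᵢ−2)` (kept unchanged while fewer than
   3 SNPs are fitted, since the degrees of freedom would be ≤ 0) and
   `σ²ᵤ ~ u'G⁻¹u/χ²(N−2)`; both floored at 1e−12; κ and λ = σ²ₑ/σ²ₛ are
   recomputed after each draw.
4. **SNP sweep** — for SNP i, the log posterior scores of exclusion and
   inclusion are

        θ₀ = L₀ + log(1−π),
        θᵢ = L₀ + (xᵢ'R⁻¹y*)²/(2σ²ₑ(xᵢ'R⁻¹xᵢ+λ)) + ½log λ
                 − ½log(xᵢ'R⁻¹xᵢ+λ) + log π .

   A non-fitted SNP is skipped outright with probability 1−vᵢ; when it is
   evaluated, entry is accepted with `min(1, e^{θᵢ}/(e^{θ₀}vᵢ))`. A fitted
   SNP is always evaluated (its effect is first added back to y*, so the
   cross-products are corrected for all *other* effects) and its exit
   proposal is accepted with the reciprocal ratio. A SNP ending in the
   model draws `sᵢ ~ N(rhs/(diag+λ), σ²ₑ/(diag+λ))` and y* is updated.
   All acceptance arithmetic is in log space, so |θᵢ−θ₀| of order 10⁴
   cannot overflow. The cross-products are formed from uncentered 2-bit
   codes via the identities
   `x'R⁻¹y* = x̃'R⁻¹y* − x̄·1'R⁻¹y*` and `x'R⁻¹x = x̃'R⁻¹x̃ − (1'R⁻¹1)x̄²`
   (note the square on x̄ — it is forced by expanding
   `(x̃−x̄1)'R⁻¹(x̃−x̄1)`), with x̄ and x̃'R⁻¹x̃ cached once per dataset.
5. **Missing records** — each missing y is drawn from
   `N(Fb + u + ΣIᵢxᵢsᵢ, σ²ₑ/weight)` (weight defaults to 1 when absent).

**Cycle 1** performs only the fixed-effect and polygenic updates, then
scores every SNP against the resulting y* with no SNPs fitted (a
GWAS-like scan), ranks SNPs by θᵢ (ties broken by SNP index, stable
sort), and fixes the update schedule `vᵢ = (1−ρ)^{rᵢ}` for the whole
chain, with ρ calibrated so the lowest-ranked SNP is expected to be
evaluated `target_evals_lowest` times: `(1−ρ)^M·C = target`. Cycle 1
contributes no posterior samples. Skip-sampling changes only the
*proposal* distribution; the 1/vᵢ factor in the acceptance ratios keeps
the stationary distribution exact, which the test suite verifies against
an exhaustive 2⁶-model enumeration for both vᵢ ≡ 1 and a geometric
schedule.

Setting π = 0 disables the SNP machinery entirely (no schedule, no sweep,
no σ²ₛ draws): pure GBLUP through the same code path.

**Chains.** `n_chains` chains run sequentially against one shared
read-only genotype store, GRM and eigen-system; chain k gets its own
`numpy` Generator from `SeedSequence(seed, spawn_key=(k,))`, so runs are
bit-reproducible. GEBV (`u + ΣIᵢxᵢsᵢ`, fixed effects excluded), inclusion
counts, effect sums and the per-cycle fitted-SNP trace are accumulated
over post-burn-in cycles and merged by summation across chains; the
correlation matrix of per-chain GEBV means is reported as the convergence
diagnostic. The SNP sweep runs in a compiled (numba) kernel; all random
numbers are pre-drawn by the Python layer, so the kernel is a pure
function and results do not depend on compilation details.

## Defaults and tunable parameters

| parameter | default | meaning |
|---|---|---|
| `pi` | — (required) | prior inclusion probability; 5e−4 at whole-sequence scale, ~2000–3000/M in general |
| `sigma2_e` | — (required) | known residual variance for a weight-1 record |
| `n_cycles` / `burn_in` | 10,000 / 2,000 | chain length and discarded prefix |
| `n_chains` | 10 | parallel (here: sequential) replicate chains |
| `target_evals_lowest` | 100 | expected evaluations of the lowest-ranked SNP; with M = 4,809,520 and C = 10,000 this gives v_min = 0.01, ≈1.03M evaluations/cycle, a ≈5× reduction |
| `min_fitted_for_sigma_s` | 3 | guard on the σ²ₛ draw |
| `init_sigma2_u`, `init_sigma2_s` | σ²ₑ, σ²ₑ/100 | starting variances (burn-in absorbs the choice) |
| `grm.ridge` | 0.01 | added to diag(G) before inversion; imputed/duplicate-like individuals make G near-singular |
| region width | 250,000 bp | local-GEBV window, tiling from bp 0 |
| `max_snp_distance` | 500 | credibility-interval restriction, strict (<500 index positions) |

The GRM uses VanRaden Method 2 with one pooled (unweighted) allele
frequency per SNP across all breeds; monomorphic SNPs are dropped from
the GRM subset automatically. The eigen orientation is contract-based:
whatever the backend returns is stored so that `E' diag(D) E`
reconstructs `R½G⁻¹R½`.

## QTL mapping layer

Local GEBV of a window is the Bayes C contribution of its SNPs using
posterior-mean effects (effect sums ÷ total samples, i.e. PP-weighted
conditional means), with the same weighted centering the sampler uses;
its population variance (÷N) across individuals scores the window. This
makes the region scan a deterministic function of the posterior summary —
the alternative (per-cycle local GEBV variance, then averaging) coincides
up to Monte Carlo noise for stable chains but was not chosen.

The credibility interval around a top SNP is built from the trace: per
post-burn-in cycle (chains pooled), the fitted SNP nearest in SNP-index
distance (ties to the lower index) is recorded unless it is ≥500 index
positions away (treated as a different QTL); collected bp positions are
sorted and floor(2.5% × count) are trimmed from each end; the interval is
the remaining [min, max] bp, clamped to contain the top SNP. The summed
PP inside is reported for comparison and may exceed 1 — during
transitions two SNPs tagging one QTL are co-fitted, which is exactly why
cumulative-PP intervals are anti-conservative and are not used as the
primary method here. Trimming operates in bp order ("furthest from either
side"); index distance is used only for the nearest-SNP restriction.

## Synthetic data

The generator emulates a multi-breed dairy design: breed allele
frequencies diverge from ancestral `p ~ U(0.05, 0.95)` by Balding–Nichols
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with F the target Fst (realized Hudson
Fst on simulated output reproduces F to ±0.02). LD comes from a Markov
lineage-quantile walk: each haplotype carries a uniform quantile along
the chromosome, refreshed with probability `ld_decay` per SNP, and the
allele is the indicator that the quantile is below the breed frequency.
Marginal frequencies are exact; haplotypes sharing a lineage segment are
identical over it, so r² decays geometrically with SNP distance
(`ld_decay = 1` gives independent loci). A site-independent founder-pool
copying scheme was tried first and rejected: with site-independent
founders the realized r² is only ≈ 1/pool-size, i.e. essentially no LD.

The trait is `n_qtl` large-effect QTL (effects ~ N(0,1), rescaled so the
QTL explain `prop_var_qtl` of the genetic variance) plus a polygenic
background over all remaining SNPs (rescaled to the remainder), with
heritability `h2` for a weight-1 record; 40% of individuals are "bulls"
with weights log-uniform on [5, 100], the rest weight 1; breed×sex class
means are drawn N(0, 0.5²). Defaults — three breeds of 400/300/300,
M = 5,000 SNPs on 5 chromosomes at 10-kb spacing, Fst = 0.05,
`ld_decay` = 0.1, 20 QTL, h² = 0.5, `prop_var_qtl` = 0.5 — are the
standing study conditions for all simulation-based tests. A
`drop_breed_from_training` flag masks one breed's phenotypes (kept as
missing records) to emulate pure across-breed prediction.

What this generator does **not** reproduce: ancestral recombination maps
and mutation (LD is breed-specific but phase-consistent by construction),
selection, pedigree structure, non-Gaussian residuals, and imputation
error. Passing tests therefore demonstrate correctness of the machinery
and qualitative behaviour (variable selection beating GBLUP when few QTL
carry much variance; fine-mapping precision), not field accuracies.

## Problem sizes used in the validation suite

Chain-agreement and enumeration checks run at their stated sizes
(N = 1,000 / M = 5,000 / C = 10,000 with two chains; N = 30 / M = 6 with
2×10⁵ total cycles over 8 chains). Parameter recovery uses 10 replicates
of the generator defaults with C = 3,000 (burn-in 1,000, one chain per
method); interval coverage uses 50 replicates at N = 300 / M = 1,200 /
C = 1,500 with a single isolated QTL. These sizes are the package's
choice of a desk-scale experiment; detection of a QTL explaining ≥ 25% of
phenotypic variance stabilizes well before these chain lengths.

## Known limitations

* Between-chain GEBV correlation at desk scale (N ≈ 1,000) plateaus
  around 0.995–0.997 with 8,000 retained samples: the dominant Monte
  Carlo noise is the weakly identified direction between each breed×sex
  fixed effect and the class-mean of u (with fixed effects removed the
  correlation is ≥ 0.9998). This is a property of the b/u Gibbs blocking
  at moderate class sizes, not of the SNP machinery; it shrinks as class
  sizes grow.
* Chains run sequentially; the shared-input design permits thread
  parallelism but none is attempted.
* σ²ₛ mixing is slower than GEBV mixing (as expected: individual SNP
  effects converge more slowly than their sum), so per-SNP effect
  estimates need more chains/cycles than prediction does.
* One record per individual; no dosages; biallelic SNPs only; no
  estimation of π or σ²ₑ.
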