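# Methods

`methylgxe` dissects how genetics (G), the environment (E), their additive
combination (G+E) and their interaction (GxE) contribute to inter-individual
DNA methylation variability measured on microarrays. It takes matched
M-value methylation, genotype dosage, exposome and covariate tables and
assigns each variably methylated locus the best-supported explanation, with
a variance decomposition and a permutation-calibrated filter against chance
findings.

## Pipeline model

### 1. Highly variable probes (HVPs)

Per-probe M values are residualized by OLS on the concomitant variables
(intercept always included; the design must be full rank). The per-probe
sample variance of the residuals (denominator n−1) is thresholded at its
90th percentile (linear-interpolation quantile, R type 7); probes strictly
above the cutoff are HVPs, so ties at the threshold are excluded
(`hvp_inclusive` flips to ≥). Residuals are used *only* here: all later
stages model unadjusted M values and re-enter the covariates explicitly in
every regression, so covariate variance is accounted for rather than
removed twice.

### 2. Variably methylated loci (VML)

HVPs are grouped on each chromosome into maximal runs with successive
positions < 1 kb apart (strict inequality, absolute bp difference of
1-based positions). Within a run, each adjacent probe pair must be
co-methylated — Pearson r > 0.15 on unadjusted M values — otherwise the run
is split at that pair. Surviving runs of ≥ 2 probes are VMRs; their
per-sample methylation is the median across member probes. Adjacent-pair
splitting (rather than an all-pairs mean, available via `all_pairs`) keeps
the construction order-deterministic and local, matching how regional
co-methylation decays with distance.

An HVP outside every VMR becomes a single-probe locus (sVMP) only if the
*full array manifest* contains no other probe within 1 kb: isolation by
array design, not failed co-methylation, is what rescues it. An HVP with a
near neighbour that did not chain is discarded (counted in the log);
`svmp_mode="hvp"` restricts the neighbour search to HVPs instead.

### 3. cis SNPs

A locus's cis set is every SNP on its chromosome with
start − 1 Mb ≤ pos ≤ end + 1 Mb. The boundary is inclusive and the window
is anchored at the locus span, not its midpoint. Empty cis sets are valid —
such loci can only be explained by exposures or the baseline.

### 4. Variable screening

Per locus, an L1-penalized regression screens (1) cis SNPs only, (2)
exposures only, (3) both pools together. Covariates are present and
unpenalized in every scenario; this block is profiled out exactly (the
lasso with an unpenalized block equals a plain lasso on block-residualized
response and candidates), with the projection fitted on each training fold
and applied to its held-out fold so cross-validation never leaks. Candidates
are standardized to unit variance for penalization; coefficients are
reported on the original scale. Variables with a nonzero coefficient in any
scenario are pooled ("nonzero" rather than literally positive — the sign of
a lasso coefficient is arbitrary with respect to allele and exposure
coding). A locus with nothing selected skips model fitting and is assigned
the baseline class B.

The penalty is chosen by 10-fold CV over a 50-point geometric grid spanning
three decades below the smallest penalty that zeroes every candidate. The
default rule is the **one-standard-error rule** (sparsest penalty within one
SE of the CV-MSE minimum); `lambda_rule: min` selects the CV minimizer
instead. This default is deliberate: the screen's output feeds an AIC
competition over the *best* of many candidate models, so any noise variable
that survives screening is, by construction, the most response-correlated of
its pool and will be retained by AIC far more often than a random regressor
(empirically ~70–90%, versus 15.7% for an arbitrary one-df addition). Under
the CV-minimum rule noise candidates survive screening in roughly a quarter
to half of null scenarios, which caps the sensitivity for single-factor
classes near 0.5; the 1se rule keeps null selections near zero (median 0,
as a shuffled-data screen should give) while leaving planted effects of
partial R² ≥ 0.1 essentially always selected at n = 500.

Each locus draws its CV fold stream from a stable CRC-32 hash of
(global seed, locus id), so results are independent of evaluation order and
of the number of workers.

The solver is cyclic coordinate descent on the precomputed Gram matrix with
warm starts down the penalty grid (convergence: max coefficient change
< 1e-7, ≤ 1000 sweeps), JIT-compiled with numba. The permutation stage
evaluates hundreds of thousands of locus-level screens, where a general
purpose solver's per-call overhead would dominate the run time; the
scikit-learn path solver serves as the correctness reference in the test
suite. For large candidate pools (≥ 400 columns, or more columns than
samples) the per-coordinate cost of the Gram formulation, O(p), loses to
the X-based formulation's O(n), so those calls are routed to scikit-learn's
`lasso_path` on the same penalty grid; and when candidates outnumber
samples the grid floor rises from 1e-3·α_max to 1e-2·α_max (the glmnet
`lambda.min.ratio` convention) so the saturated end of the path is not
chased. Coefficients below 10× the convergence tolerance are treated as
zero, and the top of the penalty grid is nudged up by a factor 1+1e-10 so
the all-zero solution is exactly all-zero despite the KKT condition sitting
on a floating-point boundary there.

### 5. Model competition and variance decomposition

Every selected SNP and exposure is used one at a time to fit

| model | form |
|-------|------|
| G | DNAme ~ SNP_i + covars |
| E | DNAme ~ EE_j + covars |
| G+E | DNAme ~ SNP_i + EE_j + covars |
| GxE | DNAme ~ SNP_i + EE_j + SNP_i·EE_j + covars |

SNP dosage enters as a single additive numeric term (1 df); the interaction
model is hierarchical (main effects always included). The winner minimizes
AIC = n·ln(2π·RSS/n) + n + 2(k+1), where k counts estimated coefficients
including the intercept and the +1 is the error variance (the R `AIC()`
convention; equal to the statsmodels OLS AIC plus 2 — only differences
matter, but the constant is pinned for cross-implementation tests). RSS is
floored at 1e-12 so perfect fits keep a finite AIC. Exact AIC ties break to
fewer parameters, then the fixed class order G < E < G+E < GxE, then
lexicographic variable ids. Singular designs (e.g. a SNP monomorphic in the
complete cases) are dropped from the competition with a warning; if every
model is singular the locus falls back to B.

The winner's variance is decomposed by the LMG (Lindeman–Merenda–Gold)
method: the average over all orderings of the winner's non-covariate terms
of each term's sequential R² increment, with the covariate block always
entered first. With at most three terms the 3! orderings are enumerated
exactly (no sampling); shares are non-negative and sum to
R²_winner − R²_baseline to numerical precision. Because the raw interaction
column correlates with its main effects, its LMG share includes orderings
where it enters first and absorbs main-effect variance — the standard LMG
behaviour for correlated regressors.

One known property of this competition: adding one spurious degree of
freedom beats AIC whenever it improves twice the log-likelihood by more
than 2, which happens with ~16% probability for a null term. True-additive
loci are therefore called GxE at about that rate; it is inherent to AIC
model selection, not to this implementation, and is visible in the
recovery tests as a G+E sensitivity of ~0.86 rather than 1.

### 6. Permutation null filter

Genotype and exposome rows are shuffled with a *single shared* permutation
(preserving every G–E correlation) while methylation and covariates keep
their order; screening and competition are re-run on every locus,
reusing the same per-locus CV seed streams as the observed run so the
shuffle is the only difference. ΔR² = R²_winner − R²_baseline values of
informative permuted winners, pooled over 10 permutations (configurable)
and all loci, form the null distribution. It is bimodal — joint winners
(G+E, GxE) carry more fitted terms than marginal ones (G, E) — so it is
stratified into marginal and joint components and each gets its own 95th
percentile cutoff (linear interpolation). Observed winners with ΔR²
strictly below their stratum's cutoff are demoted to B (equality keeps; the
original class is kept in an audit column). Cutoffs are pooled across loci,
not computed per locus. If a stratum receives no null samples at all —
common at small scale with the conservative 1se screen — its cutoff is 0
and nothing in that stratum is demoted: an empty null carries no evidence
against the observed winners. With only 10 permutations the 95th percentile
of a small pooled sample is coarse; ≥ 20 permutations are advisable for
small locus sets.

## Synthetic data

The generator produces the full input bundle plus ground truth. Each
planted locus occupies its own block (2.5 Mb spacing, so 1 Mb cis windows
do not overlap between loci); cis SNPs are Binomial(2, MAF) dosages with
MAF ~ U(0.1, 0.5) placed within ±0.9 Mb. Exposures are half binary
(prevalence U(0.1, 0.5)) and half standard normal; covariates are standard
normal with per-locus coefficient vectors drawn N(0, 0.3²). A locus's
shared signal is covariate contribution + N(0, 1) latent regional factor +
planted class effects; member probes add independent noise sized so the
expected within-region correlation equals ρ (default 0.7). VMR loci carry
2–5 probes with gaps U[50, 800] bp; sVMP loci one isolated probe. Isolated
low-variance filler probes pad the array to 10× the planted probe count so
planted loci occupy the top variance decile.

Effect sizes are solved from target per-term partial R² (default 0.2):
the term's variance share is computed against the realized base variance,
inflated by the median-of-m noise attenuation (frozen Monte-Carlo constants
for the variance of a median of m standard normals) so the target refers to
the *summarized* response the pipeline actually models. Interaction terms
are residualized against both main effects before scaling, so the target is
a genuine partial R². Infeasible targets (total required share ≥ 1) raise
an error.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, correlated exposures, population stratification, beta-value
heteroscedasticity, batch effects, or missing data. Passing recovery tests
therefore demonstrate the machinery is correct under the model's own
assumptions — independent candidates, linear effects, Gaussian noise — not
that real cohort data meets those assumptions.

## Problem sizes in the shipped experiments

The reference recovery experiment uses n = 500 samples, 20 loci per class
(B, G, E, G+E, GxE), 10 cis SNPs per locus, 15 exposures and per-term
partial R² 0.2, pooled over 10–12 seeded replicates so class sensitivities
are estimated from 200–240 loci per class. The null-calibration experiment
uses 8–20 replicates of 200 baseline-only loci at n = 300 with lean
candidate pools (6 cis SNPs, 8 exposures). These sizes estimate each
reported fraction to within a few percent while a full run stays in the
minutes range on one core.

## Design choices made where the design was open

- **Exposure standardization**: candidates (SNPs and exposures alike) are
  standardized inside the lasso only; models are always fitted on original
  scales, so reported coefficients and R² are unaffected.
- **Adjacent-pair correlation** for VMR chaining (vs all-pairs mean):
  local, deterministic, and the natural reading of "proximal probes with
  correlated methylation"; the all-pairs variant is kept behind a flag.
- **Discarding near-but-uncorrelated HVPs** (vs rescuing them as sVMPs):
  a probe with a close neighbour that fails co-methylation had its chance
  to form a region; only array sparsity rescues singletons. Switchable via
  `svmp_mode`.
- **Inclusive cis boundary**: a SNP exactly 1 Mb away is in cis; the choice
  only matters for exact-boundary positions and is documented.
- **Complete cases only**: the pipeline fails fast on missing values
  rather than dropping silently; imputation belongs upstream.
- **Lambda rule**: 1se by default, for the screening-then-AIC interaction
  documented above; `min` remains available.

## Limitations

- AIC's ~16% acceptance of a spurious extra term bounds additive/interaction
  discrimination; at the shipped effect sizes all other class boundaries are
  essentially error-free.
- The LMG share of an interaction term is not orthogonalized against main
  effects; compare shares within a model, not across models.
- Correlated candidates: the lasso keeps an arbitrary representative of a
  correlated block. Each selected variable's maximum |r| with unselected
  candidates is recorded (`max_corr_unselected`) to flag such cases.
- The permutation null preserves G–E correlation but breaks G–methylation
  and E–methylation links jointly; it cannot calibrate hypotheses about one
  factor conditional on the other.
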