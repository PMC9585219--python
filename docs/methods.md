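# Methods

## The trial model and its REML engine

All phenotypic analyses rest on the linear mixed model

    Y_ijk = μ + G_i + E_j + R_k(j) + GE_ij + e_ijk

with genotype `G`, environment `E` (a location×year combination),
replicate-within-environment `R(E)`, genotype-by-environment `GE`, and an
i.i.d. plot residual. Every random term is independent with its own
variance component. Terms degenerate with the design: a single
environment drops `E`, `GE` and `R` (leaving the one-way genotype model,
which is what the closed-form ANOVA oracles in the test suite check), and
`GE` enters only when some line×environment cell is replicated —
otherwise it is unidentifiable from the residual.

Estimation works through Henderson's mixed-model equations. The engine
(`gsfoundry.mixedlm`) runs EM-REML updates
`σ²_k ← (û_kᵀû_k + tr T_k)/q_k` for a configurable warm-up (default 5
iterations), then attempts average-information Newton steps, falling back
to EM whenever a step would leave the feasible region or reduce the
restricted likelihood. Convergence requires relative restricted-likelihood
change < 1e-8 and relative change in every component < 1e-6; components
are floored at 1e-10 × var(y). The dense inverse of the coefficient
matrix is produced each iteration via Cholesky + LAPACK `dpotri`; its
diagonal blocks are exactly the prediction-error covariances the Cullis
estimator and the Tukey contrasts consume. The restricted log-likelihood
identity `−2ℓ_R = log|R| + log|G| + log|M| + yᵀPy + const` and all BLUP /
PEV extractions are verified in the tests against direct `V`-matrix
algebra, against a 20×20 likelihood grid, and against an lme4 REML fit of
the same data (components and log-likelihood to ~1e-3 relative).

Fixed-genotype fits use a cell-means design (one column per line), so the
EMM of line *i* is its GLS coefficient with random effects at zero
expectation; on balanced data this reduces to the line mean. BLUPs are
reported as deviations and as μ-anchored values; the deviation form is
canonical. Lines observed in a single environment-replicate are retained
(shrinkage handles them in the random fit) but flagged `large_se_flag` in
the EMM table.

`V̄_Δ` for Cullis H² is computed exactly for any line count via
`mean_{i≠j}(T_ii + T_jj − 2T_ij) = 2(g·tr T − 1ᵀT1)/(g(g−1))` on the
genotype PEV block — no pair sampling is needed because the block is
already in memory. H² is clipped to [0, 1] with a warning.

## The synthetic breeding program

The generator emulates the data a regional winter-wheat cooperative
accumulates; its defaults are the study conditions the rest of the
package is tested under.

* **Genotypes.** ~10³ lines × ~10⁴ biallelic SNPs. Ancestral allele
  frequencies uniform on `maf_range` (default 0.05–0.5); two
  subpopulations with Balding–Nichols divergence F = 0.18, calibrated so
  PC1 of the centered genotype matrix explains ≈10% of variance at 1,000
  lines × 5,000 markers — the signature of a panel split by a major
  translocation. Lines are advanced selfed material: with probability
  `inbreeding` (default 0.95) a locus is autozygous, leaving ~1.5%
  residual heterozygosity. This matters practically: a Hardy–Weinberg
  panel would lose nearly every marker to the standard ≤10%
  heterozygosity QC filter, and the VanRaden kinship diagonal averages
  ≈ 1 + F_inbreeding rather than 1.
* **Markers vs. QTL.** Markers are drawn independently within
  subpopulation (no LD blocks); the trait's QTL are a random marker
  subset with normal effects rescaled so the realized breeding-value
  variance equals `var_G` exactly. Without LD the effective marker
  dimension equals the raw marker count, so genomic-prediction accuracy
  follows the n/(n + Me) law in the *panel size*, not in an
  LD-compressed effective number. Scaled-down studies therefore shrink
  the marker panel along with the population; this is the single largest
  divergence from real wheat data, where LD both compresses Me and makes
  marker imputation informative.
* **Trials.** Observations are generated from the same model the
  analysis fits. Each line×location-year cell is observed with
  probability `presence_fraction` (completely at random — the archive's
  actual entry/exit process is unknown, so no informative dropout is
  modeled); replicate counts are drawn per location-year from
  `reps_range`. Default μ = 4,500 kg/ha for readability on the yield
  scale.
* **Heritability presets.** `target_h2` is a line-mean heritability for
  the *balanced reference design*: `var_eps = J·K·var_G(1−h²)/h² −
  K·var_GE` with J environments and mean replicate count K. Unbalanced
  designs realize less information per line and hence a lower Cullis H²
  than the target — by construction, not error. Trait presets (YLD 0.56,
  TW 0.74, HD 0.85, PH 0.83) shrink the GE:G variance ratio as
  heritability rises, reflecting that phenology and stature show far
  less G×E than yield; without that, heritabilities above
  `var_G/(var_G + var_GE/J)` are unreachable at small J.
* **Major genes.** Carriers are Bernoulli at the configured frequency;
  the gene's additive effect is added to carrier observations in the
  region of the observation's location. A configurable fraction of calls
  is masked as heterozygous/null/failed to exercise call filtering.

What passing tests on this generator do *not* show: robustness to LD,
to informative missingness, to pedigree relatedness beyond the two-group
structure, or to spatial field trends — all out of scope.

## Genotype QC and kinship

Calls are encoded as counts of the per-marker minor allele
(heterozygote = 1); every downstream quantity is invariant to which
allele is counted, and the tests assert this for the GRM, PCA and GBLUP
predictions. Filtering removes high-missing lines first (> 85%), then
recomputes marker statistics and keeps markers with MAF ≥ 5%,
heterozygosity ≤ 10% and missingness ≤ 20%; filtering is idempotent.
Missing codes are mean-imputed per marker — a deliberate replacement of
haplotype-based imputation, defensible at the MAF/missingness levels that
survive QC and without LD to exploit. `K = WWᵀ/Σ2p_jq_j` with
column-centered W; zero-variance markers are an error directing to QC.
PCA is a plain SVD of the centered code matrix; requesting more
components than the rank clips with a warning.

## Environment clustering

The line×environment table of replicate means is completed by iterative
rank-2 SVD imputation (initialized at environment means, 50 iterations or
Δ < 1e-6 of the data sd), environment-centered, and decomposed by SVD;
environment loadings are right singular vectors scaled by singular
values, so their cosines approximate inter-environment correlations. The
correlation-PCA path eigendecomposes the pairwise-complete Pearson
matrix, imputing underpowered pairs to 0 with a warning. Grouping is
average-linkage hierarchical clustering on `1 − r`, cut at a group count
or height — an explicit automation of what is usually done by visual
biplot inspection, not a reproduction of any particular manual grouping.

## Training-population optimization

PEVmean scores a candidate training set T for a prediction set P as
`mean diag(X_P A⁻¹ X_Pᵀ)`, `A = X_TᵀX_T + εI`, where X carries an
intercept plus the first `n_pcs` genotype PCs (default 100) and
ε = `ridge_epsilon` · tr(A)/cols (default 1e-8) for conditioning. The
criterion is deliberately model-free of variance components. The subset
GA uses a population of 100 subsets, elitism (default 10), size-2
tournaments, uniform subset crossover (child sampled from the parents'
union), and per-slot member-swap mutation at rate 1/tp_size, over 300
iterations × 10 replications by default; it is deterministic under the
seed and is checked against exhaustive enumeration on 8-choose-3
instances. When the pool is smaller than the requested size the set is
reduced to ⌊0.875·pool⌋. Default TP size is 400 — the "population size"
parameter is read as the TP size, with the GA's internal population a
separate knob, since the optimized sets in the motivating workflow
contain 400 lines.

## GBLUP

REML for `y = 1β + g + e`, `g ~ N(0, σ²_u K)`, is profiled to one
dimension: project y onto the orthocomplement of the fixed effects,
eigendecompose the projected K, and maximize over `log λ ∈ [−10, 10]`
(λ = σ²_e/σ²_u) by bounded derivative-free search with 1e-8 tolerance.
Marker effects `m̂ = (σ²_u/c) Wᵀ V⁻¹(y − 1β̂)` and line values
`û = σ²_u K V⁻¹(y − 1β̂)` are algebraically the same model; predictions
for new lines center their codes at the *training* allele means (missing
new-line codes imputed there too) and are anchored at the fitted
intercept so GEBVs live on the trait scale. Fixed effects are an
intercept only. A constant response returns a flagged degenerate fit.

## Validation

Accuracy is Pearson correlation between observed genetic values and
GEBVs (Spearman carried as a secondary column). Five-fold CV shuffles the
sorted line list under a seed — sorting makes fold membership a function
of the line *set*, so results are invariant to input order — into folds
differing by ≤1 in size, without stratification; repeated CV is available
but defaults to a single partition. Quadrant classification splits the
observed-vs-predicted plane at the two means: A/B correct, C/D wrong;
boundary points (exactly at a mean) classify by sign convention into A/B.

## Gene-by-region interaction

Per gene, calls other than present/absent are discarded (genes with < 20
usable calls are skipped; carrier frequency < 2% or > 98% is flagged
low-power). The trial model gains a fixed allele×region cell-mean term
(6 cells); G, E, R(E), GE stay random. Cell EMMs are the GLS
coefficients, with covariance from the fixed-effect block of the inverted
MME matrix. The contrast family is fixed at nine — present vs absent
within each region, plus the three region pairs within each allele —
excluding the six cross-factor pairs. t statistics use containment
degrees of freedom (n_obs − number of estimable cells; Kenward–Roger is
out of scope), and the Tukey adjustment evaluates the studentized-range
tail at q = |t|√2 with the family's cell count as the group count (cross-
checked against R's `ptukey`). Adjusted p-values are floored at the raw
p. Genes are analyzed one at a time. Origin stratification restricts
records to lines whose breeding-program origin matches the testing
region before fitting, as a genetic-background control.

## Problem sizes and tolerances

The acceptance script runs, per seed: Cullis H² on balanced 500-line ×
2-environment × 2-replicate trials (3 seeds per trait preset); PC1 on a
1,000×5,000 panel; and an integrated study of 600 lines (450 historical /
150 new, 58 validation) × 800 markers (~700 post-QC), 6 locations × 4
years at 30% presence, TP of 300 selected by 100 GA iterations × 2
replications on 50 PCs, with two major genes (frequencies 7.3% and 53.9%;
one with a −300 kg/ha region-3 effect) and the gene-by-region fit on a
300-line subsample that retains every carrier of the rare gene. These
sizes keep the full run to a few minutes while leaving each measured
quantity in its informative regime. Statistical test bands in the suite
are set from the quantity's own sampling distribution — e.g. a variance
component estimated from q levels has relative sd ≈ √(2/q), so the
environment variance (8 levels) gets a wider recovery band than the
genotype variance (300 levels) — rather than a uniform percentage.

## Known limitations

No LD or recombination maps; no pedigree or selection across
generations; no dominance or epistasis; completely-at-random phenotype
missingness; homoscedastic residuals across environments; single-trait
models only; mean imputation rather than haplotype imputation;
containment rather than Kenward–Roger degrees of freedom; dense MME
inversion bounds comfortable model sizes to a few thousand random-effect
levels on one CPU.
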