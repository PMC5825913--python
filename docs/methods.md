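# Methods

`supergs` implements an end-to-end phenotype-to-prediction workflow for a
resequenced panel of inbred crop lines: multi-environment mixed-model
phenotype adjustment, population structure and linkage disequilibrium (LD)
estimation, a SUPER-style mixed-model association scan, and cross-validated
genomic prediction with GWAS-informed marker subsets.  A synthetic-data
module generates genotypes and field-trial phenotypes with known ground
truth, so every stage is testable offline.  This note records the models,
the defaults and why, and the numerical choices made where the design was
genuinely open.

## Synthetic data

**Genotypes.**  `simulate_genotypes` draws ancestral allele frequencies
uniformly on a configurable minor-allele range (default 0.05–0.5), diverges
them into K populations with a Balding–Nichols beta model (default
divergence F = 0.15), and assigns each genotype Dirichlet(α) ancestry
fractions (default α = 0.2, a two-group admixed panel).  Haplotypes carry LD
through a first-order Markov chain on a latent uniform: walking along a
chromosome, the latent value is kept with probability exp(−ρ·d) for
inter-marker distance d and otherwise redrawn; the allele is the indicator
that the latent uniform falls below the marker's population frequency.
Copying the *latent uniform* rather than the allele itself keeps every
marker's marginal distribution exactly Bernoulli(p) per population — copying
alleles directly would let low-frequency alleles hitch-hike along the chain
and erase both the allele-frequency spectrum and the population structure —
while correlation still decays geometrically with distance.  The default
decay rate ρ = 5·10⁻⁶ per bp, with the default ~4 kb marker spacing (matching
the 2.4–4.3 SNPs / 10 kb densities of a resequenced chickpea-sized genome),
puts the r² = 0.2 LD extent in the tens-to-hundreds-of-kb range typical of
diverse inbred panels.  Lines are selfed to near-homozygosity (residual
heterozygosity 0.005 per call, exposed as a parameter).

**Phenotypes.**  `simulate_trait` builds an additive genetic value from
`n_qtl` standard-normal marker effects rescaled so the genetic variance is
exactly 1, adds per-site genotype×environment deviations with variance
`prop_ge`·σ²g, independent row and column effects per site (sd
`spatial_sd`), and a residual solved so the plot-level heritability
σ²g / (σ²g + σ²ge + 2·spatial_sd² + σ²e) equals the requested `h2_plot`.
Field layout is one row per replicate with genotypes randomised across
columns (`randomize_layout=False` gives a deterministic complete-block
layout).  Ordinal 1–9 scores are the latent Gaussian values quantile-binned
into nine classes, mirroring how visual field scores behave; downstream
models treat them as Gaussian responses.  G×E deviations are independent
across sites — no attempt is made to model environmental covariance.

What the generator does *not* emulate: coalescent genealogies, dominance and
epistasis, spatially autocorrelated (AR1×AR1) field trends, selection or
kinship beyond admixture, genotype-specific missingness, or sequencing
error.  Passing tests therefore demonstrate correctness of the estimators
under the stated generative model, not robustness to every feature of real
field data.

## Two-stage phenotype analysis

Stage 1 fits, per site and trait, y = genotype (fixed) + row + column
(independent random intercepts) + ε by REML; the genotype estimates are the
site BLUEs.  Independent row/column intercepts were chosen over an
autoregressive residual because they are the minimal model that captures a
row/column trend; AR1×AR1 is out of scope.  Stage 2 has two
parameterisations because no single model serves both purposes: genotype
*fixed* with environment (and, when replicated, G×E) random yields the
cross-environment BLUEs used by GWAS and prediction; genotype *random* on
replicated plot-level records yields REML estimates of (σ²g, σ²ge, σ²e).
Separating σ²ge from σ²e requires replicated (genotype, environment) cells,
so the variance-component mode refuses unreplicated input rather than
silently returning a confounded estimate.

Broad-sense heritability uses the entry-mean formula
h² = σ²g / (σ²g + σ²ge/t + σ²e/(r·t)) with t environments and r replicates;
for unbalanced data t is the number of environments and r the harmonic mean
of the cell replicate counts (the standard plug-in when the balanced formula
is applied to unbalanced designs).

**REML machinery.**  Variance components are parameterised as ratios
γ_k = σ²_k/σ²e, the residual is profiled out, and each likelihood evaluation
uses the Woodbury identity so the expensive factorisation is a q×q Cholesky
(q = total random-effect levels).  Optimisation is L-BFGS-B on log γ
(bounds −16…12) followed by a Nelder–Mead polish, which guards against the
flat ridges that appear when a term has few levels.  Ratios that end at the
lower bound are reported as exactly zero.  For fully balanced random models
the expected-mean-squares (ANOVA) estimators — which coincide with REML in
the interior of the parameter space — are used as a closed form, with the
restricted likelihood evaluated once at the estimate for reporting.

Fixed effects are tested with the genotype-block Wald chi-square (p from the
upper χ²_{k−1} tail).  Being asymptotic, its finite-sample size exceeds the
nominal level when the residual degrees of freedom are small relative to the
contrast rank; the calibration simulations therefore use designs with
generous replication (10 genotypes × 30 replicates), where the analytic size
P(F_{k,ν} > χ²crit/k) ≈ 0.055.  Variance components are tested by a
likelihood-ratio test against the boundary mixture ½χ²₀ + ½χ²₁ (the
asymptotic null for a single variance component on the boundary); equal
log-likelihoods give p = 1 by convention, and a full-model likelihood below
the reduced one (beyond 10⁻⁶) raises an optimiser-failure error rather than
returning a negative statistic.

## Kinship, LD and structure

The genomic relationship matrix is VanRaden's G = WWᵀ / 2Σpⱼ(1−pⱼ) with
dose columns centred at 2pⱼ; allele frequencies come from the sample itself
and missing calls are mean-imputed before centring.  On a fully inbred panel
the expected diagonal is ≈ 2 (the usual outbred expectation is ≈ 1); tests
assert this documented property, not a biological claim.  Compression for
the mixed model clusters genotypes by average linkage on max(G) − G and
replaces blocks by their means; group labels are renumbered by first
occurrence so that n-group compression reproduces G exactly.

LD is the squared Pearson correlation of dose vectors, computed
pairwise-complete (missing or depth-masked calls at either marker are
dropped; r² is invariant to swapping ref/alt coding).  The decay curve fits
the drift–mutation equilibrium expectation

    E[r²](C) = [(10+C)/((2+C)(11+C))] · [1 + ((3+C)(12+12C+C²)) / (n(2+C)(11+C))]

with C = c·d, by nonlinear least squares on binned mean r² (100 equal-width
distance bins by default; raw-pair fitting is exposed).  Binning stabilises
the fit because per-pair r² is extremely noisy and heavily weighted toward
short distances.  n is the number of genotypes.  The LD extent is the
smallest distance where the fitted curve crosses r² = 0.2, found by linear
interpolation on a fine grid extending ten times past the fitting window and
flagged infinite if the curve never falls below the threshold.  In the C→0,
n→∞ limit the expectation is 10/22 ≈ 0.4545, a useful closed-form check.

Ancestry is estimated under the binomial admixture likelihood
Σᵢⱼ gᵢⱼ log(qᵢ·pⱼ) + (2−gᵢⱼ) log(1−qᵢ·pⱼ) by plain EM with multiplicative
updates, several restarts (best likelihood kept) and allele frequencies
clamped to [10⁻⁶, 1−10⁻⁶] to keep the likelihood finite.  Plain EM was
chosen over quasi-Newton acceleration deliberately: accuracy, not speed, is
the contract, and monotone ascent gives a free invariant (a decrease raises
an error).  On fully homozygous data the likelihood is exactly twice the
haploid likelihood, so the maximiser is unchanged — the model remains valid
for inbred panels.  K is chosen by masked-entry cross-validation: observed
genotype entries are partitioned into folds, each fold masked and re-fit,
and masked entries scored by mean binomial deviance.  Because the
likelihood assumes independent markers, dense LD lets additional components
soak up haplotype structure and can flatten the CV curve; the model-selection
checks therefore simulate panels with fast LD decay, where the assumption
holds.

## Mixed-model GWAS and SUPER

The scan model is y = Xβ + u + ε with u ~ N(0, Kσ²g).  After one spectral
decomposition of K, REML reduces to a one-dimensional problem in
δ = σ²e/σ²g, solved by bounded scalar minimisation on log δ with a 25-point
grid guard against local minima.  Markers are tested by generalised least
squares in the rotated space: a Wald t on the marker coefficient with the
residual scale re-estimated per marker (df = n − 2).  Under P3D the null
variance ratio is reused for every marker (the default); `p3d=False`
re-estimates δ per marker and agrees with P3D to |Δlog₁₀p| well under 0.2 on
null data.  Setting the kinship to zero reduces the test exactly to ordinary
least squares, which is both a unit test and an escape hatch.  Markers with
fewer than five non-missing calls, or monomorphic ones, are flagged untested
rather than dropped.

SUPER proceeds in two steps.  Pseudo-QTNs: the genome (chromosomes
concatenated) is cut into `n_bins` equal-bp bins (default 100), the
smallest-p tested marker per bin is a candidate, and candidates are added in
increasing-p order (ties: smaller position) while the null-model REML
likelihood under a VanRaden kinship built from the selected markers
improves, up to `n_qtn_max` (default 20).  Scan: for each test marker,
pseudo-QTNs with r² above the exclusion threshold (default 0.1) are removed
and the kinship rebuilt from the remainder; markers sharing an exclusion
pattern share one null REML fit, which keeps the scan fast.  If every
pseudo-QTN is excluded the marker falls back to identity kinship, logged.
With the threshold at 1 and all markers as pseudo-QTNs the scan reproduces
the plain mixed-model scan exactly — the degenerate-equivalence oracle used
in the tests.

Multiple testing uses Bonferroni only (α/m for m tested markers; at the
study scale of m = 144,777 and α = 0.05 this is 3.45·10⁻⁷), with an optional
suggestive line at 10⁻⁴ in the Manhattan table.  Significant SNPs are
annotated with the nearest gene ending before and starting after the
position (a containing gene is flagged separately), and pooled across traits
into regions by single-linkage merging within a distance threshold; regions
holding two or more distinct traits are flagged pleiotropic.

## Genomic prediction

RR-BLUP is fitted in its GBLUP form: REML on G = VanRaden(W), then a BLUP
back-solve; marker effects are recovered as β̂ = (σ²g/denom)·WᵀV⁻¹(y−μ̂),
which makes the marker-effect route and the kinship route algebraically
identical and equal to ridge regression at shrinkage λ = (σ²e/σ²g)·2Σp(1−p)
— the central equivalence asserted to 10⁻⁸ in the tests.  The Bayesian
LASSO uses the scale-mixture-of-normals Gibbs sampler (per-marker variances
τ²ⱼ with inverse-Gaussian full conditionals, gamma(0.55, 10⁻⁴) hyperprior on
λ², a standard weakly-informative choice); Bayesian ridge regression places
one common Gaussian prior on all effects with scaled-inverse-χ² priors on
both variances, scales set by assigning half the phenotypic variance to
markers a priori.  Both samplers default to 10,000 iterations, 2,000
burn-in, thinning 5, are deterministic given a seed, and raise on any
non-finite draw.  Fixing the per-marker variances degenerates either sampler
to a conjugate model whose posterior mean is the ridge closed form — the
Monte-Carlo oracle used in testing, with MCSEs from batch means because
single-site Gibbs draws are autocorrelated.

Predictive ability is the Pearson correlation between predicted and observed
values of held-out genotypes (not divided by √h²).  Cross-validation uses
seeded permutations into near-equal folds (sizes differ by at most one);
5 folds × 10 repeats = 50 evaluations is the default.  The marker-subsetting
experiment evaluates a descending p-value ladder (all, 0.05, 0.01, 10⁻³,
10⁻⁴, 10⁻⁵, Bonferroni by default) for each model.  Whether GWAS-based
selection is re-run inside each training fold is the single most
consequential unstated design choice in this kind of analysis: re-using a
full-data scan leaks test information into marker selection and inflates
ability.  The default scheme is therefore `within_fold` (scan re-run on
each training set); `full_data` is provided to mirror analyses that
select once on the complete data and logs a prominent bias warning.  Marker columns are re-centred
within each training fold; a threshold yielding zero markers in a fold marks
that cell undefined rather than raising.

## Problem sizes used in the checks

The acceptance-grade checks run at sizes chosen to make their Monte-Carlo
error small relative to the tolerance being asserted: variance-component
recovery at n = 300 genotypes × 3 sites × 3 replicates over 50 simulations;
the h² ladder (0.1–0.9) at the same design over 20 simulations, compared on
the rank of the mean estimates; admixture recovery on a 132 × 1,000
two-group panel with divergence F = 0.5; K-selection over 10 seeds of
100 × 400 panels; type-I error of the Wald and boundary-LRT tests over
1,000 null simulations each; null-GWAS inflation on a structured 150 × 2,000
panel; and the subsetting profile on ten 200 × 5,000 panels with 10 QTL and
entry-mean h² = 0.3.  `scripts/acceptance.py` recomputes the same quantities
at moderately reduced replicate counts and prints them as JSON.

## Known limitations

- The Wald chi-square is asymptotic; small designs (few residual df per
  contrast) inflate its size, which is why the calibration designs replicate
  generously.  No Kenward–Roger-style correction is attempted.
- The LD-decay expectation assumes drift–mutation equilibrium and a single
  panmictic population; fitting it to structured panels biases c.
- The admixture CV criterion degrades under dense LD (see above).
- `full_data` marker subsetting is optimistically biased by construction.
- The spectral REML in the scan profiles a single kinship; multi-kinship
  models (e.g. G + G×E) are out of scope.
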