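# Methods

This note documents the models, defaults and numerical choices behind
`doseqtl`, and what the synthetic data do and do not establish.

## The cross simulator

Segregants are haploid meiotic progeny of two fully inbred parents, so each
marker is biallelic and fully informative: +1 for the BY allele, −1 for RM.
Chromosomes are simulated as two-state Markov chains along the genetic map:
the first marker is ±1 with probability ½, and each step switches allele
with the Haldane (no-interference) recombination fraction
r = (1 − e^(−2d/100))/2 for inter-marker distance d cM. Haldane was chosen
because it is the standard closed-form map function and makes inter-marker
correlations analytic (corr = 1 − 2r), which the tests exploit; crossover
interference would change linkage decay only modestly at the 2 cM default
marker spacing. The default grid is 16 chromosomes × 100 cM at 2 cM
spacing (816 markers), with a marker always placed on the chromosome end so
that peak support intervals truncate naturally.

The phenotype of strain i at dose D is

    y_i = μ(D) + Σ_k β_k(D)·g_{i,q_k} + Σ_{k<l} γ_{kl}(D)·g_{i,q_k}·g_{i,q_l} + s_i

with replicate measurements adding independent N(0, σ_e²) noise and radii
clamped at 0 after noise (no-growth colonies). The strain-level effect
s_i ~ N(0, σ_s²) is drawn once per strain *per dose* and shared across that
strain's replicates and layouts. It represents dose-specific non-additive
genetic variance (higher-order epistasis, strain-by-dose idiosyncrasy) and
is what makes broad-sense exceed narrow-sense heritability. It is
deliberately *not* shared with the dose-0 control plates: a strain effect
present identically on drug and control plates would be removed by the
control regression and could contribute nothing to the mapped trait.

### The default architecture

`study_architecture` plants nine additive QTL with dose-resolved effects on
a 40–200 µM dose series: a large locus on chrI active at every dose with
the RM allele beneficial (β from −0.50 to −0.15 phenotype units across
doses), three low-dose-only loci (chrVII, chrXII, chrXIII), two high-dose
loci (chrXIV, chrXV, |β| up to 0.30), and three intermediate loci (chrV,
chrVIII, chrXI). Five loci favour the BY allele and four the RM allele, so
the parents — which carry all-(+1) and all-(−1) genotypes — sit much closer
together than the segregant range: the substrate of transgressive
segregation. Three epistatic pairs among the chrI/chrXIV/chrXV loci act
mainly at 160–200 µM with mixed signs; same-sign parental allele products
then largely cancel in the parents while widening the segregant
distribution. Baselines μ(D) fall from 5.0 (no drug) to 0.15 at 200 µM, so
the top dose is strongly zero-inflated — many strains do not grow — which
is why the rank-based scan is offered alongside the regression scan.
σ_s = σ_e = 0.35 puts replicate repeatability and the H²−h² gap in the
range the replicated-panel design implies.

### What the generator does not emulate

* No polygenic background: all additive variance sits at the nine planted
  loci, so the detected-QTL additive model explains nearly all of h²
  (R² ≈ 0.6–0.7), more than a real panel where undetected small-effect loci
  keep the detected-QTL R² well below h². Tests of variance bookkeeping are
  unaffected; absolute R² values are optimistic relative to real data.
* Clamped radii are exactly 0, whereas image-derived radii of non-growing
  spots carry small positive measurement noise. Exact ties at zero make the
  pooled-null transgression test conservative at the highest dose (see
  Limitations).
* No genotyping error or missingness by default (missing codes are
  supported in the scan via flanking-marker expectation, and can be
  introduced by the caller).
* Plate position effects are a per-layout additive offset, not a spatial
  field; the layout regression removes exactly this structure.

## Phenotype preparation

Normalization regresses each drug-plate radius on the strain's mean
control-plate radius within the same layout configuration (OLS with
intercept), then averages residuals per strain across layouts and
replicates. Residuals are exactly orthogonal to the control covariate and
mean-zero within each layout fit, and invariant to affine rescaling of the
control values. Zero radii are retained as data, not treated as missing:
zero-inflation at high dose is biology, and discarding it would bias every
downstream variance estimate.

Growth curves are fitted with a cubic smoothing spline whose penalty is
chosen by generalized cross-validation (`scipy`'s `make_smoothing_spline`);
the maximum growth rate is the maximum of the fitted first derivative over
the observed interval. "Logarithmic phase" is not delimited explicitly —
the global maximum of the derivative is used, which coincides with log
phase for any sigmoid-shaped curve. An off-by-default log-OD variant fits
the spline to log(OD) and reports the reconstructed dOD/dt maximum.

## Linkage scans and peak calling

For complete ±1 genotypes the Haley–Knott regression LOD is computed
vectorized from per-marker correlations,
LOD = −(n/2)·log10(1 − R²); a brute-force per-marker least-squares oracle
verifies equality to 1e-10 in the tests. Monomorphic markers score 0 and
are flagged. A perfect fit (R² → 1) would give infinite LOD; it is reported
as a configurable cap (default 50) with a flag. The cap is applied *only*
to numerically perfect fits: on a 1008-strain panel genuinely strong QTL
reach finite LOD of 60–150, and truncating them would flatten peaks into
plateaus and split single loci into several called peaks.

The non-parametric scan computes the tie-corrected two-group
Kruskal–Wallis H per marker on shared phenotype ranks and converts to the
LOD scale via the Wilks correspondence, LOD = H/(2 ln 10). It is invariant
under strictly monotone phenotype transforms and is the recommended
statistic at strongly zero-inflated doses.

Permutation thresholds permute the phenotype vector against genotype rows
(seeded), record the genome-wide maximum LOD per permutation, and return
the empirical (1−α) quantile (α = 0.05, 1000 permutations by default).
Peaks are local maxima above max(cutoff 3, permutation threshold). Two
maxima on one chromosome are distinct peaks only if the valley between them
drops at least 1.5 LOD below the lower maximum; otherwise they merge into
the stronger peak. The support interval of a peak is the *range* of markers
within 1.5 LOD of its maximum — an isolated one-marker dip below the floor
does not truncate the interval. The range definition (rather than the
outermost *contiguous* run) matches standard linkage-interval routines; on
noisy profiles the contiguous rule truncates intervals at single-marker
noise dips and measurably undercovers the true locus. The search segment
for each interval is bounded by the deepest valley separating it from
neighbouring accepted peaks and by the chromosome ends.

## Architecture statistics

Effect sizes are OLS slopes on the ±1 coding with textbook standard
errors; positive means BY-allele carriers grow better. The additive model
and the epistasis scan are ordinary least squares (statsmodels); the
interaction p-value is the partial F-test of the product term, Bonferroni
corrected as min(1, p × pairs tested), with the family being all pairs of
loci detected at any dose, per dose. Significance for declaring a pair
epistatic defaults to corrected p < 0.005. Δvar ≥ 0 by model nesting.

Broad-sense heritability uses one-way random-effects expected mean
squares, σ²_G = (MS_strain − MS_error)/r̄ with r̄ the harmonic-mean
replicate count, clamped at 0, and a seeded bootstrap over strains
(default 1000 draws) for the SE. Narrow-sense heritability fits
y = μ + u + e, u ~ N(0, σ²_A K), K = GGᵀ/M rescaled to unit mean diagonal,
by restricted maximum likelihood: after one eigendecomposition of K each
candidate h² costs O(n), so the likelihood is maximized on a 101-point grid
over [0, 0.999] followed by bounded refinement (the grid stops short of 1
because K is rank-deficient when markers < strains and h² = 1 would make
the rotated covariance singular; estimates are clamped to [0, 1] on
output). All markers enter K, not only detected QTL, so h² measures total
additive variance; the detected-QTL R² from the additive model is the
comparable "model explained" figure. Bootstrap SEs (over strains, default
200 draws) re-decompose the resampled kinship each draw.

The transgression test computes the pooled parental SD as
√((var_A + var_B)/2) over the two parents' replicates only — thresholds
are defined from parent means, so parental replicate spread is the natural
scale; including the (QTL-inflated) segregant variance would make the
bounds depend on the very signal being tested. The null model pools all
parent replicates and segregant values and redraws both groups with
replacement (the resampling scheme is not fully specified in the
literature this follows; bootstrap-style draws keep the null exchangeable
with the observed tabulation). The p-value uses the add-one convention
p = (1 + #{null ≥ obs})/(R + 1), R = 10,000 by default.

## Factorial allele-replacement analysis

The saturated 2³ (or 2⁴ with background) factorial is fitted by OLS with
treatment coding; reference levels are MKT1 = RM, IRA2 = BY, SWH1 = BY,
background = BY, chosen so the coefficient labels name the replaced allele
(MKT1(BY), IRA2(RM), SWH1(RM), BG(RM)) and the intercept is the
all-reference strain. Any empty design cell raises an aliasing error
naming the missing cell rather than silently dropping terms. Tukey-HSD
comparisons use the studentized-range distribution (scipy's numerical
implementation) with the one-way pooled error and the Tukey–Kramer SE for
unequal group sizes; with exactly two groups the adjusted p equals the
pooled-variance t-test p via q = t·√2, which the tests check to 1e-6.

The factorial generator's default replicate noise is σ = 0.18: with 36
replicates per cell this reproduces the coefficient standard errors of the
published replacement experiment (intercept SE σ/6 ≈ 0.030, pairwise-term
SE 2σ/6 ≈ 0.059). Its default cell-mean surface places all pairwise
interactions in the RM background — dominated by a +0.77 MKT1(BY):SWH1(RM)
product — and a purely additive surface in BY.

## Problem sizes in the test suite

The test suite runs everything at the sizes the analyses are designed for
where that is cheap (single 1008 × 816 panels, factorial with 36
replicates), and scales resampling loops to what a laptop CPU does in
seconds: 20 seeded study-scale panels for planted-architecture recovery
(500 permutations per threshold), 200 null scans of a 200-strain /
200-marker panel for threshold calibration, 100 phenotype draws on one
panel for heritability recovery, and 500 null datasets × 2000 resamples for
transgression calibration. The acceptance script uses the same sizes and
finishes in a few minutes.

## Known limitations

* **Ghost peaks.** Very strong QTL (LOD > 50) on long chromosomes can
  throw secondary local maxima 20–40 cM away (linkage shadows plus sampling
  noise) that satisfy the 1.5-LOD valley rule and are called as distinct
  loci. The cross-dose union therefore counts a few more distinct loci than
  were planted. Guarding against this would require a multi-QTL model
  search, which is out of scope.
* **Top-dose transgression power.** With radii clamped at exactly 0 and a
  near-zero baseline, the pooled-null resampling test loses power at
  200 µM (parents and most segregants tie at the growth floor); the test is
  calibrated but conservative there. Real image-derived radii carry
  measurement spread that restores power.
* **1.5-LOD interval coverage** is approximately 90–95% for loci explaining
  2–5% of variance and higher above that; it is not a guaranteed 95%
  confidence interval, especially for weak loci on long chromosomes.
* The kinship REML h² assumes the causal loci are tagged by the marker
  panel (exact here, where causal loci are markers); with sparse real maps
  it underestimates additive variance in proportion to untagged LD.
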