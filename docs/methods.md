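# Methods

`wildintro` re-implements, as a tested library, a pipeline for detecting
historical wild-relative introgressions in a clonally propagated crop and
quantifying their contribution to trait variation: diagnostic-marker
detection from reference panels, windowed ancestry-dosage mapping,
LD-aware genome partitioning, partitioned-heritability mixed models,
mixed-model association scans, and cross-validated genomic prediction.
Every stage is exercised end to end on a synthetic-data generator that
emulates the genetic structure such a study assumes. This note records
the models, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## Diagnostic markers

Two reference panels anchor the analysis: a small wild panel (*M.
glaziovii*-like; 8 accessions by default) and a per-window panel of
non-introgressed cultivated samples. Cultivated panels are chosen per
1000-SNP window as the `top_k = 10` samples with the largest mean Hamming
distance to the wild panel (`MeanGlazDist`); windows whose maximum
distance falls below `min_dist = 200` are discarded — every candidate
looks wild-like there, so no trustworthy cultivated reference exists.
Distance is the allele-count metric `sum |a_i - b_i|` on dosages rounded
to the nearest integer (ties to even), skipping sites missing in either
sample. Only distance *rankings* are consumed (panel selection), so the
metric's treatment of heterozygote pairs (het-het distance 0) affects
nothing downstream beyond rank stability, which the synthetic tests
exercise. A terminal window of fewer than 100 sites merges into its
predecessor.

Classification is per site against its own window's panels, on hard
(rounded) dosages with zero tolerance — any discordant or missing call in
either panel disqualifies the site:

- **strict**: both panels fixed, for opposite alleles;
- **glazpoly**: cultivated panel fixed, wild panel segregating.

The wild-diagnostic allele is the allele absent from the cultivated
panel. A recoding step flips dosage counting at diagnostic sites so
dosages count the wild allele, making PC loadings, window dosages and
GWAS effect signs interpretable against introgression.

## Windowed dosage maps and summaries

`DoseGlaz` is the mean wild-diagnostic dosage over the diagnostic markers
in 250-kb nonoverlapping windows (window w spans bp
`[1 + w*250000, 1 + (w+1)*250000)`; the anchor at position 1 is a
convention). Windows without markers are missing. Per-individual
summaries: proportion = sum of diagnostic dosages / (2 x number of
markers); homozygosity = fraction of markers with rounded dosage 2.
"Rounded dosage equals 2" is the nearest-integer rule applied to
fractional imputed dosages. Group comparisons report means, not medians.
PCA standardizes dosages (center, unit variance; per-site mean imputation
of missing calls) and fixes component signs so each loading vector's
largest-magnitude entry is positive.

## LD tagging and genome partition

A background SNP in strong LD with the diagnostic set would let the
"background" kinship absorb introgression variance. For every non-IDM
SNP we compute `maxLD` (largest squared dosage correlation against any
diagnostic site) and `totalLD` (the sum over all of them — an LD-score
against the diagnostic set, computed genome-wide, not windowed; chunked
evaluation changes nothing but memory). SNPs with `totalLD >=` a
threshold (inclusive boundary) are reclassified as tag-IDMs; `maxLD` is
available as an optional conjunctive filter, off by default, since the
LD-score alone decides the published partition. The threshold grid
evaluation reports, per threshold, the off-diagonal correlations of the
tag/diagnostic/background/combined kinships; the objective is to
maximize cor(tag, idm) while minimizing cor(tag, non) and
cor(idm+tag, non). Random partitions of matched size serve as controls.

## Mixed models

All models share the form `y = X b + sum_k Z_k u_k + e` with
`u_k ~ N(0, s2_k G_k)` and `e ~ N(0, s2_e R)`, `R = diag(1/w)` for
optional per-record weights. Genetic covariances are VanRaden method-1
GRMs (dosages centered by twice the counted-allele frequency; optional
nonnegative per-site weights; zero-variance sites dropped; missing calls
mean-imputed). The suite per trait: NULL (no genetic term), IID
(identity clone covariance), ALL (all-marker kinship), IDM
(introgression-partition kinship), IDMnull (background kinship), and
PARTITIONED (both). Fixed effects: intercept, plus the harvested-stand
count (NOHAV) for plot-level yield traits (RTWT, RTNO, SHTWT), which are
natural-log transformed (non-positive records dropped with a log
message). Per-trial fits add a replication random effect (and optionally
incomplete blocks nested in replications, per breeding-program
configuration); multi-trial fits add location-year-trial and
location-year-trial-rep identity randoms.

REML maximizes the profiled restricted likelihood over variance ratios
`gamma_k = s2_k / s2_e` on the log scale with L-BFGS-B (coarse-grid
initialization; derivative-free polish if the line search stalls), with
a spectral (eigendecomposition) fast path for single-kernel models.
Components converging to the lower box bound are refit at an exact zero
and kept there when the likelihood does not decrease; bounds on
log-gamma are [-13, 11]. Convergence tolerances: optimizer `ftol` 1e-13;
an engine that fails both passes raises rather than returning a bad
optimum. The average-information/EM updates common in this literature
are one path to the same optimum; the contract here is the optimum, and
the test suite verifies it against dense grid searches of the restricted
likelihood. The likelihood carries its full Gaussian constant (no |X'X|
term) identically across models, so within-run AIC differences and LRTs
are valid; absolute log-likelihoods and AICs are software conventions
and are not comparable across packages.

`npar` = number of fixed coefficients + number of variance parameters
(including the residual), applied uniformly; only AIC *differences*
matter for the curation rules. The variance-component LRT uses a plain
chi-square reference (no 50:50 boundary mixture), which is conservative
for a variance component on the boundary — the type-I study asserts an
upper bound (rejection <= 0.08 at alpha = 0.05) rather than exactness.
Heritability `h2_x = s2_x / (sum of genetic variances + s2_e)` excludes
design variances (rep, block, location-year terms) from the denominator
by default (`include_design=True` reverses this); the share is
`h2_idm / h2_total`.

Trial curation drops a trait-trial when (1) no genetic model beats NULL
at p < 0.05; else (2) no kinship-based model does; else (3) the IID
model's AIC is >= 2 units below the best genomic AIC.

## Association scans

The GWAS response is the per-clone BLUP from the IID genetic model with
the multi-trial design randoms. Both scans test a predictor as a fixed
effect in `y = mu + x b + g + e`, `g ~ N(0, s2 K_background)` with the
background (non-introgression) kinship absorbing structure. Variance
components are estimated once under the no-predictor null and reused for
every test (the standard single-pass approximation; an exact per-marker
re-estimation mode exists and is slow). SNP scans exclude markers with
MAF < 0.05 (distinct from the MAF > 0.01 filter used when building the
background GRM); diagnostic SNPs are tested on wild-recoded dosages so
the effect sign reads against the wild allele. The window scan tests the
250-kb mean-dosage columns by default; a fixed-count windowing mode
(15 diagnostic markers per window) is provided as an alternative, since
both conventions appear in this literature. `WaldStat = (b/se)^2` with
p from the upper tail of chi-square(1); Bonferroni thresholds are
computed separately per scan (strict inequality at the boundary).

## Genomic prediction

Two stages. Stage 1 is the IID-model fit above, from which each clone's
BLUP, prediction error variance (PEV), reliability `r2 = 1 - PEV/s2_g`,
deregressed value `dEBV = BLUP / r2`, and weight
`w = (1 - h2) / ((c + (1 - r2)/r2) h2)` are derived; `c` (the fraction
of genetic variance unaccounted by markers) defaults to 0.5 and is
configurable — accuracy rankings are insensitive to it across
{0.1, 0.5, 0.9} in the test suite. Clones with nonpositive reliability
are excluded. Stage 2 cross-validates kinship models on the dEBVs with
per-record residual variance `s2_e / w_i`; GEBVs for held-out clones
come from their kinship with the training set, and the PARTITIONED
model's total GEBV is the sum of its two component BLUPs. Fold
assignments (k-fold per replicate, scikit-learn KFold seeded from the
master seed) are drawn once per replicate and shared bit-identically
across models; accuracy is the test-set Pearson correlation of stage-1
BLUP and GEBV, exactly as the response defines it. On synthetic data a
truth-based accuracy is additionally reported for diagnostics only.

A held-out-clone GBLUP accuracy does not approach 1 even for a fully
heritable noiseless trait: the GEBV is a projection onto the span of the
training relationships (about 0.83 at n = 200 training relatives here).
Accuracy comparisons between models are therefore the meaningful
quantity, not absolute accuracy.

## Synthetic-data generator

Founders: ancestral allele frequencies drawn uniform on [0.3, 0.7], the
two populations drifted apart by a Balding-Nichols model with divergence
F = 0.2. A stated fraction of sites (default 2%) is forced to fixed
opposite alleles (the wild-diagnostic allele is randomly the REF or ALT,
so the recoding step is exercised); another fraction is wild-private
polymorphic, conditioned on the realized wild panel actually segregating.
Neutral sites are conditioned on staying polymorphic within every
panel-sized subset of the cultivated pool. This conditioning represents
SNP-panel ascertainment (sites are sites *because* they are polymorphic
in the collection) and is what makes exact recovery of the annotated
classes a meaningful test: without it, finite panels realize accidental
fixation and the truth labels would be wrong, not the classifier.

Pedigree: each admixed individual descends from an independent F1 (one
wild, one cultivated gamete) backcrossed `backcross_depth` times
(default 3; expected wild fraction 1/16) to random cultivated founders,
with optional random-mating generations and truncation selection on
regional wild dosage. Meiosis is Haldane (Poisson crossovers on the cM
scale, no interference) — simplicity over realism. The genetic map is
uniform at 3 cM/Mb (a round value in the range of dense crop consensus
maps) and compressed inside the designated introgression regions (chr1
distal 10 Mb and chr4 5-25 Mb of a two-chromosome default genome) by
factors 0.86 and 0.29, i.e. 14% and 71% recombination suppression.
Local ancestry is recorded exactly per meiosis; at fixed-difference
sites the wild-allele dosage equals the ancestry count by construction,
which is the lever most truth-based tests use.

Phenotypes: clone genetic value = region component (effects on local
wild-haplotype count at fixed-difference sites inside the regions) +
background component (effects on dosage at neutral sites outside),
scaled so plot-basis variance shares hit the `h2_idm` / `h2_nonidm`
targets — exactly on the realized sample by default, or in expectation
over effect draws (`exact_scale=False`), where the realized variance of
a single draw is highly dispersed because region LD correlates the
causal genotypes. Plot records add location-year-trial and replication
effects at configured variances (excluded from the heritability
denominator, matching the model convention), optional NOHAV covariate
effects, and Gaussian plot residuals with `s2_e = 1 - h2_idm -
h2_nonidm`. Deleterious load: at designated sites, a haplotype carries
the deleterious allele with probability `base_rate`, multiplied by an
enrichment factor when the haplotype is wild-derived inside a region;
carrier status is drawn conditional on local ancestry, so
identity-by-descent sharing of load between relatives is not modeled.
Genotyping noise adds truncated Gaussian dosage jitter and missingness.

What the generator does not emulate: imputation artifacts with
structured (LD-dependent) errors, multiallelic sites, assay batch
effects, genotype-by-environment interaction, spatial field trends, and
selection on phenotype during the pedigree. Passing tests therefore
demonstrate the pipeline's correctness and statistical behavior under
the stated generative model, not robustness to all real-data pathology.

## Validation studies and their problem sizes

The end-to-end studies (in `wildintro.studies`, rerun by
`scripts/acceptance.py`) use sizes a single CPU completes in minutes,
chosen as this package's reference experiment scale:

- **Diagnostic recovery**: 20,000 sites, 8 wild + 25 cultivated
  founders, noiseless; recovery of annotated classes must be exact.
- **Segment mapping**: chr1-only genome, 8,000 sites with a 10%
  diagnostic fraction (the dense end of real intersection panels — map
  resolution is marker-density-limited, and a sparse panel would test
  density, not the method); spliced heterozygous/homozygous distal
  blocks; breakpoint error and window MAE measured against identically
  windowed true ancestry on strict markers, clean and at 20% missingness
  with 0.1 dosage jitter.
- **Partition-LRT calibration**: four-chromosome genome (regions hold
  ~20% of markers), one genotype draw, phenotype replicates; type-I at
  n = 300 clones x 200 replicates (h2_idm = 0), power at n = 500 x 50
  (h2_idm = 0.2 of 0.6).
- **Share recovery**: two-chromosome genome (regions hold ~46% of
  markers, well separated from the causal share 1/3), n = 500 clones,
  two location-year-trials, 20 phenotype replicates, with equal-size
  random-partition fits as controls; random shares should track the
  marker proportion, the region-defined share the causal truth.
- **GWAS calibration**: permutation-null uniformity over ~500 background
  predictors plus a protective chr4 segment effect that must be
  Bonferroni-significant with a negative sign. The genomic-control
  check (naive regression inflates, mixed model stays near 1) lives in
  the unit suite on a stratified three-subpopulation collection — the
  textbook setting for that property; in a two-chromosome pedigree
  cohort every SNP tags family structure across megabase LD blocks and
  the mixed model is intrinsically conservative there.
- **Prediction contrast**: n = 500 clones, two backcrosses (region
  wild-allele frequencies ~0.12, matching the 10-20% of real
  introgressed germplasm), a 5% diagnostic fraction, and a polygenic
  architecture (60 region + 400 background causal sites): GBLUP's
  implicit infinitesimal model makes the single-kinship and partitioned
  models nearly equivalent only for polygenic traits, which is the
  regime the claim concerns. Traits at h2_idm in {0, 0.1, 0.3} of 0.6,
  averaged over 3 causal-architecture draws, 5 replicates of 5-fold CV
  with shared folds.

## Known limitations

- The variance-partition studies use the region-based genome partition
  (every site inside the designated regions joins the introgression
  kernel — the limiting case of tag reclassification for fully linked
  blocks); the LD-score tagging machinery is exercised separately.
- Exact per-marker variance re-estimation in the GWAS is O(markers x
  REML) and only practical for small scans; the single-pass
  approximation is the default, as in standard mixed-model GWAS tools.
- The heritability-share estimator inherits upward bias toward the
  marker proportion when region LD leaks background variance into the
  introgression kernel (visible as mean shares ~0.35-0.40 for a true
  1/3 at the study scale); the tolerance of the recovery study covers
  this and the random-partition control quantifies the baseline.
- PEV-based reliabilities assume the stage-1 model is correctly
  specified; weights propagate no uncertainty in `s2_g` itself.
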