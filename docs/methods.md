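# Methods

`prstune` implements the fine-tuning workflow behind genome-wide polygenic
risk scores (PRS) for a binary, gestational-diabetes-like phenotype:
external GWAS summary statistics are harmonized to a target genotype
cohort, per-variant weights are derived by three LD-aware methods across a
tuning grid, individuals are scored, models are ranked by AUC, and the top
model is applied — frozen — to a replication cohort. This note records the
models, the defaults and the deliberate design choices.

## Synthetic cohorts

Real consortium summary statistics and biobank genotypes are access
controlled, so the package carries a first-class generator whose output has
a known ground truth.

**Genotypes.** Each haplotype is a latent multivariate normal with
block-Toeplitz correlation `r^|i-j|` (blocks of `block_size` variants,
independent across blocks); the allele is present where the latent value
falls below the quantile of the variant's allele frequency (drawn uniformly
from `maf_range`), and the dosage is the sum over two haplotypes. The
Gaussian-copula construction was chosen over haplotype resampling because
the implied dosage correlations can be checked against a closed-form /
Monte-Carlo oracle. Frequencies, variant metadata and the per-variant
sample-size pattern are fixed by the configuration seed, so all cohorts
drawn from one configuration describe the same population. Variants sit at
1 kb spacing on one synthetic chromosome by default (kb windows and
variant-count windows then coincide); an `n_chromosomes` option spreads the
blocks over several chromosomes so leave-one-chromosome-out calibration can
be exercised.

**Architecture and phenotype.** Effects follow a point-normal prior:
causal with probability `fraction_causal` (p), effect `N(0, h2/(M p))` on
the standardized-genotype scale, so the genetic liability variance is `h2`
in expectation. The binary status is a liability threshold: liability =
genetic value + `N(0, 1 - h2)` noise, case where liability exceeds the
`(1 - K)` standard-normal quantile at prevalence `K` (default 0.36,
matching a discovery cohort in which roughly one woman in three met the
South Asian-specific oral-glucose-tolerance criteria). `label_gdm`
implements those criteria directly: case iff fasting glucose >= 5.2 mmol/L
or 2-h post-load glucose >= 7.2 mmol/L (inclusive), with self-report used
only when both measures are absent — the sources do not state how conflicts
between measures and self-report were reconciled, so measures always win
here.

**Training GWAS.** `make_summary_stats` runs a per-variant univariate
regression on a per-variant subsample whose size follows
`missing_n_pattern` — by default 70% of variants at the maximum N and 30%
uniform on [0.5, 1] x max, which populates every sample-size-floor level
(0/85/90/95/98% of max N). The default regression is linear on the
continuous liability: at M >= 10^4 variants per-variant logistic fits
dominate runtime while ranking variants identically for tuning purposes;
`model="logistic"` is available for spot checks. Heterogeneous per-variant
N emulates meta-analyses in which many SNPs were tested in far fewer
samples than the maximum.

What the generator does *not* emulate: realistic human MAF/LD spectra,
long-range LD, relatedness, population stratification, X chromosome,
genotyping error. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated generative model, not
real-data performance.

## Harmonization

Matching is chr:pos first, variant id as a fallback (tolerant of build/ID
drift); duplicates at a position are dropped on both sides rather than
arbitrated. Alleles resolve in order: (effect, other) = (alt, ref) keeps
the beta; = (ref, alt) negates it; the two rules are retried after strand
complement; anything else is dropped as a mismatch. Palindromic (A/T, C/G)
variants are dropped by default because strand cannot be established
without reliable allele frequencies; `drop_palindromic=False` keeps them at
face value. Both variant filters are inclusive (`info >= 0.7`,
`n >= floor x max(n)`), and `floor = 0` encodes the "all variants" level.
Odds-ratio columns are converted to `beta = ln(OR)` at read time.

## LD panel

Pairwise Pearson correlations of dosages are computed inside a physical
(kb, default 250) or variant-count window and held in banded sparse
storage; out-of-window pairs are structurally zero. Missing dosages are
mean-imputed per variant; monomorphic variants are flagged with zero
off-diagonal r. No small-sample shrinkage is applied by default (an
optional `r/(1 + 1/n_ref)` damping exists). The regional LD score is
`l_i = sum of r^2(i, j)` over the window, self term included, so `l >= 1`.
Panels can be subset to match consortium ethnic proportions by a
largest-remainder allocation over population labels.

## Weighting methods

**Clumping + thresholding (P+T).** Candidates with P <= the index cutoff
are visited in ascending P (ties: position, then id); each surviving
candidate becomes an index variant and removes in-window candidates with
r^2 >= the threshold. Defaults r^2 = 0.5 and 250 kb follow the common
clumping tooling's documented defaults. The index weights are the aligned
summary betas for variants passing the P threshold.

**LDpred-style Gibbs.** Summary betas are first standardized as
`beta_std = (beta/se) / sqrt(N)` — robust to the reporting scale and the
single supported convention. The point-normal model has prior variance
`sigma2 = h2 / (M p)` and residual variance `1/N`. Each Gibbs sweep updates
variants in order: the residual marginal effect conditional on the current
neighbors within the LD radius `L` (default `round(M/3000)`, floor 1) is
scored against the causal (`N(0, sigma2 + 1/N)`) and null (`N(0, 1/N)`)
components in the log domain; a causal indicator and effect are sampled;
the reported weight is the average of inclusion-probability x conditional
mean over post-burn-in sweeps (a Rao-Blackwellized posterior mean — the
upstream software's exact output convention is not documented, so this is
this package's definition). Defaults: 100 sweeps, 20 burn-in, seed 42 —
small enough for desk-scale grids, and at p = 1 the sweep is deterministic
and reproduces the closed form `beta * sigma2 / (sigma2 + 1/N)` exactly.
A divergence guard restarts the chain with the prior variance halved when
the sampled signal variance exceeds `10 x h2`. `h2` is a required
assumption (default 0.5, near published SNP-heritability estimates for
type-2 diabetes); in-package heritability estimation is out of scope.
Output weights are returned per allele (standardized weights divided by the
panel dosage SD) so that all three methods score raw dosages on the same
footing; `output_scale="standardized"` exposes the raw posterior means.

**Gradient-boosted calibration with regional LD adjustment.** The
calibration target is the magnitude of each variant's univariate
association with the phenotype in the calibration cohort, computed by
vectorized linear regression on standardized dosage (a per-variant logistic
fit would scale each magnitude by a near-constant factor at these effect
sizes while costing three orders of magnitude more time). Boosted
regression trees (250 trees, depth 3, learning rate 0.05, squared error —
conservative, config-exposed) predict that target from five summary-level
features: |beta|, -log10 P, per-variant N, allele frequency, regional LD
score. The feature list and window are this package's definition — the
method's original description leaves them open. The weight is
`sign(beta) x max(0, prediction) / l`. Because the trees can memorize
individual variants through near-unique feature values, the default is
leave-one-chromosome-out prediction; `mode="full"` mirrors calibrating on
the whole cohort at once. On single-chromosome data LOCO raises with an
instruction to use full mode (the pipeline downgrades automatically). The
method earns its keep when the external GWAS is underpowered relative to
the calibration cohort; with a precise external GWAS the raw betas are
already near-optimal and recalibration cannot help.

## Evaluation

Scores are weighted dosage sums (mean-imputed missing calls; weights tied
to a counted allele, with `2 - dosage` used where the counted allele is the
dataset reference). Association uses a univariate maximum-likelihood
logistic fit on the standardized score, so the slope is log-odds per SD;
perfect separation returns an infinite-beta sentinel rather than raising.
AUC is the Mann-Whitney form with the half-tie convention; its SE and the
test between two correlated AUCs use the DeLong structural-components
estimator, with `p = 1` and a degenerate flag at zero estimated variance.
Quartile contrasts define "top 25%" as score >= the lower-interpolated 75th
percentile (inclusive; the tie policy changes group sizes, so it is
serialized into the run manifest), compare against the remaining 75% or the
mirrored bottom quartile, and report Wald CIs from the logistic slope, with
a Haldane-Anscombe add-1/2 fallback (flagged) for empty 2x2 cells. Power
uses a one-stage non-central chi-square: `lambda = N_eff R2 / (1 - R2)`;
a two-stage (training + target) power model is deliberately out of scope,
and an optional harmonic-mean case-control `N_eff` is available.

## Tuning grid and determinism

The grid is the Cartesian product, per method, of summary source x
sample-size floor {0, 0.85, 0.90, 0.95, 0.98} x LD source x threshold
(64 log-uniform values from 5e-8 to 1, shared between P+T cutoffs and
fraction-causal values; the exact 64 values are serialized into every run
manifest since only their range and count are externally fixed). Ranking
is by descending AUC, ties broken by ascending slope P, then config hash.
Harmonization is cached per (source, floor) and LD per source; cell
failures are logged and excluded. Every cell seed derives from the config
hash, so runs are byte-reproducible (the manifest contains no timestamps)
and cells are independently schedulable. Replication is reachable only
from the fitted result object and scores frozen weights after an
info-score >= 0.6 filter, reporting the fraction of weight variants found
and warning below 98% coverage; the tuning stage never reads the
replication cohort.

## Problem sizes used in the checks

The oracle and calibration checks run at deliberately small sizes (5-200
variants, 100-2000 samples, 1000 DeLong replicates); the end-to-end
parameter-recovery study uses M = 2000 variants in blocks of 10, a 20,000
sample training GWAS on the liability scale, a 1000-sample target cohort, a
1000-sample LD panel, h2 = 0.5, 1% causal variants and prevalence 0.36,
with a 2000-sample replication cohort — sizes chosen so the full study runs
on a laptop-class single core in minutes while keeping the oracle PRS AUC
well away from both chance and ceiling.

## Known limitations

- The LDpred-style sampler conditions on a fixed variant-count radius, not
  shifting kb windows, and does no allele-frequency-dependent prior.
- GraBLD-style calibration on the evaluation cohort (full mode) leaks
  calibration information into tuning, exactly as calibrating on the whole
  discovery cohort would; LOCO mode is the guard, not a cure.
- The one-stage power model ignores training-sample noise in the weights.
- Palindromic variants are discarded rather than frequency-rescued.
- No covariate adjustment, calibration plots or reclassification metrics.
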