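# Methods

This note documents the statistical models implemented in `protmr`, the
assumptions behind the synthetic-data generator, the numerical
conventions, and the design choices made where more than one defensible
option existed.

## Two-sample MR model

For exposure X (a plasma protein) and outcome Y (a disease on the
liability scale, with betas read as log-odds), each instrument j
contributes a harmonized pair (β̂_Xj, σ_Xj, β̂_Yj, σ_Yj). Under the IV
assumptions the Wald ratio β̂_Yj/β̂_Xj estimates the causal effect.

**IVW.** Weighted zero-intercept regression of β̂_Y on β̂_X with weights
w = 1/σ²_Y. The fixed-effect SE is (Σ w β̂²_X)^(−1/2). By default a
multiplicative random-effects inflation √(Q/(n−1)) is applied whenever
Cochran's Q exceeds its degrees of freedom — the prevailing convention
in two-sample MR software. Both variants are exposed (`ivw` and
`ivw_fe`), and the inflation state is flagged on the estimate. Note that
the inflated variant is deliberately conservative: under a strict null
the inflation triggers on ~45% of draws (whenever Q/(n−1) > 1), so its
p-values are not exactly uniform; calibration checks therefore assess
`ivw_fe`, whose z-statistic is exactly standard normal under the null
conditional on the instruments.

**MR-Egger.** Weighted regression with a free intercept after orienting
all β̂_X ≥ 0. The slope is the causal estimate; the intercept, its SE
and t(n−2) p-value form the directional-pleiotropy balance test. SEs use
the plain WLS covariance with residual variance RSS/(n−2) — no
overdispersion floor — so that the intercept test is an exact t-test for
homoskedastic independent instruments (an earlier floored variant drove
the test's size far below nominal in simulation).

**Weighted median.** Wald ratios are ordered; with normalized weights
w_j = β̂²_Xj/σ²_Yj the estimate interpolates the ratio at which the
standardized cumulative weight s_j = (Σ_{i≤j} w_i − w_j/2)/Σw crosses
0.5. SE by seeded parametric bootstrap (β̂_X and β̂_Y re-sampled from
their normal errors; default 1000 replicates).

**Weighted mode.** Weighted normal-kernel density over the Wald ratios,
bandwidth φ × 0.9·min(sd, IQR/1.349)·n^(−1/5) (φ = 1 by default),
maximized on a fixed 512-point grid spanning the ratios ± 3 bandwidths;
grid ties resolve to the smallest ratio. SE by the same bootstrap.

Exposure-side uncertainty σ_X enters only through the bootstrap
procedures; IVW and Egger use the standard first-order forms without a
weak-instrument correction. Consequently CI coverage is nominal only in
the NOME regime (instrument z-scores large relative to the causal effect
times the outcome SE) — the recovery experiments are sized accordingly
(protein GWAS n = 20 000, cis effects 0.3 SD, outcome GWAS n = 5 000).

## Instruments

Clumping is greedy: significant variants (p < 5×10⁻⁸) sorted ascending
by p (ties by variant id), accepted iff r² < 0.1 with every accepted
variant within ±500 kb. Pairs farther apart than the window are treated
as independent regardless of r² (single-window semantics). Variants
significant but absent from the LD panel are dropped with a warning by
default. cis means: same chromosome and position within [start − 1 Mb,
stop + 1 Mb] of the encoding gene; gene intervals are 1-based inclusive,
BED input converted on read.

Proxies (index variant missing from the outcome study) must be present
in both studies, exposure-significant, within 500 kb, and in r² > 0.7
with the index; the highest-r² candidate wins, ties broken by smaller
exposure p then lexicographic id. A proxy carries the index variant's
exposure effect; its outcome effect is sign-aligned through the sign of
r(index, proxy).

Harmonization aligns the outcome to the exposure's effect allele:
swapped allele pairs negate the outcome beta and complement the EAF;
palindromic variants (A/T, C/G) with minor-allele frequency above 0.42
are dropped as strand-ambiguous. Both studies are assumed forward-strand;
an optional flag enables frequency-based strand inference (complement
matching) for non-palindromic variants.

## Sensitivity analyses

**RSS-simulation outlier test (MR-PRESSO style).** Observed statistic:
Σ_j w_j (β̂_Yj − β̂_(−j) β̂_Xj)², with β̂_(−j) the leave-one-out IVW
slope. The null re-samples β̂*_Y ~ N(β̂_(−j) β̂_X, σ_Y) (1000 draws by
default) and recomputes the statistic; the global p is the empirical
rank with the +1 correction, so the floor is 1/(n_sim+1). Per-instrument
terms are ranked the same way; instruments with empirical p below
0.05/n_IV are removed and IVW recomputed on the survivors. The
distortion test ranks the corrected-vs-raw shift against removals of
random same-sized subsets. Requires ≥4 instruments.

**HEIDI-style filter.** Reference = instrument with the smallest
exposure p. For each other instrument the Wald-ratio difference from the
reference is tested with the delta-method variance
σ²_Y/β̂²_X + β̂²_Y σ²_X/β̂⁴_X (reference variance added, covariance
ignored); two-sided p < 0.01 removes the instrument, and the test is
iterated once on the survivors. The reference is never removed. This is
a single-reference simplification of the multi-SNP reference set used by
the original software.

**Multivariable MR.** Outcome z-scores regressed on the variant ×
protein exposure z-score matrix without intercept. z-scores have unit
sampling variance, so coefficients' SEs come from the unscaled (XᵀX)⁻¹.
Variants are expected pre-clumped at r² < 0.01 within 500 kb and
significant for ≥1 exposure. No estimating-equation bias correction is
applied — a stated simplification appropriate for the generator's strong
instruments; rank deficiency raises an error naming a collinear exposure
pair.

## Multiplicity, replication, phenome scan

Significance flags come from the primary method (IVW) within a family =
all testable exposure × outcome pairs per (direction, IV mode,
ancestry). Bonferroni uses α/m with m the number of testable pairs —
reported alongside the flags, since published thresholds frequently
cannot be reconstructed from stated trait counts. BH follows the
standard step-up rule. Replication re-runs the same MR on a second,
smaller pQTL panel for the discovery-significant set; flags at raw
p < 0.05, BH < 0.05, and Bonferroni over the replication family are
monotone by construction, and direction consistency is the sign match of
the primary beta.

The phenome-wide scan runs protein × phenotype MR over a panel filtered
to ≥50 cases, with per-cell z = β/se of the primary method. Specificity
labels: one significant phenotype; all significant phenotypes in one
category; or pleiotropic at k ∈ {20, 15, 10, 5}. Over-representation of
protein group G in disease category D uses the upper-tail hypergeometric
with N = (#phenotypes)·|G|, M = (#phenotypes in D)·|G|, n = significant
signals in G overall, k = those in D; scan-level significance is
Bonferroni over (#groups × #categories).

## Colocalization

Per trait and variant, the Wakefield log approximate Bayes factor is
½·log(σ²/(σ²+W²)) + ½ z² W²/(σ²+W²) with prior effect SD W = 0.15 for
quantitative traits and 0.2 for binary traits (log-odds). Three
configuration families are weighed: all-null (weight 1); independent
causality (each trait causal somewhere, prior p₁ = 10⁻⁴ per variant per
trait, including all partial-causality subsets via Π_t(1 + p₁ Σ_j ABF));
and shared causality (all traits causal at the same variant, prior p₁
times a conditional sharing prior per additional trait, defaults 0.005,
0.01, 0.02 for the 2nd, 3rd, and further traits). The regional
probability is the posterior that every trait is causal; the alignment
probability is the shared configuration's share of all-causal mass; the
reported posterior for a passing cluster is their product, with the
argmax of the per-variant joint evidence as candidate variant.

If either probability misses its threshold (default 0.7 each; a
0.6–0.9 sweep helper is provided) the trait whose removal maximizes the
remaining alignment is split off and the remainder re-assessed; pairs
that fail split into singletons. This divisive rule is a deliberate,
fully specified simplification — no equivalence with published
divisive-clustering implementations is claimed. Regions with fewer than
10 shared variants warn as unstable.

## Single-cell analysis

Pseudobulk = exact integer sums of nucleus counts by donor × cell type.
TMM factors: reference = profile whose upper-quartile count fraction is
closest to the mean; factor = precision-weighted mean of log2 ratios vs
the reference after trimming 30% of M-values and 5% of A-values per
side, exponentiated, rescaled to geometric mean 1. log₂-CPM =
log2((count + 0.25)/(lib·factor + 0.5)·10⁶) — the pseudocount applied
directly to the effective library size rather than the adjusted-library
variant some implementations use; the difference is O(pc/count) and
documented here. Under count-and-library doubling the value shifts by
≈ pc/(2·count·ln2), i.e. near-invariance requires counts ≳ 200.

Cell-type enrichment requires the conjunction: one-vs-rest fold of mean
TMM-normalized CPM > 4 with one-sided Welch-t BH-FDR < 0.01 on
profile-level log-CPM (BH across genes × cell types), ≥25% of the cell
type's nuclei expressing, and single-gene Mann–Whitney AUC > 0.6
(midrank ties) separating the cell type's nuclei from the rest — the
minimal training-free classifier consistent with an "AUC of a
single-gene classifier". Display ordering: cell type of highest average
nuclei expression, then the mean of the Gini coefficients of (per-type
average expression, per-type fraction expressing), descending.

Differential expression per cell type regresses pseudobulk log-CPM on
disease group (DCM or HCM vs NF) with age and sex covariates, using
voom-style observation weights: an unweighted first pass yields a lowess
trend of √(residual SD) against average log-CPM, and each observation's
weight is the trend at its fitted value to the −4. The group coefficient
is the log2 fold change; BH within cell type; pass = log2FC ≥ log2(1.5)
and FDR < 0.01. Arms with <3 donors are not testable; a group indicator
collinear with a covariate raises an error naming the confounding. The
weighting is a stated approximation of the published limma-voom
procedure, not a re-implementation.

## Synthetic-data generator

Summary statistics are sampled directly in β̂-space: per LD block,
β̂ = R·β_joint + L z/√n with L the Cholesky factor of R, se = 1/√n,
two-sided normal p. This reproduces exactly the moments two-sample MR
assumes (marginal means R·β_joint, covariance R/n) without
individual-level genotypes. LD blocks are AR(1), r(i,j) = decay^|i−j|
(default decay 0.6, block size 12), optionally jittered and re-projected
to the PSD cone. Allele codes are non-palindromic by construction with
EAF ~ U(0.05, 0.95); the effect allele is always the alternate, and a
recoding helper flips a random subset (allele swap, β negation, EAF
complement) to exercise harmonization. An overlap parameter ρ correlates
the sampling errors of an exposure/outcome pair (cov = ρR/√(n_X n_Y))
to emulate shared participants; it is off by default.

Causal structure: each protein has cis variants inside ±1 Mb of its gene
(default 2 at 0.15 SD per allele — strong cis-pQTLs), optional shared
trans hubs, and each disease has its own liability variants on a
dedicated chromosome (default 3 at 0.08). A disease's β_joint adds
Σ_p γ_p × (protein p's cis/trans effects) and any direct (pleiotropic)
effects; a protein's adds Σ_d δ_d × (disease d's own liability-variant
effects). Mediated chains deeper than one step (e.g. protein → disease →
other protein appearing in the other protein's GWAS) are deliberately
not propagated: a disease that both receives a forward effect and emits
a reverse effect would otherwise hand reverse MR a contaminated,
heterogeneous instrument set — real reverse-causation leakage that
desk-scale exact-recovery checks cannot absorb. Study designs in the
tests therefore plant reverse effects from diseases without forward
causal proteins; the contamination mechanism itself is exercised through
the explicit pleiotropy channel.

Default scales: protein GWAS n = 20 000 (a UK-Biobank-interim-like
panel), disease GWAS n = 100 000, replication panel n = 1 225 (a
FinnGen-Olink-like second study), γ = 0.5 and δ = 0.35 in the discovery
experiments — chosen once so that forward power exceeds 95% at the
family-wise Bonferroni threshold.

The single-cell generator draws negative-binomial counts (dispersion
0.5, gene base means log-normal around 2) for a donor panel of 8 NF /
6 DCM / 6 HCM — about half the scale of a published left-ventricle
snRNA-seq cohort — with 60 nuclei per donor per cell type. Enriched
genes multiply the mean in one cell type (pseudobulk one-vs-rest ratio
equals the fold in expectation); DE genes multiply the mean for one
condition within one cell type.

What the generator does **not** emulate: realistic human LD maps and MAF
spectra, genome-wide variant counts, case/control ascertainment and the
liability→log-odds mapping (betas are read as log-odds without
conversion), sample overlap by default, batch effects or ambient RNA in
the single-cell counts, and cell-type misassignment. Passing tests
therefore demonstrate algorithmic correctness and calibration under the
assumed sampling model, not robustness to those real-data features.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed, and fixed-input
fixed-seed runs are bit-reproducible. The test suite and the acceptance
script size their simulations for a single CPU: 1000-instance oracle
sweeps, 1000-seed null calibrations, 200-seed recovery/PRESSO/coloc
batches, 100-replicate end-to-end and single-cell round trips, and
exhaustive hypergeometric enumeration to N = 60 (tests) / N = 40
(acceptance script). The full acceptance run completes in a few minutes.

## Known limitations

- No Steiger filtering or F-statistic weak-instrument pruning; no
  MR-RAPS/contamination-mixture estimators.
- MVMR omits measurement-error bias correction.
- The HEIDI filter uses a single reference instrument.
- The colocalization clusterer is a simplified divisive scheme; only the
  discrimination behavior (shared vs distinct causal variants) is
  validated, not equivalence with published software.
- TMM/log-CPM and the DE weighting approximate the reference R
  implementations; exact numerical equality is not claimed.
- Cross-database annotation (druggability, clinical evidence) is out of
  scope; protein functional groups and phenotype categories are input
  metadata.
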