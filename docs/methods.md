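# Methods

## The design being modelled

The pipeline targets a crossed-line allele-specific-expression (ASE)
design: wild-derived isofemale lines, genetically cloned for one haploid
genome and each crossed to the sequenced reference strain, so that every
RNA-seq library is heterozygous reference/wild with known phase. Lines
come from the cross of two continents × two latitude classes (temperate,
tropical); a subset of lines per population contributes a biological
replicate library. Allele-informative reads — those overlapping exonic
SNPs that distinguish the two haplotypes — form, per gene and library, a
(wild_count, ref_count) pair. Everything downstream consumes that table.

## SNP filtering and allele counting

A called SNP is trusted only if its minor state could not plausibly be
produced by systematic sequencing error. The worst case is every error at
a site pushing toward the same incorrect base, so with per-base error rate
`e` (default 0.01, a phred-20 floor) the number of same-direction errors
among `d` reads is Binomial(d, e). `min_supporting_reads(d)` returns the
smallest `m` with P(X ≥ m) < α (default α = 1e-4; strict inequality, with
a non-strict option since the wording of such thresholds varies). The
threshold is non-decreasing in depth; representative values are m = 4 at
depth 15 and m = 7 at depth 100. Further filters: total depth ≥ 15,
exactly two observed states, intersection with a gene interval, and
membership (with matching alleles) in an external high-quality SNP
whitelist read from a sites-only VCF. Pileups and VCFs are 1-based; BED
intervals are 0-based half-open and converted internally; intersection
ignores strand.

Reads assigned wild at one site and reference at another are contradictory;
the default rule drops the read (smallest information loss). An
alternative drops sites whose conflict rate among overlapping reads
exceeds a threshold, then any still-conflicted reads. After resolution a
read contributes exactly once to one allele of one gene; reads whose sites
span multiple genes are excluded.

Residual mapping bias is summarised as pooled per-gene and per-sample
reference-allele proportions, with genes stratified as biased toward
(> 0.55), away from (< 0.45) or neutral to the reference, so any analysis
can be repeated within strata.

## The ASE model

Per gene, wild counts are binomial with a logit-linear mean combining fixed
effects with a genotype-level random intercept `u ~ N(0, σ_g²)` and an
observation-level random intercept `v ~ N(0, σ_r²)`. The observation-level
effect realises "biological replicate as a random effect": it equips every
library, replicated or not, with extra-binomial dispersion, and replicate
pairs share `u` but not `v`.

Because `v` is observation-level, the marginal likelihood factorises over
genotypes; each genotype contributes a 1-D outer integral over `u` whose
integrand is a product of 1-D inner integrals over `v`. Both are evaluated
by adaptive Gauss–Hermite quadrature: the inner integrand's mode is found
by damped Newton iterations (the log-integrand is strictly concave), the
outer mode by Newton steps using the exact gradient (a posterior-score
identity) with curvature from central differences of that gradient, and
the quadrature grid is recentred and rescaled there. Nine nodes per
dimension (default) leave the log-likelihood stable to well under 1e-4 when
the node count is doubled (`results.check_quadrature()`). σ → 0 collapses
the corresponding integral to a point mass, so the boundary of the
parameter space is evaluated exactly rather than approached numerically.

Optimisation is L-BFGS-B on (β, σ_g, σ_r) with σ ≥ 0, objective tolerance
1e-8 (ftol 1e-11), starting values from pooled logits and per-genotype
empirical logit spread, and a Nelder–Mead fallback on reported
non-convergence; non-convergence is always flagged, never silent. Kernels
are numba-compiled; the first call in a fresh environment pays a one-off
compilation cost.

The ASE test drops the genotype effect and refers twice the log-likelihood
gap to χ² with 1 df, matching the conventional likelihood-ratio treatment
of this test; because the null value lies on the boundary, this reference
is conservative, and the 0.5·χ²₀ + 0.5·χ²₁ mixture is available as an
option. When the full fit lands below the reduced one (a flat profile near
σ_g = 0), it is refitted from the boundary solution before the statistic is
formed, so the nesting inequality holds to numerical tolerance. FDR control
is Benjamini–Hochberg; genes are significant at FDR < 0.20. Genes enter
testing only if enough biologically replicated genotypes cover them — read
here as ≥ 12 genotypes whose two replicate libraries both have counts
(threshold and the both-replicates requirement configurable, since the
source protocol's phrasing admits a per-sample reading).

The mean reference-allele proportion of a gene is `expit(−intercept)` of
the full fit (wild counts are the modelled successes).

## Allele grouping

For a gene with ASE, lines are sorted by replicate-summed log₂ wild/ref
ratio (pseudocount 0.5 on both alleles only when one count is zero, and
only for ordering/display — model fits use raw counts). Every top-group
size 1…L−1 is scored by refitting the mixed model with a two-level Group
fixed effect, genotype and replicate effects retained. The
maximum-likelihood split wins; ties within 1e-6 go to the most balanced
split and are flagged when all splits tie. An option restricts the
enumeration to (number of non-replicated lines) − 1, a literal reading of
the source protocol; the default enumerates all splits because the
restriction appears to be a slip. The group whose mean log₂ ratio is
nearest 0 is the reference-CRE group (exact ties: the larger group,
flagged); the alternate group's sign decides whether the wild allele is the
high- or low-expression allele, and per-line high/low calls follow
membership. ASE magnitude is the difference of group mean log₂ ratios.
High-allele frequencies per population, the pooled major/minor designation
(ties to high) and the minor-allele frequency derive from those calls.

## Clinal statistics

Total expression is normalised to counts per million (library size =
column sum); genes need ≥ 1 cpm in ≥ 10 samples (non-strict, per "at
least"). Libraries can be down-sampled to an exact common total by
multivariate hypergeometric draws across genes. The per-continent
differential-expression stage is pluggable; the default is Welch's t on
log₂(cpm + 0.5), since all downstream statistics consume only signs and
p-values. Cross-continent concordance counts sign quadrants among genes
significant on either continent and tested on both; the concordant
proportion is reported with both Wilson (no continuity correction) and
Clopper–Pearson intervals — the two in-text worked examples are each
reproduced by one of the two methods and no single method reproduces both,
so both are always reported. CI bounds are rounded half-away-from-zero to
whole percent for display.

Population-mean ASE uses a cell-means Population fixed effect; the
latitudinal ASE difference is tropical − temperate per continent. The
latitude test compares Latitude + Continent + Latitude×Continent against
Continent alone (2 df; a 1-df interaction-only variant exists). Spearman
correlations are tie-corrected with a t-approximation p, switching to
exhaustive permutation for n ≤ 8. Fisher's exact test (two-sided,
hypergeometric enumeration convention, sample odds ratio) drives the ASE
enrichment of latitudinally differentiated genes, per-region enrichment
with BH adjustment, and the power-matched variant, which thins the
higher-coverage gene set's counts hypergeometrically to match the other
set's per-gene total distribution quantile-by-quantile before re-running
the ASE tests. Major/minor expression effects take genes with minor-allele
frequency < 0.30 and test the mean log₂ major/minor cpm ratio against 0
with a one-sample t. The QC screen flags samples beyond k·SD (default 3)
on the leading principal components of standardised log₂ cpm; the rule is
this package's own, as outlier criteria are rarely stated.

## The synthetic-data generator

The generator inverts the analysis model. Defaults mirror the emulated
design: 2 continents × 2 latitudes, 13 genotypes per population, 4 of them
replicated. Per gene: a cis effect δ ~ N(0, cre_effect_sd²) (default SD
1.0 logit, or a fixed δ for planted studies); carrier status per genotype
drawn from a per-population high-allele frequency (0.5 unless a cline is
planted — `clinal_frequencies` builds the 0.8 tropical / 0.2 temperate
pattern on one or both continents); genotype noise σ_g = 0.3 and
observation noise σ_r = 0.3 (logit); depth negative-binomial with mean 100
and dispersion 5 per (gene, library); a small additive logit shift toward
the reference (default 0.004, the scale implied by a ~50.1% mean reference
proportion). Per-gene random streams spawn deterministically from one
master seed. Total expression is negative-binomial with log-normal
gene baselines; carrying the high-expression allele multiplies the mean by
`total_expression_coupling` (default 1.0 = no coupling). Pileup simulation
emits 50:50 biallelic true SNPs and worst-case systematic errors
(Binomial(depth, e) toward one alternate base) for filter testing.

Depth parameters are guesses — per-gene allele-informative depth in the
real data is unknowable without raw reads — and are configurable. The
generator does not emulate: alignment and true mapping bias (the bias is a
logit shift, not a read-loss process), correlated expression between genes,
batch or lane structure, library-composition effects on cpm, or
non-Gaussian genotype effects. Passing recovery tests therefore show the
estimators are correct under the stated model, not that the model captures
every property of real libraries.

## Study sizes in tests and the acceptance script

Simulation studies are sized for a single-CPU run: null calibration uses
1000 genes with 12 genotypes each; variance recovery 200 genes at the full
52-genotype design, depth 200, σ_g = 1; planted-partition grouping 200
genes of 16 lines at separation 1.5 log₂, constant depth 300 and residual
SDs 0.1 (small residual noise so that the split search, not per-line
ordering noise, is what is measured); end-to-end clinal recovery 8
replicate runs of 200 genes plus 4 one-continent controls. The acceptance
script repeats these at 500/100/100 genes and 4+2 runs. Interval and
threshold checks are exact and effectively instant.

## Known limitations

- The χ²₁ reference for the boundary LRT is conservative; calibration
  tests bound, rather than match, the nominal level.
- The exhaustive split search refits L−1 mixed models per gene; for many
  lines and many genes this dominates runtime (warm-started between
  consecutive splits, but still the costliest stage).
- The observation-level random effect cannot separate replicate-pair
  covariance from within-library overdispersion with single-library
  genotypes; σ_r is identified mainly by the replicated subset.
- Power-matching equalises per-gene totals but not their distribution
  across libraries within a gene.
- The Group fixed effect is estimated on the same data used to choose the
  split, so the grouped model's likelihood is not a valid test of group
  existence; the split is descriptive, downstream of an independent ASE
  call, exactly as in the source protocol.
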