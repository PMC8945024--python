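# Methods

This note records the models, parameter choices and limitations behind
`monostim`, in the order the pipeline runs them.

## Study design

The design is a full crossing of donors, treatment arms and timepoints:
an untreated attachment control (0 h), and four arms (RPMI medium, T3,
LPS, T3+LPS) at the later timepoints. DNA methylation is collected at 0
and 24 h; RNA at 0, 4 and 24 h. The default is three donors, matching
the scale at which this kind of in vitro monocyte experiment is usually
run; with `n` donors the design yields `n*(1 + 4)` methylation samples
and `n*(1 + 8)` RNA samples. All comparisons are pairwise between arms
at one timepoint, with the 0 h control always taken at timepoint zero.
Time is deliberately not modeled as a continuous covariate: early (4 h)
and late (24 h) responses are biologically distinct programs, and the
downstream category logic consumes pairwise contrasts only.

## Synthetic study generator

The generator is first-class, tested code: it defines the conditions
under which every statistical guarantee of the package is demonstrated.

**Methylation.** Beta values arise on the logit scale,

    m_ps = logit2(b_p + offset_p(arm)) + u_pd + e_ps,

where `b_p` is the probe baseline (uniform on (0.1, 0.9) for null
probes), `offset_p(arm)` the planted beta-scale arm offset, `u_pd ~
N(0, donor_sd^2)` a donor intercept shared across arms within a donor,
and `e_ps ~ N(0, sd_p^2)` measurement noise. Betas are the inverse
logit, clipped to (1e-6, 1-1e-6). Working on the logit scale keeps
values in (0, 1) while making the planted beta-scale group difference
equal to the requested magnitude in expectation (the smoothing bias of
the nonlinearity is shared between arms and cancels to well below
0.001 in the group difference — verified by the Monte-Carlo tests).

Defaults: `noise_sd = 0.10` (log2-logit units, i.e. a per-sample beta SD
of about 0.017 at beta = 0.5 — typical of the high precision of
methylation arrays on purified cell populations), `donor_sd = 0.15`, and
per-probe noise SDs drawn from a scaled inverse-chi-square with 20 prior
degrees of freedom so that probe variances are heterogeneous the way the
empirical-Bayes machinery assumes. Probe coordinates cluster like CpG
islands (runs spaced 50–800 bp, with 5–50 kb jumps between runs) on six
synthetic 50 Mb autosomes; 1% of probes get a failing detection p-value,
1% a SNP flag, 1% a cross-reactivity flag and 2% are placed on sex
chromosomes, so the quality filter always has work to do. Planted
effects go to clean autosomal probes.

**Effect classes.** Each planted effect is one of: differentiation
(offset in every cultured arm), differentiation attenuated by T3 (the T3
and T3+LPS arms get the offset minus an attenuation), T3-specific (T3
arm only), LPS-induced (LPS and T3+LPS), LPS attenuated by T3+LPS, and
unique co-stimulation (T3+LPS only). The default panel plants 750
probes (magnitude 0.15, attenuation 0.10) among 20,000 and 360 genes
(log2FC 1.5, attenuation 1.0) among 5,000, leaving well over 10,000 null
features for calibration. Directions are contiguous within a class so
planted neighbours share a sign and region calling has material to work
with. Panel counts scale proportionally when a smaller study is
requested.

**Expression.** Counts are gamma-Poisson (negative binomial) around
`baseline * libsize * 2^offset` with dispersion 0.02 — the low end of
what paired sorted-cell RNA-seq shows, appropriate for a donor-blocked
design — log-normal baselines (median ~150 counts), and donor-specific
library factors (SD 0.15). An `XIST` gene is always present with
near-zero mean under the default all-male simulation (a high-expression
female option exists), so expression-based donor sex assignment is
testable.

**What the generator does not emulate:** array chemistry and
normalization artifacts, bisulfite conversion error, probe
cross-hybridization structure, genomic covariation of methylation with
sequence context, isoform structure, and count overdispersion that
varies with mean. Passing recovery tests therefore demonstrate that the
statistics and set logic behave as specified under a faithful
statistical model of the design — not that any particular biological
dataset would yield the same counts.

## Probe filtering

Probes are dropped when detection p > 0.01, when a SNP overlaps the
interrogated CpG, when flagged cross-reactive, or when on a sex
chromosome (all donors male by default; sex-chromosome intensities are
unreliable in mixed contexts anyway). Removals are logged per reason and
surfaced in the manifest.

## Differential methylation

Hypothesis testing runs on M-values, `log2(b/(1-b))` after clipping at
1e-6: the paper-scale beta values are variance-compressed near 0 and 1,
and the logit transform is the standard stabilization. Effect sizes are
still reported as beta-scale delta-beta, because the DMP threshold is
defined on that scale. Both the modeling scale and donor blocking are
exposed as switches (`on_m_values`, `block_donor`).

Each probe is fit by least squares with an intercept, a group indicator,
and donor indicator columns; the group coefficient is tested two-sided.
Empirical-Bayes moderation follows the standard hierarchical model
`s^2 ~ s0^2 F(d, d0)`: matching the mean and variance of `log s^2`
against their digamma/trigamma expressions yields `(d0, s0^2)` (with a
Newton inversion of the trigamma), the posterior variance is
`(d0 s0^2 + d s^2)/(d0 + d)`, and the moderated t has `d0 + d` degrees
of freedom. When the observed spread of variances is no wider than
chi-square sampling noise the prior df is infinite and all variances
collapse to the common value; `prior_df = 0` recovers the ordinary t
exactly. Constant probes report effect 0 and p = 1.

DMP calling uses strict inequalities, `|delta-beta| > 0.05` and
unadjusted `p < 0.05`. No multiplicity correction enters any calling or
category decision; a Benjamini-Hochberg column is emitted for
transparency only.

## Differential expression

Library normalization is median-of-ratios (the reference profile is the
per-gene geometric mean; size factors are re-centered to geometric mean
1). The per-gene model is `log2(count/sf + 0.5) ~ group + donor`; the
0.5 pseudocount makes zero handling explicit. This log-linear fit is the
package's own estimator: the downstream logic consumes only (log2FC, p,
mean RPKM), and the recovery guarantees are stated against the planted
truth, not against any particular count-model implementation. Moderation
is available (`moderate_variances=True`) but off by default: with
log-normal baselines the per-gene variances depend strongly on the mean,
and a mean-blind prior would over-shrink low-expression genes; the
unmoderated t at 2 residual df is conservative and calibrated.

DEG criteria (all strict): `|log2FC| > 0.58`, `p < 0.05`, mean RPKM > 1
computed over the samples of the two compared groups (a switch for the
all-samples mean exists), and the sign-agreement filter. The
fold-change-of-means test used as the modifier for LPS-induced genes
passes when `|log2(mean_a/mean_b)| > 0.58` **and** every donor's
individual ratio moves the same way; zero means are guarded with a 0.1
RPKM pseudocount. The threshold is stated on the log2 scale; a linear
ratio of exactly 1.5 (log2 = 0.585) therefore passes, and exactly
2^0.58 fails.

## Category engine

Induced sets use route semantics: a route is a target arm and a list of
reference arms, and it fires when every target-vs-reference comparison
passes its thresholds with one shared sign. Categories with several
routes (LPS-induced: LPS vs {RPMI, 0 h} or T3+LPS vs {T3, 0 h}) take the
union, de-duplicated; the direction comes from the first firing route in
the declared order and every firing route enters the provenance. Union
semantics guarantee the monotonicity property that loosening a threshold
never shrinks a set. Attenuation keeps an induced feature when the
modifier comparison (T3 vs RPMI; T3+LPS vs LPS) is significant with the
*opposite* sign at the same strict thresholds — the modifier's own
p-value and effect, not an interaction term, matching the pairwise
structure of the analysis. Uniqueness keeps a co-stimulation-specific
feature when it additionally differs from LPS alone with the *same*
sign.

The tertile partition ranks a gene set by the ratio of mean expression
(T3+LPS over LPS, 0.1 pseudocount) descending and cuts it into three
classes whose sizes differ by at most one, extras assigned top-first;
ties break by gene id ascending. Both remainder and tie rules are
conventions fixed here for determinism. Sets smaller than three fall
back to a single middle class with a warning. Summary fractions are
printed as `x/y (z%)` with one decimal, round-half-even.

## DMR calling

Candidates are probes with p below threshold; runs are chained while
consecutive candidates share a chromosome and sign and are at most 1 kb
apart (insignificant probes in between neither join nor break a chain).
A chain is a DMR when it has at least 3 CpGs and at least one CpG beyond
the delta-beta threshold; the region p combines member p-values by
Stouffer's method with equal weights. Gap-chaining replaces
kernel-smoothing region statistics deliberately: the three acceptance
criteria are then enforceable by construction, and the 1 kb gap default
mirrors the conventional smoothing bandwidth of region callers. The
same-sign rule operationalizes "correlated methylation change".
Interval intersection is 0-based half-open; abutting intervals do not
overlap.

## Annotation

Single nearest TSS within 1 Mb (not a basal-plus-extension regulatory
domain — the analysis needs one gene per probe). Equidistant ties
resolve to the lexicographically smallest gene id. Distances are signed
downstream-positive relative to the gene's strand. The promoter/distal
boundary is 5 kb; the boundary value itself, undefined under strict
`<`/`>` readings, is assigned to PROMOTER and documented here.

## Enrichment

PWM scanning scores every offset on both strands with log2-odds against
a uniform background; `N` bases contribute 0. The default hit threshold
is 80% of the motif's maximum attainable score, configurable per motif.
Enrichment is a one-sided hypergeometric tail over target vs background
sequence counts (HOMER-style ZOOPS/binomial machinery is intentionally
not reproduced; the composite filter is what defines the result):
p < 0.05, fold change in abundance > 1.5 (percent of target sequences
with the motif over percent of background sequences), difference > 5
percentage points, at least two target hits, and the TF-expression
exclusion (log2 mean RPKM < 0 in every treatment group). Percentages
count sequences, not hits. The default background is the non-target
windows of the same universe. Term enrichment applies the same test per
term with the p < 0.05 / two-gene filter; no ontology propagation is
performed, and no curated term content ships with the package.

## Summaries

Row z-scores use ddof = 1; constant rows are zeroed and flagged. PCA
treats samples as observations, centers features, and fixes each
component's sign so its largest-magnitude loading is positive, making
coordinates reproducible. The default PCA input is raw beta values of
the selected probe set, with a z-score switch. The expression trajectory
statistic is the median over features of the per-feature group mean,
then the log2 ratio to the 0 h value ("median of means"); the
alternative reading ("mean of medians") is available as a flag.
Methylation trajectories report the change in median beta. Ranked
tables sort by |effect| descending with gene-id tie-breaks.

## Orchestration and provenance

The configuration is one declarative block; validation rejects unknown
keys, enumerates type errors rather than failing fast, and checks sign
constraints. A SHA-256 hash over the analysis-relevant parameters
(everything except the output directory and the plotting switch) is
stamped into every output filename and the manifest, and the manifest
records per-stage counts including the `x/y (z%)` category summaries.
All randomness descends from the single configured seed through
independent child streams, so two runs with one configuration are byte
identical.

## Problem sizes

The default desk-scale study is 20,000 probes, 5,000 genes and three
donors; a full pipeline run takes a few seconds on one CPU, and the test
suite under ten. Calibration checks use at least 10,000 null probes;
oracle-equivalence checks use instances up to 1,000 features where
brute-force evaluation stays exact and fast.

## Known limitations

* The expression estimator is a log-linear fit on normalized counts, not
  a negative-binomial Wald/LRT; at very low counts its p-values are
  conservative rather than exact.
* The moment-matched variance prior assumes exchangeable probe variances;
  a mean-variance trend is not modeled on either assay.
* Nearest-gene assignment knows one TSS per gene; isoform-level TSS
  choice is out of scope.
* The motif stage is criteria-faithful, not tool-faithful: a given HOMER
  run would produce different p-values while applying the same filter
  thresholds.
* Attenuation percentages depend on strict-inequality thresholds; values
  sitting exactly on a threshold are excluded by design.
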