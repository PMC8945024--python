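# monostim

Differential DNA methylation and gene expression analysis for in vitro
monocyte stimulation studies, together with a synthetic study generator
that plants every effect class the analysis is meant to detect.

## The problem

Monocytes cultured ex vivo start differentiating toward macrophages within
hours, and stimuli layered on top of that trajectory — the thyroid hormone
triiodothyronine (T3), the TLR4 agonist lipopolysaccharide (LPS), or both —
each leave their own marks on the methylome (Illumina EPIC beta values) and
the transcriptome (RNA-seq counts). With a design of

    donors x {0 h control, RPMI, T3, LPS, T3+LPS} x {0, 4, 24} h

the scientific questions are set-logic questions over pairwise
comparisons:

* which probes/genes change during differentiation (RPMI vs 0 h)?
* which of those changes does T3 **attenuate** (T3 vs RPMI significant,
  opposite in sign: `0 h < RPMI > T3` patterns)?
* which changes are **treatment-specific** (changed versus *every*
  reference arm with one sign, e.g. T3 vs both RPMI and 0 h)?
* which co-stimulation changes are **unique** to T3+LPS (different from
  0 h, RPMI, T3 *and* from LPS alone)?

`monostim` implements this chain end to end: probe quality filtering,
per-feature moderated linear models with donor blocking, DMP/DEG calling,
the multi-arm category engine, region (DMR) calling, nearest-gene
annotation, motif/term enrichment, and descriptive summaries.

## Statistical core

* **Methylation.** Testing runs on M-values `log2(beta/(1-beta))` with the
  model `M ~ group + donor` per probe; effect sizes are reported as
  beta-scale group differences (delta-beta). Residual variances are
  shrunk by empirical Bayes: the posterior variance is
  `(d0*s0^2 + d*s^2)/(d0 + d)` with `(d0, s0^2)` moment-matched to the
  marginal distribution of the per-probe variances, and the moderated t
  gains `d0` degrees of freedom — essential with three donors.
  A **DMP** satisfies `|delta-beta| > 0.05` and unadjusted `p < 0.05`.
* **Expression.** Counts are normalized by median-of-ratios size factors;
  the model is `log2(count/sf + 0.5) ~ group + donor`. A **DEG** satisfies
  `|log2FC| > 0.58` (linear fold change 1.5), unadjusted `p < 0.05`,
  mean RPKM > 1 over the compared groups, and sign agreement between the
  model fold change and the fold change of mean RPKM (noise filter).
* **DMRs.** Runs of same-sign significant CpGs chained at gaps <= 1 kb,
  reported when >= 3 CpGs and >= 1 CpG beyond the delta-beta threshold;
  region p by Stouffer combination.
* **Enrichment.** PWM log-odds scanning of +/-100 bp windows on both
  strands; one-sided hypergeometric enrichment with the composite filter
  p < 0.05, fold > 1.5, difference > 5 percentage points, >= 2 target
  hits, and exclusion of motifs whose TF shows log2 mean RPKM < 0 in
  every treatment group.

All of it is exercised against a generator whose ground truth table
records every planted effect, so sensitivity, false discovery and exact
category recovery are measurable.

## Worked example

```python
from monostim import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, n_probes=20_000, n_genes=5_000, outdir="demo")
manifest = run_pipeline(cfg)
print(manifest["stages"]["categories"]["meth"])
```

prints (seed 1, generator defaults: 3 donors, 750 planted probes among
20,000, 360 planted genes among 5,000):

```
{'DIFFERENTIATION': '413',
 'DIFF_ATTENUATED': '101/413 (24.5%)',
 'T3_SPECIFIC': '101',
 'LPS_INDUCED': '255',
 'LPS_ATTENUATED': '51/255 (20.0%)',
 'T3LPS_SPECIFIC': '218',
 'T3LPS_UNIQUE': '50/218 (22.9%)'}
```

Read: 413 differentiation-associated DMPs were called (400 planted — the
extra are the expected false positives at unadjusted p < 0.05 combined
with the delta-beta gate); 101 of them are attenuated by T3 (100
planted); the 50 planted unique co-stimulation probes are recovered
exactly out of the 218 probes that differ from all LPS-free arms.
Category counts are reported in the `x/y (z%)` form throughout the
manifest, every output file carries the configuration hash
(`c1d602e62499` here), and re-running with the same configuration
reproduces every table byte for byte.

The same run writes per-comparison statistics TSVs, DMP BEDs, DMR BEDs
with probe intersections, nearest-gene tables split into promoter
(<= 5 kb from TSS) and distal classes, motif/term enrichment tables, PCA
coordinates, z-scored heatmap matrices, and XIST-based donor sex calls
(all MALE under the default male simulation).

A CLI mirrors the library (`monostim run-all`, `simulate`, `diff-meth`,
`diff-expr`, `categorize`, `dmr`, `annotate`, `enrich`, `report`).

## Layout

```
src/monostim/
  design.py      study design (donors x arms x timepoints x assays)
  synthetic.py   planted-effect generator (methylation, counts, sequences)
  matrices.py    BetaMatrix / CountMatrix / RPKMMatrix containers + TSV IO
  diffmeth.py    probe filtering, M-value models, moderation, DMP calling
  diffexpr.py    RPKM, size factors, gene models, DEG calling, FC-of-means
  categories.py  induced/attenuated/specific/unique sets, tertiles
  dmr.py         gap-chained DMR calling and interval intersection
  annotate.py    nearest-gene within 1 Mb, promoter/distal split
  enrichment.py  PWM scanning, motif and term hypergeometric enrichment
  report.py      z-scoring, PCA, trajectories, ranked tables
  config.py      validated declarative configuration with provenance hash
  pipeline.py    stage orchestration and manifest
  cli.py         command-line surface
```

See `docs/methods.md` for the modeling assumptions, generator design and
known limitations.
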