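# Methods

This note documents the models and procedures implemented in `rnalof`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Alternative polyadenylation usage (Ψ)

For a gene with polyadenylation sites ordered proximal → distal along
the transcribed strand (ascending genomic coordinate on "+", descending
on "−") and indexed m = 1..n, the usage metric is the
expression-weighted mean of the normalized site rank:

Ψ = Σₘ TPMₘ·(m−1)/(n−1) / Σₘ TPMₘ.

Ψ is a *relative* 3′UTR-length summary: 0 = fully proximal, 1 = fully
distal, ½ = uniform usage. It is undefined (reported as NaN, never
dropped or zero-filled) when n < 2 — the rank denominator vanishes — or
when the gene has zero retained TPM in a sample. Undefined values keep
genome-wide tables rectangular and make missingness explicit.

**Expression filter.** A PAS is retained when its mean TPM across *all*
samples in the analysis is strictly greater than 5. The mean-across-
samples scope (rather than per-sample filtering) keeps n identical in
every sample, so Ψ values are comparable across samples; per-sample
filtering would silently change the metric's support per column.
After filtering, sites are re-indexed 1..n′ preserving order, and Ψ is
computed over n′: the formula's (n−1) must match the index range of the
sites actually evaluated.

**Differential usage.** Per gene, a two-sided Welch t-test on
per-replicate Ψ, requiring ≥ 2 defined values per condition; genes
failing that are reported as untested rather than omitted. The default
decision rule is a raw p < 0.01 cutoff with no multiplicity correction —
this stage screens for usage shifts rather than controlling a
genome-wide error rate — and BH adjustment is available as an option.
When both groups have zero variance the t statistic is undefined; the
implementation reports p = 1 when the means agree (no evidence of
change) and p = 0 when they differ, matching the limit behaviour.

## Annotation-free intron clustering and differential splicing

Junction evidence is one record per intron per sample with a read count
and the minimum read overhang (anchor) on either side. Records with an
anchor below 6 bp are discarded (boundary inclusive: 6 bp passes);
short-anchor junction reads are dominated by alignment artifacts.

Introns are clustered by transitive closure of "shares a start or an
end coordinate on the same chromosome and strand", on counts pooled
across samples; clusters totalling fewer than `minclureads = 10` reads
are discarded. Strand-unknown junctions are clustered apart from
stranded ones at the same coordinates — merging them would fabricate
connectivity. Cluster ids are assigned after sorting by (chrom, smallest
start, strand) so outputs are deterministic and diffable. No secondary
refinement (e.g. minimum per-junction usage fraction within a cluster)
is applied.

**Cluster test.** Counts are pooled within each condition and the
junction × condition table tested with a G-test (log-likelihood ratio,
df = J−1), BH-adjusted across tested clusters at 0.05. This pooled test
deliberately ignores replicate-level overdispersion — it is a documented
simplification of Dirichlet-multinomial cluster regression, adequate for
planted-effect recovery in simulation but anticonservative on real data
with strong biological replicate variability. Junctions with zero counts
in both conditions contribute nothing to G and are not removed from the
degrees of freedom. Per-condition junction proportions (summing to 1
within each condition over cluster members) are reported for
spliced-pair displays.

## Cryptic-exon quantification

A cryptic event is a canonical exon–exon junction plus one or more
junctions flanking a cryptic exon. Coordinates must match junction
records exactly; an absent junction counts zero reads — absence is
evidence of non-use, not an error. Percent cryptic inclusion is
100·S/(S+K) with K the canonical count and S the *mean* of the
cryptic-junction counts: a read pair spanning into a cryptic exon
supports each flanking junction once, so the mean counts each inclusion
event once while the sum (available as an option) would double-count
two-junction events. When S+K = 0 the percent is undefined and the
sample is flagged "no evidence". In the per-condition summary, samples
with zero canonical reads are flagged and excluded from percentage
statistics (their rate is 100% or undefined regardless of depth), but
still count toward detection (any cryptic read) when cryptic evidence
exists.

## Differential expression and phenocopy scoring

**Normalization.** Median-of-ratios size factors over genes with
strictly positive counts in every sample; normalized value =
count / factor. The per-gene geometric-mean reference is frozen at fit
time so new samples can be normalized consistently — required for
out-of-sample PCA projection.

**DEG calling.** A Welch t-test on log2(normalized + 1) per gene, BH
adjustment across genes, fold change log2((mean₂+1)/(mean₁+1)) on
normalized means (pseudocount 1, configurable). A gene is a DEG only
when padj < 0.05 AND |log2FC| > 0.25. This is a deliberately simple
stand-in for a negative-binomial GLM with dispersion shrinkage: the
package's reusable content is the normalization, the double cutoff and
the downstream comparison logic. The cost is power — with three
replicates the Welch statistic has ≈ 4 degrees of freedom, putting a
floor on attainable p-values — so at realistic noise this caller is far
more conservative than a moderated NB model. log2FC is always
condition₂ over condition₁ with condition order taken from the sample
map, and the output columns name both conditions to prevent silent sign
flips.

**Fold-change concordance.** Pearson r of log2 fold changes between two
contrasts over a supplied gene universe, pairing genes by id, dropping
(with a logged count) genes lacking a finite fold change in either
contrast, and excluding a configurable gene set first. The canonical
exclusion is the TDP-43 transcript itself (TARDBP): its autoregulation
makes it rise under a loss-of-function *mutation* but fall under
*knock-down*, so keeping it would deflate an otherwise genuine phenocopy
correlation.

**Reference PCA with projection.** Pipeline: frozen median-of-ratios
normalization → log2(normalized+1) as the variance-stabilizing stand-in
(a pragmatic replacement for a fitted VST; adequate for projection
geometry at these depths) → restriction to a fixed gene subset
(typically a DEG-list intersection) → gene-wise centering on the
*reference* means → SVD loadings. Query samples reuse every stored
piece and are never re-centered on themselves; projecting a reference
sample therefore reproduces its own score to numerical precision
(round-trip error < 1e−8 is asserted in tests). Defaults: k = 2
components, centering without unit-variance scaling.

## Synthetic-data generator

The generator emulates the study design the analyses were built for —
two genotypes × three replicates — with planted, recoverable effects.
One master seed feeds three fixed-offset substreams (APA, junctions,
counts) so each dataset can be regenerated independently and all outputs
are byte-identical under a fixed config.

* **APA.** Site count per gene uniform on `pas_count_range` (default
  2–5); baseline usage from a symmetric Dirichlet(2); gene expression
  log-normal (median 200 TPM, σ = 1); per-sample TPM = expression ×
  usage × gamma multiplicative noise (CV 0.2 by default — replicate
  dispersion of bulk TPM is weakly constrained, so it is exposed as
  config). For a planted gene the baseline is blended with an endpoint
  mass of ΔΨ at both the most proximal and most distal site, and the
  mutant condition moves a mass of exactly ΔΨ from one endpoint to the
  other (direction random). Because the Ψ weights of the endpoints are
  0 and 1, the expected Ψ shift equals ΔΨ exactly, which makes recovery
  analytically checkable; shifts above 0.5 are rejected as infeasible
  under this blend. This is a stand-in generative model, not a model of
  any real dataset.
* **Junctions.** Per event and sample, cryptic reads ~ Poisson(depth·ρ)
  — both junctions flanking a cryptic exon carry the same count, since
  one inclusion read pair supports each once — and canonical reads ~
  Poisson(depth·(1−ρ)), with ρ = `cryptic_rate` in the mutant and
  `wt_cryptic_rate` (default 0) in wild-type, so the observed cryptic
  fraction is binomial around ρ. Event records always carry anchors
  ≥ 6 bp, modelling extraction run with a read-level anchor filter;
  the configurable anchor-failure fraction applies to the background
  junctions, which are emitted in runs of three sharing a splice site to
  give the clustering stage real connectivity. Zero-count junctions are
  not written, as in real junction files.
* **Counts.** Gene means log-normal, scaled to the target library size;
  counts gamma-Poisson (negative binomial) with a common dispersion;
  planted DE genes draw log2FC ~ Normal(0, 1) with |log2FC| < 0.25
  resampled so every planted effect clears the calling threshold. A
  designated TARDBP-like gene is planted up (+1) in mutant-style
  contrasts and down (−1) in knock-down-style contrasts.
  `simulate_phenocopy_pair` builds both contrasts over one shared DE
  gene set with 80% shared directions by default, the configuration the
  concordance and projection analyses expect.

**Default dispersion.** The NB dispersion default is 0.01, the regime of
deeply sequenced isogenic cell cultures. The choice is deliberate: the
simplified Welch caller's p-value floor at n = 3 means that at
dispersions ≳ 0.02 essentially no planted gene is recoverable, which
would make every downstream phenocopy analysis vacuous; at 0.01 the
caller recovers a called-DEG fraction (~2–3% of genes) in line with
published TDP-43 comparisons, while leaving the caller's conservatism
visible (only a quarter of planted effects are called).

**What passing tests do not show.** The generator draws independent
genes with a common dispersion, multiplicative noise and no correlation
structure, batch effects, GC/length bias, isoform structure beyond PAS
usage, or mapping artifacts. Recovery and calibration results under
these conditions validate the implementation's logic and its behaviour
under its own assumptions — they do not certify calibration on real
RNA-seq data, where replicate overdispersion (cluster G-test) and
non-normality (Welch at n = 3) matter.

## Numerical choices and degenerate inputs

* Undefined Ψ and untested genes/clusters are NaN-flagged rows, never
  silent omissions.
* Zero-variance-in-both-groups t-tests return p = 1 (equal means) or
  p = 0 (unequal), replacing scipy's NaN.
* BH adjustment rejects out-of-range or missing p-values; callers
  adjust only over tested units.
* Cluster and junction ordering, ids, and file output are fully
  deterministic under a fixed seed; floats are written in pandas'
  default repr, so reruns are byte-identical.
* Size-factor computation drops zero-count reference genes from a query
  sample's median rather than propagating −∞.

## Known limitations

* The DEG caller and cluster test trade statistical efficiency for
  transparency; neither reproduces NB-GLM or Dirichlet-multinomial
  results numerically.
* Ψ comparisons assume the same retained site set across samples; a
  gene whose expression collapses in one condition can lose sites to
  the mean-TPM filter and change its n′ relative to an analysis run on
  either condition alone.
* The G-test df convention keeps all-zero junctions in a cluster; with
  many such junctions p-values are mildly conservative.
* Problem sizes in tests (hundreds to a few thousand genes, tens of
  seeds) are chosen for fast, deterministic validation of the planted
  effects; they are desk-scale stand-ins, not re-analyses of any
  published dataset.
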