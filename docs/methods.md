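# Methods

This note documents the models and procedures implemented in `blastoseq`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that affect results.

## Repeat quantification (`te_quant`)

Repeat-derived reads multimap heavily; when the aligner reports a single
random alignment per multimapper, per-copy quantification is meaningless
but per-type quantification (pooling all genomic copies of one RepeatMasker
`repName`) is well defined. The stage implements:

1. **Annotation loading.** RepeatMasker `.out` dialect (1-based inclusive
   coordinates, joined `class/family` column) or an extended 9-column BED.
   `Simple_repeat` and `Low_complexity` classes are dropped by default —
   they are alignment artifacts rather than transposon transcription. A
   `repName` must map to exactly one (family, class); anything else is an
   annotation error, because downstream aggregation keys on that mapping.
2. **Fragment filter.** A pair is kept iff each mate is *completely
   included* in some repeat element and neither mate overlaps a gene body
   by ≥ 1 bp (unstranded). Containment is evaluated per mate against
   single elements: a mate spanning two abutting copies of the same
   repName is **not** contained. This mirrors full-overlap counting
   semantics and keeps the rule checkable against a naive interval oracle
   (the test suite enforces exact agreement over 100 random
   annotation/fragment draws).
3. **Counting.** Fragment-level (pair) counting, unstranded. Pairs whose
   mates sit in elements of two different repNames are discarded as
   ambiguous and counted separately; the upstream tools' behaviour for this
   corner is not documented anywhere we could verify, so the discard rule
   is our explicit, logged choice.
4. **FPKM.** Depth is the aligner's *input read* count divided by two
   (reads → fragments), not the number of aligned fragments; repFamily
   FPKM sums counts and summed lengths over members *before* dividing. A
   regression test pins the family formula against the tempting-but-wrong
   mean-of-member-FPKMs.
5. **DNA covariate.** DNA-transposon classes are transcriptionally silent;
   their apparent RNA FPKM tracks genomic-DNA carry-over. The per-sample
   sum of DNA-class FPKM is exported as a model covariate, and samples
   above median + 3·MAD are flagged. The 3·MAD default replaces a manual
   inspection step and is configurable; with MAD = 0 (identical samples)
   no one is flagged.

Interval queries are backed by an interval tree; correctness, not speed,
is the contract, and the oracle-agreement test is the guarantee.

## Genotyping and QC (`embryo_geno`)

- **Sexing**: score = summed size-factor-normalized counts of Y-linked
  genes (*Ddx3y*, *Eif2s3y*); male iff score > threshold. The default
  threshold of 10 normalized counts separates the bimodal score
  distribution this design produces (tens-to-hundreds in males, ~0 in
  females); ties go to female, a configurable ambiguity band marks
  borderline calls, and a gap statistic (largest sorted-score gap over the
  score range) diagnoses whether two clusters are actually present.
- **Allele calling** at a mutated codon distinguishes wild-type, missense
  and 3-bp-deletion templates by exact substring match against the full
  read sequence. Deletion alleles are only visible through soft-clipped
  tails: an end-to-end aligner maps the read prefix and clips the rest, so
  the clipped bases spell the post-deletion junction. Matching on the
  query sequence (clipped bases included) makes the caller independent of
  deletion-aware alignment. Defaults: ≥ 3 informative reads for any call
  (`min_reads`), heterozygous when two alleles each reach `min_reads` and
  ≥ 20% of informative reads (`het_min_fraction`). A WT call supported
  only by absence of mutant reads carries a `wt_by_absence` qualifier,
  since absence of deletion reads cannot formally exclude a heterozygote.
- **Tag genotyping** is a step function: wild type iff tag-mapping reads
  < 72. The cutoff is a calibrated constant of the assay design this
  package models; the tests pin the boundary (71 → WT, 72 → tagged).
- **QC**: discard embryos with < 10⁶ reads, then per-axis
  median ± 3·MAD outliers in mitochondrial fraction and rDNA fraction
  (computed over depth-passing embryos). The MAD rule is a reproducible
  proxy for a visual scatter-plot inspection and is a documented departure
  from it. Fewer than 4 depth-passing embryos make robust statistics
  meaningless, so the outlier step is skipped with a warning. The filter
  is deterministic, permutation-invariant and idempotent, and every
  discarded embryo carries reason codes.

## Differential expression (`diffexpr`)

Counts are modeled as K_gj ~ NB(s_j·q_gj, α_g) with log q_gj = x_j'β_g.

- **Size factors**: median-of-ratios over features positive in every
  sample; a single sample gets 1 by convention; absence of any
  all-positive feature is an error (a pseudo-reference fallback exists
  conceptually but is off, so the failure is loud).
- **Fitting**: IRLS, vectorized across genes for a shared design; offsets
  log s_j; linear predictor clipped at ±60 to guard overflow; a 1e-9 ridge
  stabilizes near-degenerate weight matrices.
- **Dispersion**: per-gene profile ML with the Cox–Reid adjustment
  −½ log det(XᵀWX), maximized by a coarse grid plus golden-section refine
  over log α ∈ [log 1e-8, log 10]; a parametric trend a₀ + a₁/μ is fitted
  to the gene-wise estimates by iterative gamma-weighted least squares
  with ratio-outlier exclusion; final estimates maximize the CR likelihood
  plus a log-normal prior centered on the trend, with prior variance
  max(MAD-based residual variance − trigamma((n−p)/2), 0.25). This is an
  approximation of the published shrinkage estimator family; small
  numerical discrepancies against any specific tool are expected and out
  of contract.
- **Inference**: Wald z on the condition coefficient, referred to a t
  distribution with n − p degrees of freedom. With the k = 6
  unwanted-variation covariates and ~20 samples, the normal reference is
  visibly anticonservative; the t reference keeps type-I error inside the
  tested [0.03, 0.07] band in both the plain and the RUV-adjusted designs.
  Fold changes are unshrunken MLEs on the log2 scale (display shrinkage is
  out of scope). Features with failed fits get NA p-values and leave the
  BH denominator.
- **Independent filtering** scans baseMean-quantile thresholds 0–95% in 1%
  steps, recomputes BH on survivors, and keeps the threshold maximizing
  rejections at the cutoff (ties → lowest threshold). Filtered features
  get padj = NA.
- **Control genes**: baseMean > 100, padj > 0.8 and |log2FC| < 0.05 in
  *every* supplied comparison. The fold-change criterion is read as an
  absolute value — a signed reading would admit strongly down-regulated
  genes as "controls", defeating the purpose — with a `signed=True` escape
  hatch for the literal reading.
- **RUV factors**: row-centered log(normalized+1) of the controls,
  sample-side singular vectors as W (orthogonal columns, sign fixed so
  each column's largest-magnitude entry is positive). log(x+1) is the
  package's pseudocount choice for both RUV and PCA transforms.
- **PCA**: drop features with mean normalized count ≤ 10, keep the top
  1,000 by variance of log2(normalized+1), centered SVD; variance
  fractions are relative to the retained matrix, so they sum to ≤ 1.

## Enrichment and figure statistics (`enrichment`)

- Ranking score −log10(padj)·sign(log2FC) with padj floored at 1e-300 to
  avoid infinities; ties broken by |log2FC| toward the extreme end of the
  list, then feature id, making the order total and deterministic.
- GSEA: running sum with hit increments |score|^weight (normalized within
  the set) and miss decrements 1/(N−N_h); ES is the signed maximum
  deviation, with the earliest-position extremum winning exact-magnitude
  ties (a 1e-9 tolerance absorbs float noise). The null permutes gene
  labels — at the ranked-summary level sample permutation is impossible —
  with NES = ES / mean |null ES| of matching sign and a two-sided
  empirical p with +1 smoothing: p = (1 + #{|ES_null| ≥ |ES|})/(1+B).
  Default set-size bounds 10–500.
- Over-representation: upper-tail hypergeometric, BH across sets,
  gene_ratio = overlap/|hits|.
- Developmental-delay constructions: per-feature blastocyst value =
  max(E3.5 ICM, E3.5 TE); developmental log2FC = 0.75·(TE vs 8-cell) +
  0.25·(ICM vs 8-cell); Pearson correlation between mutation-induced and
  developmental fold changes reported for all features and for the
  significant subset.
- The chi-squared test is implemented as goodness of fit of observed
  genotype counts against stated (Mendelian) proportions — that is how the
  genotype-ratio figures such tests accompany are constructed — not as a
  contingency test; a contingency use is possible by passing the
  appropriate expected proportions.
- Classical tests (Wilcoxon rank-sum exact, Fisher exact, Welch t,
  Pearson r, hypergeometric) delegate to scipy.stats; the test suite
  verifies each against full-enumeration oracles for all inputs with
  n + m ≤ 10 (and all 2×2 tables with total ≤ 10). Zero-variance corner
  cases return the documented conventions (p = 1 for identical degenerate
  groups, error for the all-zero Fisher table).
- Bootstrap CI: percentile interval of B = 1,000 resampled means,
  deterministic under seed; coverage for a normal mean is verified to sit
  in [0.92, 0.97] over 500 seeded samples of n = 100.

## The synthetic-data generator (`simdata`)

The generator emulates the *structure* of the study's data, not its
biology: the genome is random sequence, and only interval/sequence
mechanics, count distributions and planted effects matter downstream.

- One RNG stream per generator operation, derived from the master seed via
  `SeedSequence(seed, spawn_key=(label,))` (fragment simulation adds a
  per-sample subkey), so adding a generator never perturbs existing
  outputs and identical configs give byte-identical outputs.
- Annotation: non-overlapping repeat elements (400–1,500 bp) and gene
  bodies (2–6 kb) on autosomes, each catalog repName appearing at least
  once, with optional requested gene/repeat overlap; designated Y-linked,
  mitochondrial, rDNA-proxy, tag and mutation-target genes on dedicated
  contigs. Requesting more elements than fit raises a sizing error.
- Fragments: multinomial per feature with weights rate × length; insert
  sizes 160–320 bp, 80-bp mates; a configurable fraction (default 10%) of
  repeat fragments straddle the element boundary to exercise the filter;
  DNA-contaminant fragments are drawn uniformly over DNA-class elements
  with Binomial(depth, fraction) count. Deletion-allele reads carry the
  post-deletion junction as a trailing soft clip (match + soft-clip CIGAR
  only — no sequencing-error model, no quality simulation, no full CIGAR
  grammar). SAM output is headered and coordinate-sorted.
- Counts: gamma–Poisson (exact NB) with mean
  baseline · 2^(log2FC·group) · 2^(loading·batch) · sf and a single
  dispersion knob; batch loadings are N(0, batch_strength) per gene; size
  factors log-normal with σ = 0.15 (geometric mean 1). Empirical moments
  are tested against (μ, μ+αμ²) and the α→0 Poisson limit.
- Embryo cohorts: per-embryo totals ~3×10⁶ reads (10% CV), mt fraction
  0.05, rDNA fraction 0.02 by default, with explicit overrides for planted
  QC outliers; Y-gene rate 50 in males, 0 in females; tag reads
  Poisson(500) for tagged genotypes, 0 otherwise; 20 codon-spanning reads
  per embryo drawn from the configured allele mix.

What passing tests do **not** show about real data: no mapping bias,
GC/length effects, sequencing errors, partial-containment edge cases from
soft-clipped repeat alignments, cross-contamination between samples, or
biological covariance between genes. Calibration and power results
transfer only to the extent the NB-with-covariates model holds.

## Pipeline problem sizes and thresholds (`pipeline`)

The workflows default to desk-scale problem sizes — 24 embryos, 400 genes,
60 repeat elements, 6,000 fragments per embryo (4,000 in the replicated
acceptance runs), 500 GSEA permutations — chosen so a full end-to-end run
takes seconds while every stage still operates in its intended regime.
Thresholds mirror the study design: genes at padj < 0.05, repeats at
padj < 0.1, depth ≥ 10⁶, k = 6, tag cutoff 72, all configurable. Reports
are flat JSON/TSV with a SHA-256 over the payload; reruns with the same
config are byte-identical, and every discarded sample or fragment is
accounted for with a reason.

## Known limitations

- The NB engine does not implement outlier replacement (Cook's distance),
  likelihood-ratio tests, or fold-change shrinkage.
- Per-locus repeat quantification and EM reassignment of multimappers are
  out of scope by design; the repName pooling is the point.
- The sexing threshold and QC outlier rule are reproducible proxies for
  steps that were originally visual; on real data both should be inspected
  via the provided diagnostics rather than trusted blindly.
- GSEA p-values are empirical with +1 smoothing; with the default 10,000
  permutations the smallest attainable p is ~1e-4.
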