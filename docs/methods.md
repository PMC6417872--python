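# Methods

## Variant classification and retention

Each somatic variant is re-interrogated in every sample of a pair from
pileup counts (depth, alt reads) at the union of the two call sets and
assigned exactly one of five labels. With depth threshold *D* = 20 reads
and VAF threshold *V* = 5% (both inclusive — "at least 20×"):

| label | condition |
|---|---|
| detected | alt > 0, depth ≥ D, VAF ≥ V |
| low_coverage | alt > 0, depth < D |
| low_VAF | alt > 0, depth ≥ D, VAF < V |
| undetected_low_coverage | alt = 0, depth < D |
| undetected | alt = 0, depth ≥ D |

The five labels partition all cases. The corner where alt > 0 but both
depth and VAF fall below threshold is unreachable at the defaults (one
alt read in ≤ 19 gives VAF ≥ 1/19 > 5%) but can occur at other settings;
insufficient coverage takes precedence and the label is `low_coverage`.

A tumor-called variant is **retained** when independently called in the
PDX and **recovered** when the PDX caller missed it but re-interrogation
finds ≥ 1 alt read. One supporting read is deliberately permissive: it
operationalizes "accounted for after relaxing filters" and is the
configuration under which detected% + recovered% equals the overall
shared% exactly (before rounding). Reported percentages use one decimal
with round-half-up; passage (P0/P2) percentages are truncated integers —
both modes are explicit arguments, matching the two conventions such
tables are printed in.

VAF concordance is ordinary least squares of PDX VAF on tumor VAF over
variants with alt reads in both samples and ≥ 20× coverage in both
(scipy's linregress; R² = r²). Fewer than 3 usable points or constant
tumor VAFs raise rather than returning a degenerate fit.

## Purity estimation

**LOH-mode tumor purity.** At heterozygous germline sites inside
copy-neutral LOH regions, the tumor carries two copies of one allele, so
minor-allele signal comes only from contaminating normal cells:
E[MAF] = (1 − p)/2, hence p = 1 − 2·mode(MAF). The mode is located as the
peak bin of a histogram (bin width 0.01 over [0, 0.5]) and refined by a
Gaussian KDE over the unique MAF values within ±5 bins of the peak,
maximized on a 501-point grid. The weighted-unique-value KDE makes the
estimate invariant to site order and to duplicating the site list, and
its bandwidth shrinks with the number of distinct sites, so recovery
error decreases as sites accumulate (~±0.03 at 500 sites and 80×
depth). Two degenerate paths: if every observation in the peak bin
coincides, that exact value is the mode (so all-zero MAFs give purity
exactly 1); if the KDE is singular, parabolic interpolation over the
peak bin and its neighbors is used. A hemizygous-deletion model,
m = (1 − p)/(2 − p), is available behind `model="hemizygous_deletion"`;
copy-neutral is the default because it is the simplest standard identity
and the field's usual first assumption.

**Xenograft read purity** is human-specific reads over all five
classification classes (human-specific, mouse-specific, both, neither,
ambiguous). The denominator includes the minor classes because every
non-human-specific class is removed before downstream analysis.

## Copy-number concordance

Segments (absolute copy number) are projected onto fixed 10 kb windows;
each window takes the length-weighted mean of overlapping segment means
and windows without coverage are masked. Chromosome-end windows shorter
than 10 kb are kept at their true width, which preserves the
genome-average copy number exactly. Pairwise Pearson correlation uses
jointly unmasked windows; pairs with < 50% joint coverage are flagged,
not dropped. Matched pairs are compared with all other off-diagonal
pairs by a one-sided rank-sum test (below).

Focal gene calls use the base-pair length-weighted median segment mean
over the gene ± 100 kb — the weighted median (not a plain median of
segment rows) is what makes the call invariant to splitting a segment
into identical pieces. Amplified means median > 3, lost means
median < 1.5 absolute copies. Arm-level calls are a deliberately simple
invented rule, configurable: gained if ≥ 50% of an arm's unmasked
windows sit at ≥ 2.5 copies, lost if ≥ 50% sit at ≤ 1.5 — symmetric with
the focal thresholds.

## Rank-sum comparison of matched vs unmatched pairs

The matched-vs-unmatched comparison (used identically for copy number
and expression) is a one-sided Wilcoxon rank-sum test with mid-ranks for
ties. When the number of rank assignments C(n₁+n₂, n₁) is ≤ 2×10⁵ the
p-value is computed by exact enumeration, P(rank sum ≥ observed); all
ties therefore give p = 1 under "greater" rather than an arbitrary
continuity value. Larger configurations use the tie-corrected normal
approximation (scipy's mannwhitneyu).

## Expression filtering and concordance

PCA runs on log2(x+1), gene-centered values (log stabilization is the
standard choice for FPKM-scale data), keeping all n_samples − 1
components. Signs are fixed by making each component's
largest-magnitude gene loading positive, so results are byte-for-byte
reproducible. For each component the top ceil(1% × n_genes) genes by
absolute loading are collected — ties at the cutoff are all included
(a deterministic superset beats arbitrary tie-breaking) — and the union
is removed. The post-filter correlation matrix defaults to the linear
FPKM scale (a log-scale flag exists) because genome-wide sample
correlations are conventionally quoted on the abundance scale.

## Subtype classifier and CAF score

Expression is log2-transformed when given on the linear scale and
gene-median-centered per dataset; per-dataset centering is the sole
cross-platform harmonization. The classifier is a random forest
(default 500 trees, mandatory seed) over the 638-gene signature rows
(missing signature genes are imputed as 0 — the centered null — and
reported; > 20% missing refuses). Class probabilities are ensemble vote
fractions; calls with top probability below 0.4 are flagged *marginal*
(the threshold is an invention — "marginal" is not defined numerically
anywhere authoritative — and is an explicit argument). The CAF score is
the per-sample median centered expression over the 412 CAF genes,
requiring ≥ 80% of them present; mesenchymal samples are compared with
each other subtype by the one-sided rank-sum test.

## Synthetic cohort generator

The generator emulates the data-generating process the analyses assume,
so every stage is testable without controlled-access data.

- **Clone tree.** A founding clone at cancer-cell fraction (CCF) 1 with
  nested subclones (child CCF ≤ parent CCF). Cell-population fractions
  are f_c = CCF_c − Σ children CCFs.
- **Expected VAF** of a variant private to clone c in a sample whose
  cancer-cell fraction is q (tumor purity, or PDX human-cell fraction):
  q·CCF_c / (q·⟨CN⟩ + (1 − q)·2), one variant copy against the
  population-averaged local copy number (diploid unless a clone CN
  event overlaps the locus).
- **Engraftment bottleneck.** PDX clone fractions are a multinomial
  draw of N founding cells (default 10⁵) from the tumor's population
  fractions; a subclone at fraction f is lost with probability
  (1 − f)^N.
- **Read counts.** Depth is negative-binomial (mean 80, dispersion 3 —
  overdispersion mimicking capture sequencing; the mean matches typical
  exome depth); alt reads are binomial at the expected VAF; the normal
  sample uses a 0.1% error rate (near-zero VAFs without exact zeros).
- **Copy number.** Observed segment mean = q·(clone-CN mixture) +
  (1 − q)·2, plus Gaussian noise (sd 0.05).
- **Expression.** In log2 space: subtype centroid + a patient effect
  shared between matched tumor and PDX (the tumor-intrinsic component)
  + a stromal vector (loading on the CAF genes) scaled by (1 − purity)
  for tumors and by 0 for PDXs + i.i.d. noise; the mesenchymal
  centroid additionally carries the stromal vector, reflecting that
  this subtype's signature is largely CAF-driven. Values are emitted as
  2^x (linear, FPKM-like).
- **Defaults** are chosen as plausible study conditions: 16 patients,
  purities drawn in 0.4–0.95, PDX human-cell fraction 0.95, ~180
  variants per patient over a 2 × 50 Mb toy genome (2 × 10 Mb or
  smaller in tests for speed), detection thresholds mirroring the
  analysis (20×, 5%).

What the generator does **not** model: read-level artifacts (mapping
error, strand bias, FFPE damage), germline contamination of somatic
calls, subclonal copy-number/variant interaction beyond the local-CN
adjustment, linked variants/phasing, batch effects and library-size
variation in expression, and immune (non-CAF) infiltrate components.
Passing tests therefore demonstrate internal consistency of the
estimators under the assumed generative structure, not robustness to
every artifact of real sequencing data.

## Numerical and reporting choices

- Percentages: round-half-up via decimal arithmetic (never float
  banker's rounding); truncation mode for passage tables.
- All randomness flows from explicit `numpy.random.default_rng` seeds;
  fixed seed ⇒ byte-identical outputs, including the pipeline's
  `report.json` (stage timings go to the log file, which is excluded
  from the canonical report rendering).
- Coordinates: 0-based half-open everywhere internally and in BED/SEG;
  VCF output is 1-based and read back with conversion.
- Degenerate inputs raise (`ValueError`) rather than returning NaN:
  empty architectures, zero bottlenecks, < 3 regression points,
  constant matrices, empty rank-sum groups, zero read totals.
- Problem sizes in the test suite and acceptance script (e.g., 2 × 4–10
  Mb genomes, 250–520 genes, 8–16 pairs, 100-cohort power loops) are
  chosen so the full run completes in minutes on one core while keeping
  every Monte-Carlo check inside its stated tolerance.

## Known limitations

- The LOH purity identity assumes copy-neutral LOH; regions under
  hemizygous deletion bias the copy-neutral estimate upward (the
  alternative model is provided but region-wise model selection is not).
- Retention metrics are computed over whatever variant table they are
  given; no filtering to non-silent or reviewed calls is applied.
- The arm-level calling rule is an invention (documented above);
  published arm-event counts depend on the original caller's rule.
- The subtype classifier's real-data accuracy depends on the training
  cohort (microarray/RNA-seq harmonization is by per-dataset median
  centering only); simulation centroids are the test surface here.
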