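# Methods

This note documents the models and procedures implemented in `hccsvr`,
the parameters that matter, the design choices made where the design
was genuinely open, and what the synthetic cohort does and does not
emulate.

## Somatic-variant filtering

A candidate somatic call from a tumor/normal exome pair carries
read-level metrics of the kind `bam-readcount` reports. Ten elimination
criteria are applied (see README for the list). Numerical conventions:

* Every inequality is strict exactly as stated, so a variant sitting on
  a boundary (quality 50, depth 20, control VAF 2.5%, clipped length
  90, position fraction 0.05, MAPQ ratio 0.8, length difference 80)
  **passes** that criterion.
* All ten criteria are evaluated for every variant — no short-circuit —
  so the verdict carries the complete set of violated criteria, which
  supports removal attribution and per-criterion reporting.
* Criterion 7 (MAPQ1/MAPQ0 ratio among variant reads) passes when
  `var_mapq0 = 0`: the ratio is undefined and there is no MAPQ0
  evidence, so the conservative direction is to keep the variant.
* Criterion 8 is interpreted as |mean read length over reference-
  supporting reads − mean over variant-supporting reads|.
* Criterion 9 uses a one-sided Fisher exact test on the 2×2 table
  {reference, variant} × {MAPQ0, MAPQ≥1}. Under the null the variant
  row's MAPQ0 count is hypergeometric; the p-value is the upper tail
  P(X ≥ var_mapq0). The closed form for the extreme table ref=(0,10),
  var=(5,0) is 1/C(15,5) = 1/3003, used as a test anchor.
* VAFs are percentages (the control-VAF cut-off is 2.5, not 0.025).
* The in-house false-positive blacklist (criterion 10) ships empty —
  such lists are site-specific — and is supplied as a chrom/pos/ref/alt
  TSV.

Quality is treated as an abstract caller score compared against 50; no
assumption is made about its Phred-ness. Thresholds are taken as fixed
constants of the procedure, not re-calibrated here.

## Mutational signatures

Single-base substitutions are folded into the 96 pyrimidine-centered
trinucleotide classes (purine-reference mutations are reverse-
complemented, so a mutation and its reverse complement share a class).
A sample's normalized spectrum **m** is approximated as a non-negative
mixture **Pw** of reference signature columns by iterative forward
selection, the strategy of the standard deconvolution tool re-authored
here:

1. start with an empty support;
2. for each candidate signature, re-optimize all supported weights by
   cyclic bounded line search (golden-section on [0, 1−Σ other
   weights], `scipy.optimize.minimize_scalar(method="bounded")`) and
   record the squared reconstruction error;
3. add the candidate giving the largest error reduction; stop when the
   relative improvement falls below 1e-4;
4. zero final weights below the floor (default 0.06, the reference
   tool's convention; configurable) and rescale the kept weights to the
   pre-floor sum.

The error never increases across iterations (each step re-optimizes a
superset). Weights are in [0,1] with Σw ≤ 1; `1 − Σw` is reported as
residual. No trinucleotide-frequency renormalization between exome and
genome contexts is applied (a flag exists at the decomposition call
site in the sense that a custom matrix may be supplied).

The packaged 96×30 matrix is a **synthetic stand-in** with the shape
and numbering of the COSMIC v2 catalogue, generated deterministically
(`synthesize_reference_signatures`, seed 20220217) from sparse gamma
draws with three disjoint characteristic peaks per signature; pairwise
cosine similarity stays below 0.35, so mixtures are identifiable. The
real catalogue, where available, can be passed as a TSV with the same
row labels.

## Copy-number variation

Segments carry a copy-number estimate, a segment-test p-value and an
adjusted mirrored-BAF log ratio. Classification: gain (p < 0.001,
CN ≥ 2.5), loss (p < 0.001, CN ≤ 1.5), copy-neutral LOH (p < 0.001,
1.5 < CN < 2.5, log2 mBAF ≥ 0.2), else neutral. The CN-LOH band is
open at both ends: at CN exactly 2.5 or 1.5 the gain/loss arms take
precedence, since their bounds are explicitly inclusive, and each
segment gets exactly one label.

Joint depth/BAF segmentation models (saasCNV-class tools) are out of
scope; `segment_log_ratio` is declared plumbing: recursive binary
segmentation on the mean log2 depth ratio (Welch-gated at α = 1e-3,
minimum 10 SNVs per side), per-segment p from a two-sided one-sample
t-test of log-ratios against 0, copy number 2·2^mean, and
log2(mean|BAF−0.5|/0.25) as the mirrored-BAF statistic. Coordinates are
1-based inclusive internally (SEG-like export unchanged; a BED export
with 0-based half-open coordinates is provided).

Burden comparisons count non-neutral segments per sample per class and
compare groups by Mann–Whitney; whether to count segments or affected
samples was open, and segments per sample was chosen as the more
sensitive statistic.

## Integrative expression × copy-number aberrations

For catalogue genes only: amplification requires oncogene role,
tumor/matched-normal fold change ≥ 5 and gene-level CN ≥ 2.5; deletion
requires TSG role, fold change ≤ 0.2 and CN ≤ 1.5. Thresholds are
inclusive, with a 1e-9 tolerance so log2/exp2 round-trips cannot flip a
boundary case. Fold change uses the same patient's adjacent normal
tissue as baseline (the natural reading where matched normals exist;
samples without one are skipped with a warning). Gene-level CN is taken
from the segment containing the gene midpoint, ties resolved to the
earlier segment. The group shortlist keeps genes with two-group Fisher
p < 0.1 — computed on sample counts, not event counts — or with events
in ≥ 6 samples overall.

## Expression signatures

Raw intensities are log2-transformed and each sample shifted so its
75th percentile is 0 (idempotent; invariant to per-sample scaling). A
signature score is the arithmetic mean of the normalized values of the
set's member genes present in the matrix, with coverage reported; the
TP53-inactivation score is the fixed four-gene set *CDC20*, *PLK1*,
*CENPA*, *KIF2C*. Scores are computed on tumor columns by default;
matched-normal columns are available for tumor-minus-normal variants of
any analysis. Volcano tables use per-gene two-sided Mann–Whitney with
Benjamini–Hochberg q-values alongside the raw p (fold change = group
mean difference on the log2 scale). Hierarchical clustering is Ward
linkage on Euclidean distances over gene-wise z-scored rows (constant
genes dropped); dendrograms export to Newick.

## Cohort statistics

* Chi-squared without Yates continuity correction by default (matching
  the closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) on 2×2 tables); a
  correction flag exists.
* Two-sided Fisher exact p by summation of all tables, at fixed
  margins, with probability ≤ the observed table's (the R convention).
  `method="auto"` selects Fisher when any expected count is below 5;
  both p-values are always reported.
* Mann–Whitney: two-sided, average ranks; exact enumeration when the
  smaller sample has ≤ 20 tie-free observations, otherwise the normal
  approximation with tie correction. All-tied data returns p = 1 with a
  warning.
* Spearman with average-rank ties; constant vectors yield NA with a
  warning.
* Survival: Kaplan–Meier product-limit curves per group (lifelines)
  with the standard log-rank chi-squared across groups.
* p53 IHC: mutant-pattern at ≥ 30% distinct nuclear staining
  (boundary inclusive), null-type when no immunoreaction is observed at
  all, wild-type otherwise; mutant-pattern and null-type jointly flag
  aberrant p53 for the mutation-concordance 2×2.
* Report percentages are rounded half-up to one decimal (so 4/35 →
  11.4, 1/24 → 4.2, 6/34 → 17.6); raw fractions are kept alongside.

## The synthetic cohort

`cohortsim` generates, from a single seed, a cohort whose statistical
structure matches the study design the pipeline targets. Defaults are
the study conditions and are not tuned per run:

* **Strata**: 34 HCV-positive / 8 SVR-DAA / 24 SVR-IFN / 3 SVR-other
  tumors, each with matched normal liver.
* **Driver prevalences** (fraction of samples mutated, planted as fixed
  counts round(f·n) with randomized carrier assignment, so cohort
  margins are deterministic): ARID2 6/34, 0/8, 1/24; PREX2 1/34, 1/8,
  3/24; KEAP1 1/34, 1/8, 3/24; TP53 12/34, 5/8, 5/24, 1/3; CTNNB1
  10/34, 2/8, 8/24, 1/3. TP53/CTNNB1 rates are free parameters of the
  design; the chosen TP53 contrast (62.5% vs 20.8%) gives a chi-squared
  p near 0.03 at these stratum sizes. Fixed counts rather than binomial
  draws make the frequency layer checkable against its configuration.
* **Variants**: per sample, Poisson(80) true somatic calls (10% indels)
  across a ~2,000-gene universe tiled over 22 synthetic chromosomes,
  with trinucleotide contexts drawn from a fixed signature mixture
  (0.5/0.3/0.2 over signatures 1/5/16) and a random strand emitted;
  clean QC metrics are drawn from truncated normals comfortably inside
  every threshold. Poisson(25) artifacts per sample each violate
  exactly one of criteria 1–9 (verified at generation time by the
  filter itself; the injected criterion is recorded in the truth
  labels).
* **Expression**: gene baselines N(7, 1.5) log2 units, gene-wise
  Gaussian noise sd 0.4. A per-tumor latent factor loads on the
  TP53-inactivation and chromosomal-instability sets with a loading
  solved (by root-finding) to give a configurable score correlation
  (default 0.9); the PI3K/mTOR set takes a weaker shared loading plus a
  private factor, emulating a moderate (~0.7) correlation. Planted
  group effects (log2 shifts before noise): +1.0 TP53-inactivation,
  +0.8 CIN, +0.8 PI3K/mTOR and +2.0 SKP2 in SVR-DAA tumors; −1.0 on the
  cytolytic / B-cell / interferon-response sets in SVR non-tumorous
  liver. The matrix is exported on the linear scale so the
  normalization stage is exercised.
* **CNV**: chromosome-wide neutral segments (CN ≈ 2, non-significant p)
  partitioned around planted events; deletions Poisson per sample with
  group rates 3.0 / 6.0 / 1.5 / 2.0 (the DAA excess), gains ~2 per
  sample, CN-LOH ~1. Planted losses sit over catalogue TSGs and knock
  tumor expression down 3 log2 units (gains: oncogenes, +3), giving the
  integrative caller true positives.
* **Clinical**: stage, portal-vein invasion and liver-background
  categories drawn from per-group marginal tables of the targeted study
  design (e.g. cirrhosis enriched and Vp1 invasion frequent in the DAA
  stratum); exponential survival at 0.0025/month (~86% five-year OS)
  with uniform follow-up censoring, identical across groups; p53 IHC
  percentages concordant-with-noise with planted TP53 mutations; ground
  truth tumor content in place of purity estimation.

What the generator does **not** emulate: realistic genome coordinates
or gene lengths, germline variation, read-level data (metrics are drawn
directly, not recomputed from alignments), probe-level microarray
artifacts, correlated passenger structure, subclonality, or
purity-driven signal attenuation. Passing tests therefore demonstrate
the correctness and power of the pipeline's inference machinery under
the stated noise model — not performance on real sequencing data.

## Problem sizes and determinism

The default cohort (69 tumors, ~7,400 variant candidates, 2,000 × 138
expression matrix, ~2,300 segments) runs end-to-end in well under a
minute; replicated power checks use 100 seeded replicates of the
expression layer at the 8-vs-24 stratum sizes. All randomness flows
from `numpy.random.default_rng(seed)`; identical seeds give
byte-identical output files (verified by SHA-256 in `report.json`).

## Known limitations

* The synthetic reference-signature matrix and non-TP53 gene-set
  fixtures are placeholders; conclusions about specific real signatures
  or pathways require the real catalogues (drop-in TSV/GMT).
* The changepoint stage is a mean-shift segmentation of the depth
  ratio; it does not jointly model BAF and is not a substitute for
  allele-specific CNV callers on real data.
* Printed-table clinical p-values from the targeted study design are
  not all reproducible from their marginal counts under either plain
  chi-squared or Fisher conventions; the statistics layer therefore
  reports both p-values rather than privileging one.
* Survival simulation is exponential and group-independent; the
  survival layer is validated by construction (step heights, label
  invariance, power under a planted hazard ratio), not against a
  cohort effect.
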