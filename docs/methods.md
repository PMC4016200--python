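# Methods

## Experimental design modelled

The pipeline targets a two-tissue Cd-exposure time course in rice
seedlings: roots and shoots sampled before treatment (0 h) and at 1 h
and 24 h after transfer to 50 µM CdSO₄, with 2–3 biological replicates
per condition sequenced as separate libraries. All analyses compare a
treated timepoint against the 0 h baseline within a tissue, giving four
contrasts (root/shoot × 1 h/24 h).

## Quantification

Expression is RPKM computed from uniquely mapped reads: 10⁹·C/(N·L)
with L the union length of the transcript's exon intervals (1-based,
inclusive; computed from GTF via gffutils). A transcript is *detected*
when RPKM > 0. Replicates are QC'd by Pearson correlation of
log2(RPKM+1) — the log transform stabilises the heavy right tail of
expression values; correlations below 0.92 emit a warning but do not
abort, since admission of borderline replicates is a judgement call.
Replicates are merged by summing raw counts and totals (pooling reads).
Pooling, not averaging per-replicate RPKM, is the correct operation for
a proportion-based test and weights deeper libraries accordingly.

## Differential expression

The responsive-transcript test is a likelihood-ratio G-test on the 2×2
table (reads on the transcript vs all other mapped reads) × (baseline,
treatment), natural logarithm, no Williams or continuity correction,
referred to χ²(1). Its null model is multinomial read sampling with
equal transcript proportions — it models sequencing (technical) noise
only, not biological replicate variability. Consequences:

- On data with biological overdispersion the test is anticonservative by
  construction; this is a property of the method, preserved faithfully,
  not corrected into an NB GLM (explicitly out of scope).
- FDR-control simulations therefore run at dispersion 0 (the test's own
  null); the generator's default dispersion (0.05) is used everywhere
  else to exercise realistic data.

P-values are BH-adjusted **within each contrast** (the analysis reports
per-tissue/timepoint counts, so each contrast is a self-contained
family); responsive ⇔ q < 0.01. The tested universe per contrast is
transcripts detected in at least one of its two conditions; undetected
transcripts are carried with G=0, p=q=1, FC=1.

Fold changes add a pseudocount of 1 to **RPKM values**, not raw counts:
(RPKM_t+1)/(RPKM_0+1). Both readings of "1 was added" exist; applying
it on the expression scale keeps FC=1 for transcripts undetected in
both conditions and is the configurable default (`pseudocount=`).

Ranking of top upregulated transcripts sorts by descending fold change
with lexicographic transcript-id tie-break, after restricting to
responsive, upregulated rows and any annotation filter (e.g. "no
microarray probe").

## GO enrichment

One-tailed over-representation per term: p = P(X ≥ k) hypergeometric,
BH within each cluster (clusters — direction × tissue × timepoint — are
independent analyses, so no cross-cluster adjustment), significant at
q < 0.05. The universe is all detected transcripts carrying at least
one annotation; GO-DAG ancestor propagation is not applied (annotation
is taken as given). Heatmap scores are −log10(q) with q floored at
1e-300 so scores stay finite; absent term/cluster pairs score 0.

## Alternative splicing

The splicing pattern of a locus in a condition is the set of splice
sites with RPM strictly > 1 (a site at exactly RPM 1 is inactive). A
locus is AS-capable with ≥ 2 active sites in either condition; a
pattern change is any difference between the two active-site sets. The
percentage denominators are all representative loci, not AS-capable
loci, matching the published reporting arithmetic. The comparison is
symmetric in the two conditions, and strand is ignored.

## Cross-stress sets

Responsive sets use inclusive thresholds (FC ≥ 2 up, ≤ 0.5 down). Venn
partitioning supports 2–4 sets and returns all 2ⁿ−1 exclusive regions;
region counts always sum to the union. Overlap fractions report the
share of a reference set found in the union ("any other stress") and in
the intersection ("all stresses") of the comparison sets, as one-decimal
percentages. Platform id mapping is the caller's responsibility: the
module consumes any fold-change tables keyed by a shared gene id.

## Transporter families and the qPCR panel

Family assignment is by Pfam metal-binding domain with a fixed priority
for multi-domain transcripts (MatE > PDR_assoc > Cation_efflux > Zip >
HMA > Nramp > LCT1, the order of the published domain list). The
reporting filter keeps rows with FC strictly > 5 in ≥ 1 tissue/timepoint
and flags exactly those cells (the printed tables typeset them bold);
fold changes are reported at two decimals.

qPCR relative expression is 2^−ΔΔCt with technical triplicates averaged
first, Ubiquitin1 as reference and the water-only control as the
normalisation condition (control ≡ 1). The response-group classifier
takes U = treatments whose relative expression reaches the up-threshold
(default 2.0) in at least one tissue:

- group 4 if |U| ≥ quorum (default 8 of the 11 non-control media) —
  checked first so "general stress" takes precedence;
- group 1 if U = {Cd}; group 2 if Cd ∈ U, |U| ≥ 2; group 3 if U ≠ ∅
  without Cd; otherwise unclassified.

The 2-fold cut and the quorum of 8 are analysis choices, not measured
constants; both are keyword arguments and are logged in reports.

## Synthetic data generator

The generator emulates the study design at desk scale. Choices and what
they do / do not represent:

- **Counts**: negative binomial with mean N·p_i·2^{lfc} and dispersion
  φ (variance m + φm²); φ = 0 degenerates to Poisson. Defaults: 2 000
  transcripts, 2 M reads/library (the real libraries are ~48 M; the
  G-test's power at 2 M is already near 1 for 8-fold effects, so
  nothing qualitative is lost), 2 replicates, 10% planted DE with
  log2FC ~ |N(2.5, 0.5)| and random sign, φ = 0.05.
- **Abundances** are log-normal (σ = 1.5) per nucleotide, so RPKM spans
  ~4 orders of magnitude as in real libraries.
- **Composition**: means are renormalised per condition, so planting
  strong up-effects genuinely depresses every other transcript's read
  share. A proportion test correctly detects these compositional
  decreases — on synthetic data with many strong planted effects the
  "down" counts include such transcripts. This mirrors real RNA-Seq
  compositionality and is intentional.
- **Planted set sizes** round half-up; sampling ties are resolved by
  the seeded generator. Effects apply to both treated timepoints and
  both tissues.
- **GO annotation**: each term annotates at a 5% base rate; a planted
  (term, cluster, odds) triple raises the annotation odds by the given
  factor inside the planted up- or down-regulated set.
- **Splice tables**: active sites get RPM in (1.5, 50), inactive in
  [0, 0.5), so activity under the RPM > 1 rule is unambiguous and
  noiseless recovery is exact; changed loci toggle one site's activity.
  Real junction counts near the threshold would be noisier — passing
  recovery tests shows correctness of the rule, not robustness at the
  boundary.
- **qPCR panel**: 12 target genes (3/3/2/4 across groups 1–4, the
  group sizes of the published panel), planted 4-fold upregulation,
  Gaussian Ct noise (default sd 0.2). With triplicates the ΔΔCt noise
  sd is ≈ 0.23 cycles, leaving a wide margin to the 2-fold decision
  boundary, hence > 90% accuracy under noise.
- **Determinism**: every consumer (counts, annotation, splicing, qPCR)
  draws from its own named substream of the config seed, so identical
  configs are bit-identical and modules can be regenerated
  independently.

What the generator does **not** emulate: mappability and multi-mapping
artifacts, GC/length bias, batch effects, isoform-level count coupling
within a locus, or non-Gaussian qPCR failure modes. Passing recovery
tests demonstrates the correctness of the implemented rules under the
stated noise models, not performance on real libraries.

## Numerical choices

- G is clipped at 0 against float roundoff; zero cells contribute 0.
- Hypergeometric tails come from scipy's survival function and are
  clipped to [0, 1]; brute-force enumeration is used as an independent
  oracle in tests, never as the implementation.
- BH adjustment delegates to statsmodels (`fdr_bh`); a hand-written
  step-up serves as the test oracle.
- Report TSVs use a fixed `%.6g` float format and LF line endings;
  the manifest is sorted-key JSON without timestamps, making report
  bundles byte-comparable across runs.
- Argmax and ranking ties break to the lexicographically smallest
  transcript id, making all reports order-stable.

## Problem sizes

Simulations in the tests and the acceptance script use 150–5 000
transcripts, 0.2–2 M reads per library, 25–300 splice loci and 5–10
seeds per Monte-Carlo claim. These sizes give stable estimates for every
tested property (e.g. binomial error on the null responsive fraction at
200 000 tests is far below the 1% target) while keeping the full suite
in seconds.

## Known limitations

- The G-test's anticonservativeness under biological overdispersion is
  inherited by design; counts of "responsive" transcripts on real,
  overdispersed data should be read as technical-reproducibility calls,
  not replicate-level inference.
- GO enrichment without DAG propagation understates enrichment of
  ancestor terms.
- The splice-pattern definition (active-site sets) cannot distinguish
  isoform-usage shifts that keep the same active sites.
- Cross-platform fold-change comparisons assume the caller has resolved
  probe-to-transcript mapping.
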