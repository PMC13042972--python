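# Methods

This note records the models, parameter choices and numerical conventions
behind `editome-kit`, and what the synthetic validation does and does not
establish about real data.

## Coordinates and formats

All genomic intervals are 0-based half-open internally.  VCF, GTF and the
pileup tables are 1-based in their files; conversion happens in `io` at
the boundary.  Pileups are site-level TSV tables (chrom, pos, ref, A/C/G/T
counts, mean base and mapping quality, and the count of mismatching reads
whose mismatch lies in the first 6 read bases).  The package deliberately
does not touch reads or BAMs: alignment, duplicate marking and read-level
allele splitting are upstream of its contract, and every filter it
implements operates on site-level counts.

## Self-similarity masking

The genome is tiled into windows of 76 bp at a 19 bp step (no tail window;
a chromosome of length L yields ⌊(L − 76)/19⌋ + 1 windows).  Each window
is re-aligned to the whole genome by exact 16-mer seeding (seeds sampled
every 8 bp within the window, both strands) followed by ungapped
evaluation along the seed diagonal.  The reported alignment is the
maximal-scoring ungapped segment under match +1 / mismatch −3 — the
ungapped analogue of a local aligner's extension, which cannot chain
through mismatch-dense flanks, so a 55 bp exact duplicate reports a 55 bp
alignment rather than a longer low-identity span.  A window with an
off-locus segment of ≥ 61 aligned bases at ≥ 94 % identity marks both the
window and the hit locus; masked intervals are merged.  Masking is
symmetric by construction.  Lowering the identity threshold can only grow
the candidate set, so the mask is monotone in the threshold.

## The filter cascade

Order is fixed and documented: call → read-position → homopolymer →
known-SNP → similarity → region-stratified → presence; every step is
idempotent on its own output.  Defaults:

| parameter | default | note |
|---|---|---|
| min meanBQ / meanMQ | 25 / 20 | typical editing-caller gates; configurable |
| min coverage / edited reads | 10 / 2 | per sample |
| read-position rule | subtract first-6-bases mismatches | first 6 bases only, as specified |
| homopolymer | run ≥ 5 bp, site within ±1 bp | "in a run" read inclusively |
| known SNPs | allele-aware (alt must match) | positional mode available |
| non-repeat support | edited ≥ 3, level ≥ 0.10 | stricter outside repeats |
| repeat support | edited ≥ 2, level ≥ 0.05 | repeats are the canonical substrate |
| presence | ≥ 20 samples and ≥ 10 % of tissue | both bounds must hold |

Multiple alternate alleles at a site collapse to the highest-count alt,
ties broken alphabetically.  Strand correction complements the
substitution type for sites inside minus-strand genes; sites in no gene or
in genes on both strands keep their genomic type and carry an ambiguity
flag.  Strand correction is applied after per-sample calling and before
any spectrum computation.  The presence-calibration curve recomputes
retention and the strand-corrected A-to-G fraction across thresholds; it
is computed after the site-level nuisance filters, where the fraction
rises monotonically to the canonical plateau as sporadic errors drop out.

## Editome characterization

Editing level is edited/coverage per site and sample; a sample's overall
level is Σ edited / Σ coverage over covered catalog sites (the
coverage-weighted ratio, not a mean of ratios — the two differ whenever
coverage and level correlate).  Tissue specificity: entropy in bits of the
tissue-mean profile normalized to sum 1 (missing tissues excluded);
specific ⇔ entropy < 0.4 and range > 0.10.  The entropy base is a
convention; the 0.4 threshold is kept configurable for that reason.
Annotation precedence is exonic > UTR > intronic > up/downstream >
intergenic; coding consequences are computed by reconstructing the codon
from the transcript's CDS intervals in transcription order, so no reliance
on the GTF frame column.

Co-editing modules: sites missing in ≥ 4 tissues are dropped (the
"missing ≥ 4" rule is read as tissues because the matrix is
tissue-averaged), then tissues missing ≥ 50 % of sites, sites with
CV < 0.8 (CV uses |mean| in the denominator; levels are nonnegative in
practice) and sites seen in < 10 tissues.  Adjacency is |Pearson r|^4,
clustered by average linkage on 1 − adjacency with a fixed cut height
(default 0.9); modules below 30 members merge into "grey".  The
topological-overlap transform is intentionally omitted — plain adjacency
clustering is the package's simplified module detector, validated by
planted-block recovery (ARI ≥ 0.8 at within-block r = 0.9) rather than by
equivalence to any external network package.  Hub sites are members with
|correlation to the module eigenprofile| ≥ 0.8 (a definition this package
fixes explicitly; the threshold is configurable).  The scale-free fit
reports R² of the log–log regression of the binned connectivity
distribution.

## cis-edQTL mapping

Phenotype: logit((k + 0.5)/(n + 1)) per sample → OLS residual on selected
PCs → rank inverse-normal transform (average ranks for ties, Blom offset
3/8), giving mean ≈ 0, SD ≈ 1.  PC selection is a permutation
(parallel-analysis) criterion: PCs whose explained variance exceeds the
95th percentile of a column-permutation null (100 permutations, seeded),
taken from the top until the first failure.

Association: OLS of phenotype on dosage per SNP within ±1 Mb, MAF ≥ 0.05,
two-sided t test; the implementation is checked against the
normal-equation oracle to 1e-10.  Site-level significance: phenotype
permutations (default 1000) of the minimum nominal p, a Beta(a, b) fitted
by ML to the null sample, empirical p = Beta CDF at the observed minimum;
the direct rank estimate is always carried and is the fallback if the fit
fails.  BH across sites at q < 0.05.  Conditionally independent signals:
forward stepwise addition while the conditional nominal p clears the
site's Beta-null quantile at 0.05, with backward elimination; conditional
tests use residualized phenotype and genotypes with degrees of freedom
reduced by the conditioning set.  Collinear candidates are skipped.

Type-specificity: an edQTL is type-specific when its maximum r² against
every eQTL/sQTL SNP on the same chromosome within ±1 Mb is < 0.8; a second
pass reports the fraction of retained edQTLs whose eQTL nominal p exceeds
0.05.  Tissue sharing: Spearman rho of slopes over (site, SNP) pairs
significant in at least one tissue of the pair; pairs with < 10 shared
records are flagged low-confidence.

## Allele-specific editing

For each (site, het-SNP) group, individuals with non-zero coverage on both
alleles are matched pairs (default minimum 5 individuals).  Edited counts
follow BetaBinomial(total, μ_a, φ) per allele with a shared overdispersion
φ ∈ [1e-6, 10] absorbing between-individual variation; H0: μ_ref = μ_alt
is tested by a 1-df LRT, fitted by Nelder–Mead on (logit μ, log φ).  The
effect is Δ = logit(μ_alt) − logit(μ_ref).  If either fit fails, a
coverage-weighted paired t-test on pseudo-count logit levels substitutes,
flagged in the output.  The model is a deliberate operationalization of
"matched pairs with estimation uncertainty", validated by calibration
(type-I ≤ 0.07 at α = 0.05 over 1000 null groups) and power (≥ 80 % at
Δ = 1.5 logits, 20 individuals, coverage 50) rather than by equation
identity with any external tool.

## Trait integration

LD score: 1 + Σ r² over same-chromosome neighbors within 1 Mb (window a
package choice, documented here).  Matched controls: same chromosome,
|ΔMAF| ≤ 0.02, |ΔLD score| ≤ 0.1 SD, sampled without replacement where
possible; unmatched focal SNPs are excluded and counted.  The enrichment
statistic is the ratio of mean Z² (focal/controls) with a one-sided
Wilcoxon rank-sum test; the permutation p compares the focal mean Z²
against re-matched control draws (each draw resamples one control per
focal SNP from its precomputed candidate set), which is the ratio
comparison with a common denominator.

Colocalization: Wakefield log-ABF = ½[log(1 − r) + r z²] with
r = W/(W + se²), prior variances W = 0.15² (case-control scale) or 0.2²
(quantitative, configurable), priors p1 = p2 = 1e-4, p12 = 1e-5;
hypothesis sums are combined in log space (H3 via the log-difference
identity), regions are eligible only when the minimum GWAS p < 1e-5.
Clumping is greedy best-p-first at r² ≥ 0.4 within 250 kb, ties by
position then allele.

Heritability: K = Z′Z/m with per-SNP standardized genotypes (no
MAF-dependent weighting), variance components by average-information REML
with an EM fallback step whenever the AI update proposes an invalid state,
components floored at 1e-6·var(y); enrichment of category k is
(h²_k/h²_total)/(M_k/M_total).

## Cross-species lifting

Chain parsing validates the block arithmetic against the declared interval
ends and fails naming the chain id.  Position lifting walks blocks with
source gaps (dt) and target gaps (dq); minus-strand coordinates follow the
chain convention (positions counted on the reverse complement).  Among
overlapping chains the highest-scoring chain covering the position
decides; a position in its gap is "unmapped" (no fallback to lower-scoring
chains).  min_match applies to intervals only — single positions either
map or not, matching observed behavior of coordinate-lifting tools on 1 bp
inputs.  Conservation filtering is strictly greater-than 0.5; catalog
overlap is exact-position and strand-agnostic (the target catalog
aggregates tissues); enrichment is fold over the mean of 1000 random
position draws with empirical p = (1 + #{null ≥ obs})/(n_perm + 1).

## The synthetic study

`simgen` emulates the observation layer the pipeline consumes.  Defaults
are the package's study conditions: 3 tissues × 60 samples; 2,000 true
sites (75 % canonical A-to-G on the annotated strand, 75 % inside
PRE-like repeats), 500 artifact sites confined to near-exact duplicated
segments, 500 leak sites at common (MAF ≥ 0.25) panel SNPs; per-tissue
mean levels Beta(2, 4) clipped to [0.08, 0.95] with logit-normal tissue
(SD 0.4) and sample (SD 0.2) jitter; coverage negative binomial (mean 60,
size 5); base error rate 1e-3; 3,000 SNPs in 5-SNP LD blocks (anchor
frequency U(0.05, 0.5), per-SNP flip 0.01); 300 cis effects with logit
slopes ±N(0.8, 0.2²) within 1 Mb; GWAS of 2,000 individuals with 20
causal SNPs, half of them planted edQTLs.  The Beta level distribution is
clipped below at 0.08 so that "true sites" denote sites detectable in
principle under the presence thresholds — real catalogs additionally
contain sites edited too rarely to recur, which the cascade would
(correctly, by its own rules) not report.  Per-allele counts for het
individuals split coverage binomially and edit at invlogit(b) and
invlogit(b + 2s) on the two haplotypes; bulk samples follow
invlogit(b + s·dosage), so het bulk levels differ from the mean of the
allele levels by the curvature of the logistic — negligible at these
slopes and irrelevant to both tests.

What passing the synthetic suite shows: the filters separate the three
planted error classes at the stated rates; the statistical machinery is
calibrated (uniform null p, FDR ≤ 0.07 at q < 0.05, ASED type-I ≤ 0.07)
and recovers planted parameters (slope bias < 10 %, h² within ±0.1).
What it does not show: robustness to alignment pathologies not in the
noise model (splice-junction artifacts, strand-bias, index hopping),
realistic LD (blocks are copies, not coalescent samples), or performance
at biobank scale.

## Degenerate inputs and tie-breaks

Zero-coverage pileup rows are skipped and counted.  Constant phenotypes
raise (untestable site).  Monomorphic SNPs yield NaN LD and are excluded
from scans.  Beta-fit failures fall back to rank p-values; REML
non-convergence returns the EM estimate flagged.  All-boundary ASED groups
return p = 1 flagged degenerate.  Alt-allele ties break alphabetically;
clump ties break by position then allele.  Every stochastic routine takes
an explicit seed and is reproducible bit-for-bit under it.
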