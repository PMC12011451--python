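# Methods

`gtpanel` implements the analysis side of a GTseq (genotyping-in-thousands
by sequencing) amplicon panel workflow for noninvasive wildlife genetics:
selecting markers from a dense SNP catalog, calling microhaplotype
genotypes from amplicon reads under contamination-aware filters, inferring
sex from Y-marker read ratios, estimating error rates from replicates,
quantifying identity/kinship power from allele frequencies, and screening
low-quality extracts by qPCR. This note records the models, the defaults
and why they are what they are, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Panel design

**Filter cascade.** Candidate SNPs pass, in order: minor allele frequency
(MAF) ≥ 0.01, missingness ≤ 10%, a Hardy–Weinberg equilibrium test at
α = 0.05, and window-based LD pruning (windows of 50 loci advanced by 5,
dropping one member of any pair with r² > 0.5). All statistics are derived
from the genotype dosage matrix, so the cascade is idempotent. The HWE
test is a 1-df chi-square on observed vs expected genotype counts, with a
Yates continuity correction below 100 called genotypes — small cohorts
otherwise over-reject. In an LD-violating pair the locus later in
(chrom, pos) order is dropped; any deterministic rule works here, and
keeping the earlier locus preserves left-to-right reproducibility.

**Nei F_ST.** Per locus, F_ST = (H_T − H_S)/H_T with H_S the unweighted
mean within-population expected heterozygosity and H_T the expected
heterozygosity at the mean allele frequencies. Inputs may be single
biallelic frequencies or full allele-frequency vectors (microhaplotypes).
Fixed loci (H_T = 0) return 0. Diagnostic loci are ranked by decreasing
F_ST within each population comparison and the top 30 per comparison are
unioned (ties break lexicographically by locus id).

**Microhaplotype windows.** A qualifying cluster spans ≤ 100 bp
(inclusive of both end positions), holds ≥ 2 SNPs, contains at least one
anchor SNP with MAF in [0.2, 0.45], and the sample (n−1) standard
deviation of member MAFs exceeds 0.01. The SD rule exists to reject SNPs
in perfect phase — identical frequencies give SD 0 — and the sample SD is
the natural reading of "standard deviation between the allele
frequencies" for 2–5 member clusters. Clusters are grown maximally from
the leftmost unused SNP per chromosome, so each SNP belongs to at most
one candidate and the output is order-independent. SD is computed over
minor-allele frequencies; window span is measured between outermost
member SNPs rather than as a fixed tiling (both were open choices; the
outermost-SNP span is what a single primer pair actually has to cover).

**Diversity markers.** Greedy left-to-right scan per chromosome accepting
SNPs with MAF in [0.30, 0.45] at ≥ 250 kb from the last accepted SNP.

**Depth-peak filter.** Loci mapping to two genomic copies collect roughly
twice the read depth of single-copy loci, so the per-locus mean-depth
distribution becomes bimodal. A Gaussian KDE (Silverman bandwidth) is
fitted; the retention cutoff is the density minimum between the first
mode m₁ and 2·m₁. A unimodal fit retains everything with a warning — the
filter only ever removes the doubled peak, it never invents one.

## Microhaplotype genotype calling

Reads reach the caller either from FASTQ via probe matching — each read
is searched for every locus probe allowing ≤ 1 mismatch; exactly one hit
assigns the read, two or more count it ambiguous — or pre-aligned from a
SAM file whose reference names are locus ids. Probe uniqueness at the
mismatch tolerance is validated at panel load. A read contributes a
haplotype observation only if it covers *all* of the locus's SNP offsets
with base quality ≥ 20 at each (complete-haplotype rule; partial
haplotypes are never imputed). The Q20 base threshold is configurable and
deliberately below the Q30 used for variant *discovery*: discovery decides
which offsets exist panel-wide, calling merely reads bases at known
offsets.

A genotype call applies three filters in order, on the callable depth
(haplotypes containing N never count):

1. depth ≥ 20× — below it the call is `LOW_DEPTH`/missing;
2. depth must *exceed* 2× the per-locus read depth of the plate's
   negative PCR control (`NEG_CONTROL` otherwise) — a dynamic
   contamination floor; with several negatives on a plate the maximum
   depth is used, conservatively;
3. the second-most-frequent haplotype calls a heterozygote when its count
   is ≥ 0.1 of callable depth (the allelic ratio, second/total by default;
   minor/major available behind `ratio_basis`); otherwise the call is
   homozygous for the top haplotype. A *third* haplotype also clearing
   the ratio makes the call `AMBIGUOUS`/missing — at that point the tally
   looks like contamination or a paralog, and guessing two of three is
   worse than abstaining.

Ranking ties break by (count desc, haplotype string asc), so calls are
invariant to read order.

**Variant discovery on amplicons.** Offsets qualify as panel SNPs when
biallelic, minor-allele frequency ≥ 0.006 across pooled samples, outside
primer-masked ranges, and with a phred-scaled site quality ≥ 30. Site
quality here is the binomial surprise of the minor-allele count under the
per-base sequencing-error null (−10·log₁₀ of the upper tail at error rate
0.001) — a simple, explicit score playing the role a variant caller's
QUAL plays in a mapped-read workflow.

**Replicate error rate.** Within each replicate group, every pair of
members with PASS calls at a locus contributes one comparison; a mismatch
is an unequal unordered allele pair. The rate is total mismatches over
total comparisons; per-sample-type rates use only pairs sharing that
type. All pairwise comparisons are counted for groups larger than two
(the alternative — counting replicate-locus instances — is
indistinguishable at group size 2, which dominates real replicate sets).

**Locus QC.** Loci are dropped when the replicate error rate is strictly
above 5% (a locus at exactly 5% stays) or when under 10% of their
assigned reads match the expected amplicon structure.

## Sex inference

Each Y-linked marker is expected to draw a fixed fraction of a male's
on-target reads: 0.005 for ddx3Y and 0.003 for usp9Y. The statistic is
ratio = observed / (total on-target × expected fraction), which sits near
1 in males and near 0 in females; > 0.2 calls M, < 0.1 calls F, the band
between abstains. The ratio is deliberately observed/expected — the
opposite orientation is incompatible with thresholds that put males above
0.2 and females below 0.1. The 10× depth gate abstains only when *both*
the observed count and the expected count are below 10: a female
legitimately has ~0 observed Y reads, and a large expected count is
exactly the evidence that 0 observed means F rather than "no data". A
sample's consensus sex requires both markers called and agreeing;
disagreement reports `CONFLICT`, an uncallable marker `NOT_GENOTYPED`.
Concordance against field-assigned sex reports accuracy among assigned
samples (the headline metric — abstentions are not errors) and overall.

## Identity and kinship power

**PID.** Per locus, with allele frequencies pᵢ,

    PID_sibs = 0.25 + 0.5·Σpᵢ² + 0.5·(Σpᵢ²)² − 0.25·Σpᵢ⁴
    PID_unrelated = Σpᵢ⁴ + Σ_{i<j} (2pᵢpⱼ)²

multiplied across loci in log space. Microhaplotypes are ordinary
multiallelic loci (each haplotype string is one allele); loci are assumed
unlinked and in HWE. Both formulas are verified in the test suite against
a from-first-principles Mendelian enumeration oracle (explicit parents,
transmission, summation) to 1e-12 for up to 4 alleles. The subsampling
curve draws loci without replacement within each of 1000 iterations and
averages PID_sibs per subset size.

**Kinship likelihood ratios.** Genotype-pair probabilities condition on
IBD sharing through the kappa coefficients — (1,0,0) unrelated, (0,1,0)
parent–offspring, (0.25,0.5,0.25) full siblings — with standard
HWE-conditional sharing terms. Genotyping error uses the random-replacement
model: with probability ε an individual's observed genotype is a fresh HWE
draw. Because every kappa model's marginals are HWE, the observed pair
distribution collapses to
(1−ε)²·P_model + (1−(1−ε)²)·P_HWE⊗P_HWE, which normalizes exactly and
reduces cleanly at ε = 0. Default ε values: 0.0039 (this panel's measured
replicate rate), 0.01 (microsatellites), 0.05 (RADseq).

The test statistic is Λ = Σ_loci log[P(pair|related)/P(pair|unrelated)].
The decision threshold is the FNR-quantile of Λ under the related
hypothesis (estimated from simulated related pairs, linear-interpolated
empirical quantile); the FPR is the probability an unrelated pair reaches
it. FPR is the semantics of the published power curves: unrelated pairs
crossing the related-favoring threshold. Because useful panels push FPR
many orders of magnitude below anything countable by direct simulation,
the FPR is estimated by importance sampling: pairs are simulated under the
*related* hypothesis and weighted by P(pair|U)/P(pair|related) = exp(−Λ),
so FPR = E_related[exp(−Λ)·1(Λ ≥ λ*)] with a reported Monte-Carlo standard
error. The threshold batch and estimation batch are independent draws. A
direct-MC estimator is provided as a cross-check and agrees within
sampling error wherever FPR ≥ 1e-3. Subset analyses retain
round-half-up(fraction · L) random loci (so 25% of 194 is 49) and re-run
the estimator at a single FNR.

## qPCR screening

The standard curve is least-squares Cq = a + b·log₁₀(concentration) over
a dilution series (≥ 3 distinct positive standards; the shipped generator
uses five 10-fold standards from 20 to 0.002 ng/µL). Efficiency is
10^(−1/b) − 1; a non-negative slope flags `INVALID_CURVE`. Unknowns
quantify as 10^((Cq − a)/b); an undetermined Cq maps to 0 ng/µL.

Genotyping success is binary — fraction of panel loci genotyped ≥ a
threshold (0.50, 0.25 or 0.10) — and modeled by maximum-likelihood
logistic regression on concentration. Zero-concentration samples are
excluded by default (screening only ever applies to qPCR-positive
extracts); a flag includes them. The fit is on linear concentration by
default with log₁₀ behind a flag — the choice was open, and on synthetic
data both reproduce the characteristic sub-1 ng/µL curvature. Complete
separation (or a degenerate single-class outcome) falls back to a
Firth-type Jeffreys-penalized Newton fit and is flagged. The model
inverts as concentration = (logit(p) − β₀)/β₁ (back-transformed on the
log scale); β₁ ≤ 0 raises `NONINFORMATIVE`. A `success_prob` column
switches to a grouped-proportion GLM fit, which recovers generating
coefficients exactly on noiseless proportions.

## Synthetic data generator

The generator emulates, with full ground truth: multi-population allele
frequencies at a target F_ST, cohorts with parent–offspring and
full-sibling pairs, per-locus amplicon reads, contaminated negative
controls, replicates with a set discordance rate, sex-marker tallies, and
concentration→success screening data. Everything derives from one seed;
two runs are byte-identical.

* **Frequencies** follow the Balding–Nichols model: ancestral frequencies
  are symmetric-Dirichlet, population frequencies Dirichlet(ancestral ·
  (1−θ′)/θ′). θ′ is the target θ corrected for the finite number of
  populations r: Nei's G_ST over r sampled populations has expectation
  θ′(1−1/r)/(1−θ′/r), so θ′ = θ·r/(r−1+θ) makes the *measured* mean
  per-locus F_ST land on θ. Defaults: 3 populations, θ = 0.1, 3 alleles
  per locus.
* **Cohorts**: founders drawn from HWE; children by Mendelian
  transmission. Replicates copy a sample's truth and, with the configured
  discordance probability (default 0.0039, the panel's measured rate),
  replace a genotype by an HWE draw conditioned to differ — so the
  realized pairwise mismatch rate equals the configured rate exactly,
  which is what makes the rate recoverable by the error-rate estimator.
* **Reads**: per sample × locus depth is negative-binomial (gamma–Poisson,
  dispersion 5) rather than Poisson, emulating the overdispersion of scat
  libraries; reads copy the amplicon with the sample's haplotype at the
  SNP offsets and per-base substitution error 0.005; off-target junk pads
  each sample to an 85% on-target fraction. Negatives receive
  Binomial(depth, 0.001) stray reads copied from random samples' alleles —
  modeling well-to-well leakage and tag-jumping without distinguishing
  them. Males draw Binomial(on-target, 0.005/0.003) sex-marker reads,
  females Binomial(on-target, 0.0002).
* **Screening data**: success ~ Bernoulli(expit(β₀ + β₁·conc)) with
  defaults (−2, 6), and the reported loci fraction is placed on the
  correct side of the success threshold, so the binary outcome follows the
  generating logistic law exactly.

What it does **not** emulate: quality-score ladders and indel errors,
primer-dimer structure, index hopping, dietary/metagenomic read content,
linked loci, or population structure within a cohort. Passing round-trip
tests therefore demonstrates the pipeline's bookkeeping and filters, not
robustness to every artifact of real noninvasive libraries.

Fixed fixtures (`make_paper_fixtures`) reproduce the published validation
tallies exactly — replicate tables with 69 mismatches over 17,578
comparisons (20/10,268 blood, 3/4,125 tissue, 46/3,185 scat) and a
205-sample sexing table (175 correct, 5 assigned-but-wrong, 5 conflicts,
20 not genotyped) — built as deterministic two-member replicate pairs and
arithmetic read tallies, not simulations.

## Problem sizes and numerics

Test and acceptance runs use deliberately desk-scale problems: 500 loci
for F_ST recovery, 20–50 loci for read round trips, 40,000 simulations
per kinship batch, 6-locus panels where direct-MC cross-checks need
FPR ≥ 1e-3. PID products are computed in log space; likelihood tables
guard log(0) by construction (impossible pairs carry −inf and are never
sampled); empirical quantiles interpolate linearly; all generators are
`numpy.random.default_rng` seeded explicitly.

## Known limitations

* Probe-based read assignment replaces full alignment; indels in the
  probe region lose reads, and an exact-probe hit is not re-checked for
  fuzzy matches to other probes (probe mutual-distance validation makes
  such collisions negligible).
* The HWE chi-square is asymptotic; an exact test would be preferable for
  very small cohorts.
* Kinship power assumes unlinked loci in HWE; linked microhaplotypes
  would need haplotype-block likelihoods, which are out of scope.
* The depth-peak filter's KDE valley is sensitive to bandwidth when the
  two depth modes nearly merge; it warns rather than guesses when no
  second mode is found.
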