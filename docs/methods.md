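# Methods

## The mixture model

A bulk tumor sample contains a fraction ρ of tumor cells carrying n_t total
copies of a locus and a fraction 1 − ρ of normal cells carrying n_n copies
(n_n = 2 unless stated).  Sequencing reads at the locus therefore arrive from
the tumor compartment in proportion n_t·ρ and from the normal compartment in
proportion n_n·(1 − ρ).  For any per-read rate statistic — the methylation
rate m or the proportion of discordant reads (PDR) — the bulk value is the
copy-weighted mixture

    m_b = (m_t n_t ρ + m_n n_n (1 − ρ)) / (n_t ρ + n_n (1 − ρ)),

and the cancer-cell-specific value is recovered by the exact inversion

    m_t = (m_b (n_t ρ + n_n (1 − ρ)) − m_n n_n (1 − ρ)) / (n_t ρ).

The inversion is undefined at homozygous deletions (n_t ρ = 0) and raises
there; raw estimates outside [0, 1] (measurement noise amplified by the
1/(n_t ρ) factor) are clipped and flagged rather than dropped, so downstream
denominators keep the site.  Purity appears in some derivations as both ρ
and p; it is one parameter here.  Per-CpG n_t is looked up from the covering
copy-number segment; CpGs in segment gaps are excluded and flagged.
Allele-specific methylation cannot be resolved from total copy number and is
a known limitation: loci with allele-specific methylation (a few percent of
CpGs in real tissue) contribute to concordant/discordant event counts
according to their apparent direction.

## Differential methylation

**Per-sample DMP calls** use the thresholds effect > 0.2 and p < 0.01.  The
effect is the deconvolved difference m_t_hat − m_n.  For the p-value we use
the identity

    m_t − m_n = w / (n_t ρ) · (m_b − m_n),   w = n_t ρ + n_n (1 − ρ):

the deconvolved difference is zero exactly when bulk and normal proportions
agree, so the test is a pooled two-proportion z-test on the observed read
counts, with a conditional exact (tail-doubled hypergeometric) fallback when
any cell of the 2×2 table is below 5.  This keeps the test exactly
calibrated; an earlier design that rescaled counts by the tumor-read
fraction and treated the deconvolved rate as a binomial proportion was
anti-conservative in null simulations (7.9% false-call rate at
intermediate methylation) and was abandoned.

**Cohort-level DMP calls** aggregate multi-region evidence.  Per patient,
region counts are pooled per CpG and compared with the matched normal
through a signed mid-p conditional (hypergeometric) z-score — mid-p because
many discrete scores are combined and plain tail p-values are biased.
Patient scores are Stouffer-combined (patients are independent; regions of
one patient share a normal and are pooled, not double-counted).  A CpG is
called hyper when the combined two-sided p < 0.01 and at least two patients
show a sign-consistent patient-level deconvolved difference above 0.2 (hypo
mirrored).  The two-patient effect rule suppresses spurious single-patient
effect-size excursions at low purity, where the 1/(n_t ρ) noise
amplification makes individual patient deltas heavy-tailed.  Per-sample
calling at ~30 reads/CpG is intrinsically underpowered for single-sample
effect sizes of 0.3 at α = 0.01 (a two-sample test on 30v30 reads cannot
reach 90% power, and at purity 0.3 the normal-side standard-error floor
alone exceeds the requirement at any bulk depth); cohort-level truth is
therefore recovered by the cohort-level caller, while per-sample calls feed
region-resolved statistics (ubiquity, promoter status, timing).

**DMRs**: CpGs within 100 bp chain into bins; a bin with a run of ≥4
consecutive DMPs (consecutive = adjacent covered CpGs in the series; absent
CpGs do not break runs because they are not in the series) and ≥5 DMPs in
total is a DMR.  Promoter windows span 2,500 bp upstream to 250 bp
downstream of the TSS in transcription orientation (2,751 bp inclusive).
Gene-level methylation status comes from qualifying DMRs overlapping the
promoter window; genes without covered promoter CpGs are missing, not
"none".

**DHcR / driver ranking**: the differentially hypermethylated cytosine
ratio is hyper CpGs over profiled promoter CpGs per gene and sample, with
the hypermethylation call from a chi-squared (two-proportion) test at 15%
FDR per sample (per-sample, because the calling cohort for this statistic
is a single tumor-normal pair); normal-sample baselines are computed against
the median normal.  Expected DHcR is fitted per sample by a beta regression
across genes on stochastic-hypermethylation covariates (promoter PDR,
normal methylation, log normal expression, promoter CpG count; a
replication-timing covariate would slot in the same way but needs external
tracks and is omitted by default).  Observed ratios are smoothed off the
{0,1} boundary by (y(n−1)+0.5)/n before fitting.  The per-gene one-sided p
is the upper tail of the fitted Beta(μφ, (1−μ)φ) at the observed value;
one-sided p-values are combined across samples by Stouffer with equal
weights (the combination scheme is not dictated by the ranking procedure we
follow; Stouffer keeps per-sample evidence symmetric) and BH-adjusted.
One tumor sample per patient enters, the highest-purity one, with a
lexicographic sample-id tie-break.  Non-converging fits are flagged and
skipped in the combination, never silently dropped.

## Heterogeneity metrics

ITMD is the pairwise correlation distance d = 1 − Pearson r (range [0, 2])
between per-CpG methylation-rate vectors of two regions, on the CpGs covered
in both ("Pearson distance" fixes only the correlation; the 1 − r transform
is our choice).  Intra-patient ITMD averages all region pairs within a
patient; inter-patient ITMD averages cross-patient region pairs (all pairs
by default; a one-region-per-patient mode would subsample — all-pairs is the
default because it uses every measurement).  The shared-CpG intersection is
computed per pair, not cohort-wide, to maximize usable sites; the feature
count is reported so callers can enforce a floor (CLI default 5,000).
Zero-variance vectors make the correlation undefined; such pairs are skipped
with a warning.  ITED applies the same distance to expression after
log2(x+1) and per-gene z-scoring, reported per region as the mean distance
to sibling regions.

## M_R/M_N

Promoter CpGs hypermethylated somewhere in the cohort are classified
regulatory (two-sample t-test of cognate-gene expression, hypermethylated vs
not, p < 0.05 with the hypermethylated group lower) or nonregulatory.  The
t-test uses all tumor regions by default (a per-patient collapse is the
natural alternative; all-regions maximizes power and the validation-transfer
report guards against pseudo-replication artifacts).  Per gene,

    M_R = (ΣH_i·R_i + 1) / (ΣR_i + 1),   M_N = (ΣH_i(1−R_i) + 1) / (n − ΣR_i + 1),

with i indexing covered (CpG, sample) event opportunities, H binary
hypermethylation and R the CpG's regulatory flag; a per-CpG mode (H = hyper
in ≥1 sample) sits behind a flag.  Hypomethylated DMPs do not enter the
denominators.  Genes lacking either CpG class are non-calculable.
Deviation from ratio 1 is tested by an exact conditional test on the 2×2
event table (valid at small counts; the selection framework states an FDR
level but not a test) with BH across genes; classes gt1/lt1 at q < 0.05.
Ratios are reported raw and log2.  Regulatory assignments freeze in a
discovery cohort and transfer to validation data; the transfer report is a
confusion matrix of expression direction at p < 1e-4.

## Copy-number interplay

Events per gene and region: loss n_t < round(ploidy); gain n_t >
round(ploidy); amplification n_t ≥ ploidy + 2 (no numeric definition is
standard for multi-region data; ploidy + 2 matches the generator and common
practice, and both thresholds are configurable).  CN at a gene is taken at
its TSS; promoter windows spanning a segment boundary are flagged.
Double hit = hypermethylation and CN loss in the same region of a tumor;
parallel = both mechanisms in the tumor but never in one region; concordant
regions carry hyper+loss or hypo+gain/amplification.  Timing patterns
combine event clonality (ubiquitous = present in all assessable regions,
needs ≥2): clonal-hyper/subclonal-loss vs clonal-loss/subclonal-hyper
counts feed a 2×2 chi-squared without continuity correction (exact test
with a notice when an expected cell is below 5).  The printed statistic and
table are exposed; no particular published p-value is claimed, since the
table construction behind such summaries is not always recoverable.

**Dosage compensation**: per gene with ≥3 amplified and ≥3 non-amplified
regions, the difference of median promoter methylation between strata
(flagged above 0.2) and an expression class from a t-test on log2
expression: scaling (higher when amplified), buffered (no difference),
antiscaling (lower).

**AllChAT**: candidate pairs are each annotated oncogene with every gene
within 20 Mb on its chromosome (assumed to share CN events; the oncogene
list is user-supplied).  CNAs under 50 Mb are filtered out first when
calling gain/loss from segment input.  In the gained/amplified stratum,
paired one-sided t-tests must show the oncogene with lower tumor-normal
methylation differential, higher H3K4me3 and lower H3K27me3 TSS-window
log-ratio than the passenger (signals summed over 2 kb upstream of the TSS,
tumor/normal ratio with pseudocount 1 before the log).  In the non-gained
stratum the contrast must be compatible with equal-or-reversed; the default
mode requires the gained-stratum direction to be non-significant there
(operationalizing "equal to or more than": with true equality a
reverse-direction significance requirement would reject valid pairs at
1 − (1 − α)^3 per stratum), and a strict mode demanding a significant
reverse-direction test is available.  A pair passes only if every stratum
test passes; with histone tracks missing the verdict is methylation-only
and marked partial.  Essential-gene enrichment among compensated genes is a
generic Fisher 2×2 against any user gene list.

## Dichotomization

Per gene, expression statistics (mean, Q1, median, Q3) in the
hypermethylated and non-hypermethylated strata are estimated by a 100-fold
bootstrap that samples one region per tumor per replicate and averages each
statistic across replicates (arithmetic mean).  A sample is "low" when its
expression is strictly below the aggregated Q3 of the hypermethylated
stratum — the stratum choice is genuinely open in the procedure we follow;
Q3-of-hypermethylated is the semantically coherent reading (below the bulk
of hypermethylated tumors) and a flag switches strata.  Values exactly at
the threshold are "high" (strict inequality, documented).  A tumor with any
low region is classified as having hypermethylation-dependent reduced
expression.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, with
defaults frozen as the reference study conditions: 20 patients × 3 tumor
regions + 1 matched normal, 50,000 CpGs, Poisson coverage mean 30, purity
uniform on (0.3, 0.9), ploidy 2.  The normal methylome is a two-component
Beta mixture (modes near 0.05 and 0.95; promoter CpGs mostly unmethylated,
gene-body CpGs mostly methylated) because downstream effect thresholds
assume near-saturated baselines.  5% of CpGs are planted DMPs at effect
size 0.3 (half hyper, preferentially at low-baseline promoter CpGs; half
hypo at high baselines); planted events are clonal (all regions) with
probability 0.5 — the middle of the wide ubiquitous-event range seen in
multi-region tumors — otherwise subclonal in a strict random subset of
regions.  By default every patient carries every planted DMP (DMP status is
a cohort-level CpG property); setting the patient-prevalence below 1
produces patient-specific methylation signatures, the condition used for
the heterogeneity direction study.  Half of planted promoter hyper-DMPs are
regulatory: carrying one multiplies cognate expression by 0.5; expression
noise is lognormal with σ = 0.3 (keeps t-tests on the log scale well
behaved).  Copy-number segments are piecewise constant per chromosome with
1–3 breakpoints (n_t ∈ {1..4}, mostly 2); amplicons place an oncogene plus
≤3 neighbors within 2 Mb at n_t = ploidy + 2 in half the patients, with the
oncogene promoter demethylated (−0.2) and expression scaling with copies,
and passenger promoters gaining +0.3 methylation at baseline expression
(dosage compensation); matching H3K4me3/H3K27me3 TSS signals are emitted.
Read-level epialleles draw each read's compartment with probability
n_t ρ / (n_t ρ + n_n(1 − ρ)) and its discordance from the compartment PDR,
so bulk PDR follows the forward mixture by construction.  One global seed
drives per-stage substreams (default_rng([seed, stage])), so identical
configs give identical outputs and stages can be regenerated independently.

Focused generators cover designs the full cohort does not isolate: per-gene
regulatory/nonregulatory event tables with selective hypermethylation (80%
vs 10% event rates in planted genes, ~30% in nulls, CpG counts varying per
gene), candidate AllChAT pairs (planted gained-stratum contrasts ±0.25
methylation and ±1.2 histone log-ratio with a small favorable margin, 0.05,
in the non-gained stratum — outside the gained state the transition is
absent, not reversed), and paired expression/methylation cohorts for
threshold transfer in which per-gene baselines are fixed gene properties
shared across cohorts.

What the generator does not model: sequencing error, bisulfite conversion
failure, fragment-level (MspI) coverage structure, allele-specific
methylation, covariate-correlated DMP placement, or biological coupling
between copy number and the methylation baseline.  Passing tests therefore
demonstrate correctness of the estimators and calling rules under the
mixture model and calibrated noise, not robustness to those real-data
artifacts.

## Problem sizes and numerics

The test suite and the acceptance script use the reference cohort
(50,000 CpGs × 60 tumor samples) for deconvolution and DMP recovery, a
20,000-CpG null cohort for type-I control, 10 small cohorts (4 × 3 regions,
3,000 CpGs at 60× with patient prevalence 0.5) for the heterogeneity
direction, 220/1,000-gene event tables for M_R/M_N (1,000 genes for the
null correlation bound, where the standard error of a correlation, ~0.03,
can resolve a 0.1 bound), 100 candidate AllChAT pairs with 10 samples per
stratum, and 20-patient cohorts for threshold transfer.  Exact-test
fallbacks use tail doubling (vectorizable; never anti-conservative against
the two-sided exact p, asserted in tests).  BH adjustment propagates NaNs.
Degenerate inputs — zero-coverage sites, zero-variance vectors, empty
strata, genes without covered CpGs — are reported as missing with a reason,
never as zeros.
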