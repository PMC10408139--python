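# Methods

This note records the models, conventions and design choices behind
`oxsig`, in the order the pipeline runs them.

## Synthetic study design

The generators in `oxsig.simulate` produce inputs with the statistical
structure the analysis assumes, so every downstream stage can be
validated against planted ground truth without any external data.

**Mouse counts.** A 2×2×2 factorial design — sex (F/M) × genotype
(WT/KO) × treatment (room air / 95% FiO₂ hyperoxia) — with
`n_per_group` replicates per cell (≥ 2; the default pipeline uses 6).
Counts are negative binomial in mean–dispersion form, Var = μ + φμ²,
with a single dispersion φ (default 0.05, a typical biological-replicate
value for bulk RNA-seq) and per-gene baseline log2 means drawn uniformly
on [2, 12] so that library-size normalization is exercised over three
orders of magnitude of abundance. Planted effects are per-contrast
(sex × genotype) up/down gene sets with |log2FC| > 0 applied only in
the hyperoxia samples of the targeted cell. The default pipeline plants
the largest response in the KO female contrast (150 up / 100 down at
log2FC 2), a much smaller response elsewhere, and 36 shared up / 8
shared down genes between the two female contrasts so the overlap table
is nontrivial. The real studies' batch structure (WT and KO cohorts
sequenced separately) is deliberately **not** simulated; batch
correction is outside this package's scope, so its synthetic data is
batch-free and passing tests say nothing about batch robustness.

**Reference cohort.** A healthy human lung stand-in: log-scale
expression with heterogeneous per-gene means U(2, 12) and SDs
U(0.3, 1.5), plus a rank-5 shared-covariance component (loadings
N(0, 0.4²)) so that distinct gene sets exhibit correlated summed
z-scores — the property the reference cohort exists to expose. Default
n = 578 samples.

**Clinical cohort.** n = 111 with ordinal BPD severity composition
43 no / 40 mild / 13 moderate / 15 severe. Expression is Gaussian on
the log scale; signature up-genes are shifted by +δ·severity per-gene
SDs and down-genes by −δ·severity (default δ = 0.5). Sexes alternate
within severity strata. Gestational age is 29 − 1.5·severity weeks and
birth weight 1250 − 150·severity g, with Gaussian noise SDs (2.66
weeks, 266 g) solved from r = −slope·sd(sev)/√(slope²·sd(sev)² + sd²ₙ)
= −0.5 under the default composition (sd(sev) ≈ 1.02) — i.e. both
covariates correlate about −0.5 with severity. Oxygen at 28 days is
Bernoulli with probability (0.10, 0.85, 0.95, 1.0) by severity level,
reflecting that oxygen requirement at 28 days is close to the mild-BPD
definition. The cohort is "an expression cohort with an ordinal
outcome": blood-vs-lung tissue differences, microarray artifacts and
normalization history are not modeled, and the generator emits
already-normalized log-scale values.

**Ortholog map.** Each mouse symbol is independently 1:1 (upper-cased
human symbol), 1:many (two human targets), or missing, with
configurable fractions (pipeline default 0.90/0.05/0.05). Any leftover
probability mass defaults to 1:1.

All generators are bit-deterministic given their seed.

## Differential expression and signatures

Counts are normalized to log2 CPM with fixed pseudocounts,
log2((c + 0.5)/(libsize + 1) × 10⁶), so outputs are bit-reproducible
and log(0) never occurs. Each contrast is tested gene-by-gene with a
two-sided two-sample t-test on the log2 scale. The **pooled-variance
(Student) t is the default**: the two treatment arms share a single
noise model, and at the small group sizes typical of these designs
(n = 5–10) the Welch–Satterthwaite approximation is measurably
conservative — empirical size ≈ 0.044 at nominal 0.05 with n = 5 per
arm even on exactly normal data — whereas the pooled test is calibrated
(≈ 0.050). Welch's test remains available (`equal_var=False`) for
unequal-variance settings. Genes constant within both groups are
degenerate: p = 1 if the means agree, p = 0 (exact separation, flagged)
otherwise. Constancy is detected by zero range, not zero estimated
variance, because the mean of a constant row need not be representable
in binary floating point.

Benjamini–Hochberg adjustment is the step-up rule applied per contrast
(matching "FDR < 0.05" per analysis, not pooled across contrasts).
Signatures take q ≤ 0.05 and |log2FC| ≥ log2(1.5), both boundaries
inclusive. The DEG-table producer is pluggable: externally computed
tables (e.g. from a negative-binomial GLM) can be imported and fed to
the identical downstream machinery.

*Known limitation (composition bias).* Plain CPM shares one scale
factor per sample; a strongly asymmetric planted response (many
up-regulated genes) inflates the hyperoxia library sizes and shifts
null genes' log-ratios slightly negative, which at permissive sample
sizes admits extra genes into the down-signature. This is the
real-data phenomenon that motivates upper-quartile/TMM normalization;
robust between-sample normalization is intentionally out of scope here,
and the recovery tests quantify the effect (planted-set Jaccard remains
high).

## Ortholog translation

The default orientation translates the *human* expression matrix into
*mouse* symbol space and scores it with untouched mouse signatures; the
opposite orientation (translating the signatures) is provided and, for
a 1:1 map, yields identical scores. Unmapped rows are dropped and
counted; several sources collapsing onto one target are averaged
(arithmetic mean on the log scale — order-independent and
variance-stable); a source with several targets has its row duplicated.
A signature gene landing in both translated up and down sets (possible
after 1:many expansion) is removed from both and reported as a
conflict. Matching is case-sensitive: mouse (`Sox2`) and human (`SOX2`)
conventions differ exactly by case, and silent case-folding would mask
direction errors. Every translation returns a report (translated /
dropped / collapsed / expanded / conflicts) whose counts reconcile with
the input.

## Summed z-score scoring

z-scoring uses the sample SD (n − 1); the choice is arbitrary but must
be fixed for bit-reproducibility, and is documented so external
reimplementations can match. Zero-variance genes have undefined z and
contribute exactly 0 — the unique value preserving the score's up/down
antisymmetry. Scores are plain sums, not divided by |signature| or
√|signature|: all downstream Pearson correlations are invariant to that
scaling, so size normalization would change no reported r. Signature
genes absent from the matrix (non-conserved orthologs) are skipped and
reported as coverage; a signature with zero coverage is dropped from a
batch with a warning rather than failing it.

Exact identities maintained (and tested): antisymmetry
(score(U, D) = −score(D, U), bit-exact), additivity over disjoint
signatures (to machine precision; bitwise equality of independently
accumulated float sums is not defined), and invariance to per-gene
positive affine transforms of the expression matrix.

## Correlation, clustering and the clinical report

Pearson r with the exact t reference distribution
(t = r√((n−2)/(1−r²)) on n − 2 df), as in the standard scientific
library. Constant inputs give a distinguished not-computable result —
never r = 0. Exact linear dependence is snapped to r = ±1, p = 0.
Inter-signature correlation computes each pair once and mirrors it, so
symmetry is exact. Hierarchical clustering is agglomerative with
distance 1 − r and average linkage; labels are pre-sorted
lexicographically so equal-distance merges resolve deterministically.

The clinical report correlates each signature's scores with each
requested variable — defaults: gestational age, birth weight, BPD
severity, oxygen at 28 days — overall and within strata (by sex, and
optionally a second grouping crossed with sex). "BPD status" is encoded
as the ordinal severity 0–3, consistent with a four-level severity
axis; a binary encoding can be supplied as a derived column. Strata
with n < 3 are reported as not-computable rather than silently omitted
(sex-splitting small severity groups empties cells). Raw r and p are
reported; BH across report cells is available but off by default.

## Preranked enrichment

Genes are ranked by sign(log2FC) × (−log10 p) by default (effect
direction weighted by evidence; raw log2FC is an option), with p floored
at 1e−300 and ties broken lexicographically and recorded. The
enrichment score is the weighted KS running sum: hits add
|score|^w / Σ_hits |score|^w (w = 1 by default, the cited tool's
weighted scheme; w = 0 reduces to the classical KS statistic on ranks),
misses subtract 1/(N − N_hits); ES is the running-sum value of maximal
absolute value. If every hit score is exactly zero the increments fall
back to equal weights.

Significance uses gene-set permutation — random same-size gene draws —
because the input is a preranked list and phenotype permutation is
unavailable. Per set: NES = ES / mean(|null ES|) over same-sign null
draws; the permutation p is the pseudo-counted two-sided tail over all
draws, p = (1 + #{|ES_null| ≥ |ES|})/(1 + n_perm), which is exactly
uniform under the null regardless of null-ES asymmetry and resolves to
1/(n_perm + 1) for a maximally enriched set. FDR q follows the signed
pooled-NES procedure: each null ES is normalized by its set's same-sign
null mean, pooled across sets, and q = (null tail fraction)/(observed
tail fraction) at the observed NES, clipped to [0, 1], without
monotonicity enforcement. Defaults: n_perm = 1000 (seed always
explicit), set size bounds [5, 500] after intersection with the list.

The NES matrix keeps values at q < 0.25 per contrast (cells below the
threshold are not-significant), drops pathways significant nowhere, and
feeds the same clustering routine; discordant pathways are those
significant with opposite NES sign in two chosen contrasts, ordered by
|NES_a − NES_b|.

## qPCR fold changes

ΔCt subtracts the arithmetic mean of the housekeeping Cts of the same
sample (equivalent to the geometric mean of housekeeping expression);
ΔΔCt subtracts the mean ΔCt of the reference group **within the same
sex stratum**; fold = 2^−ΔΔCt. Consequences: reference-group folds have
geometric mean exactly 1 per sex, and any constant shift applied to all
Cts of a sample cancels.

## Pipeline and determinism

Stage order: counts → log2 CPM → per-contrast DE → signatures +
overlaps → ortholog map → reference-cohort scoring, correlation,
clustering → clinical-cohort scoring and report → ranking → GSEA →
NES matrix, clustering, discordance → manifest. Any stage error halts
the run naming the stage. All randomness derives from the single config
seed (stage seeds are small fixed offsets); the manifest echoes the
config and version but carries no timestamps, so rerunning a config
reproduces every numeric artifact byte-for-byte. Default problem sizes
(2000 genes, 6 replicates per cell, 578 reference samples, n_perm =
1000) were chosen so a full synthetic run completes in well under a
minute on one core while leaving all planted effects comfortably
detectable.

## What passing tests do and do not show

The generators are Gaussian/NB with independent genes (plus a low-rank
shared component in the reference cohort): passing recovery tests
demonstrates the statistics and their implementation are correct under
the assumed noise models, not that the pipeline is robust to batch
effects, count overdispersion heterogeneity, normalization history
mismatches between cohorts, or ortholog annotation errors beyond the
simulated 1:many/missing mixture.
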