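# Methods

## Preprocessing model

Probe-level intensities are treated as linear-scale, non-negative
measurements with replicate target probes per probe set plus a pool of
anti-genomic background probes indexed by GC count.

**Detection.** For each probe set and sample, the replicate probe
intensities are compared to the background probes pooled over the probe
set's own GC bins with a one-sided Wilcoxon rank-sum test (alternative:
targets stochastically greater). Midranks handle ties. When the
combined sample size is ≤ 20 the p-value is exact —
P(rank sum ≥ observed) enumerated over all assignments of the pooled
ranks; above that a tie-corrected normal approximation with continuity
correction is used. The detection threshold defaults to α = 0.06, the
conventional presence cutoff for this array family's QC tooling, and is
configurable. Detection always runs on the raw matrix, before any
correction, because the test is relative to the same array's background.
Whether replicate probes should be pooled into one test per probe set or
tested probe-wise is an open design point; pooling is used because the
probe set is the biological unit of reporting.

**Background subtraction.** Per sample, each target probe's intensity
minus the median background intensity of its GC bin, clamped at zero.
A GC bin without background probes falls back to the nearest populated
bin (logged). Medians rather than means for robustness to the heavy
upper tail of background noise.

**Transform.** `log2(x + 16)`. The offset keeps logs finite after
clamping and compresses noise at the bottom of the intensity range; 16
is the conventional small constant for these arrays.

**Quantile normalization** (cohort mode only) is the classic rank-mean
transform: each column's sorted values are replaced by the across-column
mean of sorted values; tied values receive the mean of their tied
positions' reference values. With this tie rule, columns with different
tie patterns can differ slightly in their sorted vectors; on tie-free
data all columns become identical, and the transform is idempotent and
rank-preserving. Fraction-level comparisons deliberately skip this step
so each fraction keeps its own intensity distribution — equalizing
distributions across fractions would erase exactly the abundance
gradients under study.

**Summarization.** Per-sample median over the probe set's probes.

The stage order is detection (raw) → subtraction → offset/log →
(normalization) → summarization. Logging before quantile normalization
matches the reported log2 intensity scale; because the normalization is
rank-based, this placement does not change detection or rank statistics.

## Contaminant catalogue

The 100% criterion is applied within each cellular class separately
(present in every RBC sample, every WBC sample, every leukocyte sample,
each considered on its own) and the three sets are unioned. The
stricter alternative — 100% across all cellular samples jointly — was
rejected as it is not what the class-wise bookkeeping of the fraction
design implies. Each array column counts once; technical replicates are
not collapsed.

## Concordance and variability statistics

Spearman correlation is Pearson on midranks (constant vectors return
NaN with a warning); Pearson is available as an option where a user
prefers it. "Top N" strata rank features by across-sample mean
intensity within the fraction set under study, ties broken
lexicographically for determinism. The contaminant reference profile
(LWR) is the per-feature mean over all cellular-class samples. CVs are
computed on linear-scale intensities (2^x for log2 input) as sample
sd/mean; a log-scale sd variant is available via the `statistic="sd"`
toggle of the class comparison. Paired stratum comparisons use the
two-sided paired t-test on per-feature fraction means; a zero-variance
nonzero-shift difference vector is reported at an underflow-safe
minimum p rather than zero.

## SAM differential expression

Two-class unpaired design (males vs females; positive score = up in
females). For feature i,

    d_i = (mean_F,i − mean_M,i) / (s_i + s0)
    s_i = sqrt( (1/n_M + 1/n_F) · (SS_M,i + SS_F,i) / (n_M + n_F − 2) )

With s0 = 0 this is the classical pooled-variance t statistic. s0 is
chosen by the percentile sweep: candidates are the 0th–100th (step 5)
percentiles of s_i; features are split into `min(100, n/5)` windows of
s quantiles; the candidate minimizing the coefficient of variation of
the per-window median absolute deviation (scaled by 1/0.64) of d wins,
ties to the smallest candidate. Candidates that leave degenerate
(zero-variance, nonzero-difference) features unpenalized are skipped;
if every s_i is equal the common value is returned.

Label permutations are enumerated exhaustively when there are at most
`n_perm` distinct assignments, otherwise sampled uniformly without
replacement; the expected score at rank r is the mean r-th order
statistic of the sorted permuted scores. The delta sweep follows the
canonical construction: at each delta the up/down candidates are the
features whose score departs from the expected score by more than
delta, the cuts are the extreme candidate scores, a feature is called
when it is a candidate and beyond its cut, and the estimated
FDR(delta) is the median over permutations of the count of permuted
scores beyond the cuts divided by the observed call count (0 when
nothing is called; no π₀ rescaling). The smallest delta with estimated
FDR ≤ the target is chosen; a feature's q-value is the minimum
estimated FDR over deltas at which it is called, clipped to [0, 1], and
1 for features never called.

Two properties of this estimator deserve note. q-values of exactly 0
occur whenever a feature's score is more extreme than every permuted
score — with small cohorts this is common and the estimate's resolution
is 1/n_perm. And at call counts near 1 the median-count estimate is
anti-conservative in the per-dataset sense: under a global null the top
feature beats the median permutation extreme in roughly half of
datasets, so a single false call at estimated FDR 0 is frequent even
though the overall fraction of features called on null data stays far
below the nominal rate (measured ≈ 0.4% at a 5% target). This is an
inherent property of the prescribed estimator, not a tuning artifact.

Detection filtering removes called features with zero detection calls
across the cohort. Fold changes are ratios of linear-scale group means
(female/male); a zero male mean yields NA. Sample clustering of the
significant features uses complete-linkage agglomeration on Euclidean
distances of log2 intensities (scipy's implementation; merge heights
are non-decreasing by the ultrametric property).

## Synthetic data generator

The generator is the package's test bed; its defaults are the study
conditions every simulation-based check runs under.

**Array layout.** 847 human probe sets × 4 probes plus 500 background
probes; GC counts uniform on 6–20 for both classes; probe length 25.

**Abundance model.** Per-feature log2 abundances are drawn from a
shifted exponential, `a = μ + σ·(Exp(1) − 1)` — mean μ, sd σ, hard
minimum μ − σ, heavy upper tail. This shape, rather than a normal,
reflects plasma miRNA content: a handful of dominant species over a
dense crowd of near-background ones, which is what produces both the
low all-feature replicate concordance and the high top-stratum
concordance seen in real fractionation data. Circulating features use
μ = 5, σ = 1.5; contaminant features use μ = 8, σ = 1.5 (hematopoietic
cells are far richer in miRNA than cell-free plasma, which is why
carryover is visible at all).

**Fraction design.** One sample per fraction per subject (3 subjects
by default — enough biological replicates for pairwise stability
analysis). Contaminant features are scaled by per-fraction carryover
multipliers (CS = P1 = cellular classes = 1.0; S1 = 0.05, S2 = 0.04,
P2 = 0.05 — small but nonzero so the +S/+L class is populated).
Circulating features are present at full abundance in CS/S1/S2/P2,
depleted to 0.1 in the dense first pellet P1 (a cellular isolate whose
non-contaminant content is compositionally distinct), and absent from
the cellular classes.

**Measurement model.** A probe reads
`bg(gc)·ε₁ + signal·ε₂` with `bg(gc) = 2^(5.0 + 0.1·gc)` and ε
log-normal with sd 0.25 log2 units; inter-subject biological effects
are N(0, 0.4²) in log2 (optionally inflated on contaminants via
`contaminant_bio_sigma_log2`, modelling variable hemolysis). The
background scale (≈ 50–130 linear units across GC bins) places the
noise floor between the dim circulating bulk — which becomes
noise-dominated, as in real plasma — and the robustly expressed band
(linear signal ≳ 64), which stays reproducible. Setting both noise
terms to zero reproduces the deterministic mean model exactly.

**Cohort arm.** 8 male + 10 female S1 samples; 4 circulating features
are multiplied by 1.8 in females. Differential candidates are drawn
from circulating features with baseline log2 abundance ≥ 6, matching
the intensity band of real cohort hits — the additive background
compresses the measured fold of dimmer features below the ~1.6–1.9×
range such hits show, so planting them there would simulate a
different study.

**What the generator does not model:** exosome/microvesicle physics,
RNA degradation, array spatial artifacts, probe-specific affinity or
cross-hybridization, and batch effects. Passing recovery tests on this
generator therefore demonstrates the pipeline's correctness under the
assumed noise structure, not performance on any particular real array.

## Problem sizes used in the test suite

Simulation-based checks run at the full default scale (847 features)
for single-seed tests; the 20-seed differential-expression recovery
uses full scale with 1000 permutations; the null calibration uses 200
replicates at 200 features with 100 permutations each — a reduced
scale chosen to keep the calibration statistically meaningful while the
suite stays quick. Fixed-seed qualitative checks use seed 1. The
replicate-stability gradient (top-20 vs all features) is an expectation
statement; with 3 replicates its pairwise-Spearman estimate carries
sampling noise of roughly ±0.1, so individual seeds can invert it.

## Known limitations

- The Wilcoxon exact branch enumerates combinations; it is intended for
  the small pooled designs where it activates (combined n ≤ 20).
- The SAM FDR estimator's small-call-count anti-conservativeness is
  documented above; consumers wanting per-dataset false-positive
  control at tiny call counts should require q strictly below the
  target or raise the permutation count.
- Quantile normalization assumes exchangeable intensity distributions
  across samples; it is intentionally not applied across fractions.
- The CLI loads whole matrices into memory; array-scale data is far
  below any practical limit.
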