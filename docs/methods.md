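# Methods

This note documents the model, its parameters, the numerical choices
made where the design was open, what the synthetic data generator does
and does not emulate, and known limitations.

## Signal model and valley calling

HAc ChIP-seq coverage is treated as a per-bp step function, sampled at
one value per 10 bp grid point (the value at the bin's start
coordinate, matching bedGraph step sampling; a bin-mean convention
would differ only at read boundaries). Sampling precedes smoothing; the
alternative order (smooth per-bp, then sample) differs only by
sub-bin-scale terms at σ = 40 bp ≫ 10 bp.

Smoothing convolves with a Gaussian of σ = 40 bp (σ/step = 4 bins),
truncated at ±4σ and renormalized — tail mass below 10⁻⁴ — with
edge-replicated (nearest) padding so a constant track maps to itself.

Valley calling uses flanking windows of 50–500 bp on each side. Windows
are truncated at track ends; a point with an entirely absent window is
not callable, because the rule requires both maxima. The comparison
`s < 0.70·min(L, R)` is strict: a point exactly at threshold is not a
valley. Consecutive valley sample points merge into one call
(`[first, last + step)`), scored by the maximum point score in the run:
one dip spans many 10 bp points and should yield one call. The flanking
maxima are computed with vectorized sliding-window maxima and are
tested for exact equality against an exhaustive per-point scan.

Since the rule is a ratio, calls are invariant to rescaling the track;
scores scale linearly.

**Enriched-region hook.** On real data, valleys are meaningful only
inside acetylated (IP-enriched) regions; deriving those regions from an
IgG control is out of scope here. `call_valleys` therefore accepts
either a boolean per-bin mask or a `min_score` floor: a valley whose
score (the local flanking signal level) is below the floor sits in
unacetylated background and is dropped. The synthetic pipeline uses
`min_score = 0.3 × plateau height` (well above the noise floor of the
inter-gene baseline, well below any promoter plateau).

## Promoters, APRs, sequences

Promoter windows are strand-aware half-open intervals: −1500/+500 bp
around the TSS for the motif background set, −2000/+500 for ChIP read
counting, mirrored on the − strand and clamped at position 0. A valley
overlapping a gene's TSS ± 5 kbp window by ≥ 1 bp is an APR of that
gene; a valley near two TSSs counts for both (no tie-break is defined
by the method; containment can be required via a flag). APR sequences
are always scored as separate regions so no motif placement can span
two valleys.

## Motif scoring

PWMs are stored as count matrices; probabilities add a pseudocount of
0.375 per base (TRANSFAC matrices contain zeros and would otherwise
produce −∞ log-ratios). Background base frequencies are estimated from
the background sequence set. The raw score is the natural log of the
mean per-sequence average likelihood ratio over all placements on both
strands. Reverse-strand placements score the reverse complement of the
window, with the background likelihood taken over the complementary
bases, which makes ALR(S) = ALR(revcomp(S)) exact for any background
composition. Ambiguous bases (N) contribute a neutral factor of 1
rather than invalidating the placement. The log base is irrelevant to
within-run comparisons; natural log is used.

This is a single-placement log-average-likelihood statistic; the
original Clover tool's multi-instance recursion is deliberately not
reproduced, and byte-compatibility with the Clover binary is not
claimed.

**Enrichment p.** The null resamples length-matched *fragments*: for
each target sequence, a random same-length substring of a random
background sequence long enough to contain it. Equal-count subset
resampling is also available, but fragment matching is the default
because APR fragments (~0.2–0.5 kb) are much shorter than whole
promoters (2 kb), so no fixed-count subset can match total target
length. Per-PWM placement products over the background are cached as
prefix sums, making any substring's ALR O(1) and the R = 1000 draws
cheap. p = (1 + #{null raw ≥ observed}) / (R + 1), floored at
1/(R + 1); calibration (P(p ≤ α) ≤ α) is verified on targets drawn
from the background itself.

Motifs with p ≤ 0.01 at ≥ 1 time point are retained. Ranking methods:
score range (default, max − min over time), max score, score at the
time nearest the expression peak, and |R| at the optimal lag. Ties
break lexicographically by motif ID.

## Expression processing

Intensities are log₂; genes whose maximum sample reaches log₂(64) = 6
define the expressed universe. Differential expression combines a
one-way ANOVA F across time points with a permutation null: "balanced"
permutations are uniform label permutations, which preserve group sizes
by construction (the exact historical scheme is not recoverable). Each
permutation is applied to all genes and the pooled null yields an
empirical-FDR q:

    q(F) = (mean # null F ≥ F per permutation) / (# observed F ≥ F)

monotonized so q is nonincreasing in F (each gene takes the minimum raw
q among genes with larger F) and capped at 1. The permutation p is
floored at 1/(B+1). With a single replicate per time point the F test
degrades and a warning suggests fold-change-only selection.

Fold change is measured against the 0 h baseline, maximizing |log₂ FC|
over stimulated time points; selection requires q ≤ 0.01 and FC ≥ 5,
with direction given by the sign at the maximizing time point. Up and
down sets are clustered separately (defaults k_up = 5, k_down = 3,
chosen to reproduce an eight-cluster structure) by Lloyd k-means under
d(x, y) = 1 − Pearson(x, y): profiles are z-scored, assignment
maximizes correlation with the centroid, and the centroid update is the
re-standardized member mean (for z-scored vectors, correlation is a
dot product, so this is spherical k-means and the objective is
nonincreasing). Ten seeded restarts keep the best within-cluster
distance sum; empty clusters are re-seeded from a random member.

The expression time grid defaults to 0/2/4/12 h (the grid the
interpolation step defines; a 1/4/12 h reading also appears in the
source material and is configurable).

## Time-lagged correlation

Cluster-median expression is linearly interpolated; the motif score
series is *not* interpolated — it is evaluated at its native 0/1/2/4 h.
Lag optimization is a dense grid search on [0, 2] h at 10⁻³ h: it is
deterministic, oracle-testable, and fine enough to resolve published
lag precision (three decimals). Ties break toward the smallest τ. The
per-cluster fixed lag maximizes Σ R_τ² over the cluster's retained
motifs; the per-motif optimal lag maximizes |R_τ| (so a strong
repressor with R < 0 is found, and the signed R at that τ is
reported). With only four paired points no p-value is attached to R.
Zero-variance series give undefined R (reported as NaN, never 0).

## ChIP-seq validation

The statistic per gene set is log₂(1 + Σ counts); the pseudocount of 1
guards empty random sets. Random sets are drawn without replacement
from the expressed universe; the null SD uses ddof = 1 over the 1000
sets. z = (obs − μ)/σ, p = 2(1 − Φ(|z|)), and BH q over the family of
all (TF, time, cluster) tests in the run. A degenerate null (σ = 0) is
flagged and excluded from the FDR family. Counting inside HAc-valley
APRs instead of the fixed promoter window is available as a region
provider. Note the test is two-tailed: when the universe is small and
strongly enriched clusters are part of it, other clusters can appear
significantly *depleted* — with a genome-scale expressed universe this
effect is negligible.

## Synthetic data generator

The generator emulates the statistical structure the method assumes,
at a scale (2 chromosomes × 2 Mbp, 200 genes, 20 motifs of width 8,
4 clusters × 25 genes, 3 replicates) that runs the full pipeline in
seconds per replicate on one CPU:

* promoter HAc plateaus (height 50, ±4 kbp) over a baseline of 2, with
  Gaussian dips (σ = 60 bp, depth 85% of the plateau — comfortably
  below the 70% calling threshold); Gaussian signal noise with
  SD = 10% of plateau height;
* each DE gene has one always-open neutral dip and three motif-rich
  dips that open when its cluster's activity crosses 0.25/0.6/0.9.
  Because the genome sequence is fixed, temporal modulation of motif
  scores is realized through which dips are open, giving a graded
  occupancy series per cluster;
* cluster activity templates pair one transient with one sustained
  program per direction, so the induced expression shapes are
  separable under the 1 − r distance (as distinct temporal programs in
  real data are); activator clusters follow + activity, repressor
  clusters − activity, shifted by a planted lag from {0, 0.5, 1.0,
  1.5} h; per-gene scaling U(0.85, 1.2), expression noise SD 0.15
  log₂ units, flat filler genes (half below the intensity floor);
* two ubiquitous motifs are planted once in every neutral dip: they are
  retained (valley sequence is denser in them than background
  promoters) but temporally flat, providing realistic decoy
  competitors; 14 motifs are never planted;
* TF reads are uniform over the genome (Poisson) plus an
  activity-scaled enrichment (factor up to 3) over target-cluster
  promoters.

The planted-lag series generator used by the lag-recovery checks emits
pulse-shaped response profiles (random peak time, width, sign,
amplitude) and defines noise relative to the score series' own range.
Near-affine profiles make the lag unidentifiable from four points and
do not occur in this family.

**What is not emulated:** fragment-level read simulation (GC bias,
mappability, adapter artifacts), IgG input controls, isoform-resolved
TSS ambiguity, overlapping promoter windows, correlated noise across
time points, and motif co-occurrence or competition. Passing tests
therefore demonstrate correctness of the statistical machinery on data
that satisfy the model's assumptions, not robustness to every artifact
of real ChIP-seq.

## Degenerate inputs and tie-breaks (summary)

* Point exactly at the 70% threshold → not a valley (strict `<`).
* Empty flanking window → point not callable.
* Sequence shorter than motif width → skipped (warning); all skipped →
  raw score NaN, motif flagged.
* Time point with no APR sequence → NaN score/p, excluded from
  retention and ranking.
* Zero-variance score or expression series → R undefined (NaN).
* Equal lag objective on the grid → smallest τ.
* Equal ranking statistic → lexicographic motif ID.
* Null SD = 0 in the ChIP test → z undefined, excluded from FDR.

## Limitations

With four time points, Pearson R is highly uncertain and the optimal
lag frequently saturates at a range boundary — both behaviors the
published analysis also shows; interpret per-motif lags as qualitative.
The empirical-FDR q is conservative for small gene counts. The valley
caller's `min_score` floor is a proxy for a proper IP-vs-control
enriched-region map and should be replaced by one when controls exist.
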