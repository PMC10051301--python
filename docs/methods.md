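# Methods

## Problem and design

`seroprofile` implements the analysis side of a two-phase autoantibody
profiling study in systemic sclerosis (SSc). Phase one is an untargeted
screen: two pooled plasma samples (diffuse-cutaneous and limited-cutaneous
patients) are assayed on a planar antigen array spanning tens of thousands
of protein fragments, and antigens with strong diffuse-pool IgG signal are
selected. Phase two is targeted: a bead array carrying the selected
fragments plus literature-reported SSc antigens screens individual case and
control plasmas; reactivity is binarized per antigen and all downstream
statistics (autoantibody load, prevalence, panel classification,
clustering) operate on the binary matrix.

## Normalization

Planar arrays are standardized array-wise to nSD units,
`(x - mean) / SD`, with the population SD (`ddof=0`); at array sizes in
the tens of thousands the `ddof` choice is immaterial, but it is fixed and
configurable for reproducibility. Bead data are normalized sample-wise to
nMAD units, `(x - median) / MAD`, with the **unscaled** MAD — no 1.4826
consistency factor, because the statistic is used as a robust scale unit,
not as a normal-SD estimator. Sample-wise centering/scaling removes
per-sample affine background differences exactly (the transform is
invariant to `a·x + b`, `a > 0`, per row); this is the motivation for the
generator's multiplicative per-sample shift (below). Medians of
even-length vectors are the mean of the two central order statistics. A
row with zero MAD is an error naming the sample; a configurable column
exclusion list (e.g. assay-control analytes) can be left out of the row
statistics.

## Planar candidate selection

Candidates are antigens with diffuse-pool nSD at or above a cutoff
(default 4) and a positive diffuse-minus-limited difference (default
margin 0). Ranking is the average of the descending rank by diffuse-pool
nSD and the descending rank by pool difference, ties broken by antigen
id — a reproducible total order combining signal strength and pool
separation without arbitrary weights; single-key orderings are available.
The cutoff is applied to the diffuse pool only, since the screen targets
diffuse-enriched reactivity.

A note on recall: injecting m spots elevated by k background SDs into an
array of n antigens inflates the array SD by ≈ √(1 + (m/n)·k²), so at
m/n ≈ 3% and k = 8 the elevated spots sit only ≈ 4.6 post-contamination
SDs out and recall at the 4 SD cutoff caps near 0.86 regardless of the
background family. At the realistic screen scale (59 of 42,000; m/n ≈
0.14%) the dilution is negligible and recall is essentially complete; the
test suite therefore checks recall at that scale.

## Reactivity calling

Per antigen, across all samples of the normalized matrix:
`cutoff = max(floor, median + c·MAD)` with defaults `c = 5`, `floor = 5`
nMAD. The rule is robust (median/MAD tolerate up to ~40% reactive
samples per antigen without drifting), monotone in both constants, and
reproducible from its parameters; an antigen whose across-sample MAD is
zero falls back to the floor-only cutoff (logged). Ties at the cutoff are
negative. A fixed-threshold strategy exists for sensitivity analysis, and
raw-intensity thresholding is possible behind an explicit flag but not
endorsed. Antigen calls aggregate to proteins by logical OR over
fragments; downstream statistics default to the protein level.

## Statistics

All tests are nonparametric. Two-group load comparisons use the two-sided
Mann–Whitney–Wilcoxon test (exact for small tie-free samples, tie-corrected
normal approximation otherwise); k ≥ 3 groups use Kruskal–Wallis with tie
correction (a completely constant sample returns H = 0, p = 1 by
convention). Load–age correlation is Spearman by default (Pearson via
option), consistent with the rank-based toolkit. Prevalence uses the
two-sided Fisher exact test under the point-probability convention — the
sum of probabilities of all tables, margins fixed, no more probable than
the observed one; this was verified against exact rational-arithmetic
enumeration on every 2×2 table with n ≤ 40. Raw p-values are reported by
default (matching the single-screen reporting style);
Benjamini–Hochberg adjustment is available and labelled.

Fisher's exact test is conservative on sparse tables: by exhaustive
binomial enumeration at 55 vs 52 samples its exact size at α = 0.05 is
0.010 at prevalence 0.04 and peaks at 0.040 near prevalence 0.3. The
type-I calibration checks therefore run at null prevalence 0.3, the
regime where the discrete test's size is closest to nominal; at sparse
prevalences the test is simply conservative, which is a property of the
test, not a defect of the pipeline.

The candidate-selection rule keeps a target when its case-vs-control p is
below α = 0.05, **or** when its case prevalence strictly exceeds the
control prevalence and the target maps to a fibrosis-related protein
("strictly exceeds" resolves the otherwise unspecified margin; a protein
is fibrosis-related when any of its fragments is flagged).

Clinical-panel augmentation counts a case positive when either the
clinical antibody panel or the added array marker is positive; all
percentages anywhere in the pipeline are rounded half-up to the nearest
integer using exact rational arithmetic (41/55 → 75%, 3/8 → 38%). Note
that 9/13 rounds to 69% under this rule.

## Panel classification and clustering

The count classifier labels a sample positive when its load over a marker
panel is at least k; sweeping k = 0..k_max+1 yields a discrete ROC whose
trapezoid AUC (curve anchored at (0,0) and (1,1)) equals the
Mann–Whitney probability that a random case outranks a random control
with half-credit ties, provided k_max reaches the maximum observed load
(the default).

Binary profiles are clustered agglomeratively with complete linkage on
simple-matching (Hamming proportion) distances. Simple matching rather
than Jaccard because all-negative profiles — a real and clinically
meaningful pattern — leave Jaccard undefined between zero vectors;
distance and linkage (average, Ward-on-Euclidean) are configurable.
Because binary data produce many tied distances and agglomerative merge
order otherwise depends on input order, rows are canonicalized by sample
id before computing distances, making assignments invariant to row
permutations. Clusters are renumbered by decreasing mean within-cluster
prevalence, so the least-reactive cluster always carries the highest
label. k defaults to 4; a silhouette score is reported as a diagnostic and
never used to choose k. Heatmap export writes a TSV twin in dendrogram
order for bit-exact checking.

## Synthetic data

The generator defines the study conditions for all tests. The bead cohort
defaults to 55 cases / 52 controls / 246 antigens with 132 truly reactive
antigens. Background MFI is log-normal, `exp(N(6, 0.35))` (≈ 400 MFI
median), times a per-sample multiplicative shift `exp(N(0, 0.3))` — the
artifact nMAD normalization is designed to remove, making normalization's
purpose directly testable. A truly reactive sample–antigen pair is drawn
Bernoulli with prevalence 0.08 (cases) vs 0.04 (controls) — placing
per-antigen positive counts in the single-digit-to-tens range and
per-sample loads on the one-to-fifteen scale — and multiplies the signal
by `exp(3.5) ≈ 33`, giving ≥ 10 nMAD separation. Cases flagged with lung
fibrosis or a skin score above 15 receive an additional +0.05 positivity
probability per feature, so the both-features subgroup has the highest
expected load by construction. Clinical metadata reproduce the study
table's marginals exactly where they are counts (42/11/2 subtypes, 14
lung fibrosis, 13 high skin score with 8 overlapping, antibody and
manifestation counts) and statistically where they are summaries (84%
female cases, median ages ≈ 61 vs 53). Controls carry missing clinical
flags and skin scores — missing is a distinct state and is never coerced
to false. All draws flow from one seeded generator; identical
configurations give bit-identical outputs.

What the generator does **not** emulate: plate/batch effects, bead-count
QC, tag-reactivity (His6ABP) artifacts, antigen cross-reactivity
structure, or the unknown true MFI distribution family. Passing tests
therefore demonstrate the pipeline's correctness and calibration under a
plausible noise model, not performance on the original restricted cohort;
cohort-specific headline numbers (reactive-antigen fraction, panel AUC,
classification rates at particular cutoffs) depend on the real data and
are not reproduction targets.

## Problem sizes

The test suite and acceptance script use: 1,000 null antigens for type-I
calibration, 300 enriched antigens for power/recovery, the default
107 × 246 cohort for end-to-end sensitivity (observed sensitivity 1.0 at
false-positive rate < 1%), the 42,000-antigen screen for planar recall,
and 50-sample two-signature fixtures for cluster recovery. Exhaustive
oracle checks cover all 2×2 tables with n ≤ 40 and Mann–Whitney group
sizes up to 8.
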