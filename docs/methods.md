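# Methods

This note documents the statistical procedure `dtwnet` implements, the
choices that were genuinely open when the package was designed, the
defaults and what they mean, and what the synthetic test-bench does and
does not demonstrate.

## Data model and preprocessing

The unit of analysis is a panel: S subjects × T assessments × K
attributes, T ≥ 3 (six in the motivating design), with assessments
treated as consecutive integer indices. Calendar spacing between
assessments may be unequal; the alignment treats consecutive assessments
as one "step", so all lead/lag statements are in units of assessments,
not weeks.

Preprocessing is pinned to the order **reverse-code → center →
standardize**:

1. *Reverse coding.* Attributes scored "higher = better" (self-efficacy,
   social support, quality of life, well-being, BMI and self-rated
   health in the shipped schema) are negated so higher always means
   worse. Negation rather than max-minus-score is used because after
   centering the two differ only by a constant, and negation requires no
   knowledge of scale bounds. Whether self-rated health belongs in this
   set is a schema flag, not a code constant.
2. *Within-person centering.* Each (subject, attribute) series has its
   own observed-value mean removed. Between-person differences in level
   are typically much larger than within-person change; without this
   step the group-level distances mostly measure level differences, and
   the cluster structure of change patterns is swamped (the synthetic
   generator plants exactly this failure mode via large random subject
   intercepts).
3. *Group standardization.* Each attribute's centered values are divided
   by the pooled SD over all subjects and timepoints, using the
   population denominator n. The denominator choice is a pure scale
   factor — every downstream quantity is invariant to it — and is pinned
   only so tests are deterministic. Standardization uses observed values
   of the dataset at hand; for imputation stacks it is applied per
   replicate.

Missing values pass through preprocessing untouched and are a hard error
at the alignment layer: DTW runs only on complete (imputed) replicates.

## Undirected alignment

For two preprocessed series the local cost is c(i,j) = |xᵢ − yⱼ| (the
conventional univariate pointwise metric). The cumulative cost uses the
symmetric2 step pattern — diagonal steps weighted 2, horizontal/vertical
steps weighted 1, initialized g(1,1) = 2c(1,1) — restricted to the
Sakoe-Chiba band |i − j| ≤ w with w = 1 by default, and is normalized by
N + M. Consequences of this parameterization:

* the distance is symmetric in its arguments and zero iff the series are
  identical;
* a perfectly diagonal alignment of equal-length series gives exactly the
  mean absolute difference (e.g. two constant series one unit apart are
  at distance 1);
* with T = 6 a band of 1 permits alignment shifts of at most one
  assessment, keeping "co-occurrence" temporally local;
* widening the band can only decrease the distance (the band-monotonicity
  property tested in the suite).

The boundary weight on the first cell is not forced by the step-pattern
name; it is pinned to 2 (the Sakoe-Chiba weighting) so that the dynamic
program agrees exactly with exhaustive path enumeration and the
mean-absolute-difference identity above holds.

Per subject this yields a K × K symmetric distance matrix. Matrices are
averaged elementwise first across imputation replicates, then across
subjects. For elementwise means the two stages commute; the order is
pinned so intermediate artifacts are reproducible.

## Dimensions (clustering)

Agglomerative clustering runs on the group distance matrix treated as a
dissimilarity, Ward linkage by default (average and complete supported).
The number of clusters k is chosen by maximizing the mean silhouette
width over k ∈ [2, K−1], ties resolved to the smaller k; the trace of
silhouette values is kept in the results and the exported run summary.
Neither the linkage, the k rule, nor the distance-to-weight transform of
the network display (s = 1/(1+d), chosen as a bounded, strictly
decreasing map) is forced by the method; all three are recorded in the
run summary as settings. Tree cuts use `cut_tree`, which yields exactly
k groups even under tied merge heights (a tie otherwise makes some k
unattainable by height thresholding). Ward is monotone under the
Lance–Williams recurrence, so merge heights are non-decreasing and the
exported Newick dendrogram has nonnegative branch lengths.

## Directed alignment and the direction contrast

The directed variant asks whether one series' changes precede another's.
Each index i of x must match exactly one index j(i) of y with j(i) ∈
{i, …, i + L} (L = 1 by default: lag-0 or lag-1), j non-decreasing and
advancing at most two target indices per step; the cost Σ c(i, j(i)) is
normalized by N. D(a→b) is small when a aligns with same-time-or-later
values of b, i.e. when a leads.

A raw DTW distance is nonnegative, so "significantly larger than zero"
cannot apply to it directly. The quantity tested is therefore the
**direction contrast**

δ(a→b) = D(b→a) − D(a→b),

antisymmetric by construction, positive when a temporally leads b. This
is the one place where the analysis required an interpretive decision
rather than a transcription; the contrast is the only antisymmetric
function of the two directed distances that is zero for symmetric pairs,
and it is flagged as a design decision rather than ground truth.

Group-level inference: per ordered pair, a one-sided one-sample t-test
across subjects of H₀: E δ ≤ 0 (Wilcoxon signed-rank available as an
option). An edge a→b is drawn when p < α (default 0.05); antisymmetry
guarantees at most one direction per pair can be significant. No
multiple-testing correction is applied to the edge tests by default —
the node-level strength tests (one per attribute, K in total) are the
designated main outcome family — with Bonferroni and Benjamini–Hochberg
available as options. Degenerate zero-variance pairs follow the pinned
convention: constant positive mean → significant (flagged
`zero_variance`), otherwise not.

## Strength centralities

Per subject, out-strength of node j sums the positive parts of δ(j→k)
over the other nodes, in-strength the positive parts of δ(k→j).
Positive-part sums keep the two kinds separately meaningful despite the
antisymmetry of δ. Standardization is within-subject mean-centering
across the K nodes (per kind), so a "significant" strength means
*above the subject-average strength of the network*, and standardized
strengths sum to zero within each subject by construction. Group
estimates are across-subject means with t-distribution 95% CIs;
significance is CI entirely above zero. Strengths are computed from the
imputation-averaged per-subject δ (analyses per replicate, then
averaged), not pooled across replicate-level strength estimates;
Rubin-style between-imputation variance is deliberately out of scope.

## Synthetic data generator

The generator emulates the cohort design the pipeline targets, and its
defaults are the study-shaped conditions: 355 subjects, T = 6, the
shipped 12-attribute schema partitioned into four dimensions of sizes
5/2/2/3, monotone dropout with per-assessment hazard 0.074 (≈ 0.93⁵ ≈
68% retention at the final assessment, matching the observed final
retention; observed retention is front-loaded at the first follow-up,
which a constant hazard cannot reproduce), and 100 imputations.

Per subject, each cluster has a latent AR(1) factor with φ = 0.4,
standard-normal innovations and stationary initialization (variance
1/(1−φ²)); attribute = intercept + loading·fₜ + N(0, noise_sd), with
noise_sd = 0.5 and loading 1. Subject intercepts are N(0, 2·noise_sd+1),
deliberately large so that skipping within-person centering visibly
destroys recovery. The planted lead is implemented at the factor level:
the follower reads its cluster's factor one step late, so its baseline
value reads the stationary pre-baseline factor instead of an edge
artifact. Reversed attributes are emitted negated. Everything is
deterministic under the config seed.

Leader placement is a free design choice the study description does not
pin. The reference configuration puts the leader and its single follower
together in one size-2 cluster (the follower's trajectory is the lagged
cluster factor, so the pair still co-varies and clusters together).
Placing followers in a *different* cluster than the leader would make
one cluster a lagged copy of another; with a band of 1 the undirected
alignment can partially absorb a one-step shift, which pressures the
clustering to merge the two and would confound cluster recovery with
lead recovery. The within-cluster placement keeps the two benchmarks
orthogonal.

The LOCF-plus-noise imputer (`naive_impute`) is a test double: it
exercises the stack plumbing (M complete replicates, replicate-level
analysis, averaging) but none of the statistical properties of
model-based multiple imputation, and it is not a recommended method for
real data.

What passing the synthetic benchmarks shows: the pipeline recovers
planted co-variation structure and one-step temporal precedence at
realistic noise levels, and its directed tests are approximately
calibrated under independence. What it does not show: robustness to
non-AR(1) dynamics, informative dropout, floor/ceiling effects of real
instruments, unequal assessment spacing, or imputation-model
misspecification — real cohort results depend on all of these.

## Problem sizes of the shipped benchmarks

The recovery bench fits the full pipeline on 20 independent draws of the
reference configuration (300 subjects, 12 attributes, T = 6); the null
calibration uses 200 cohorts of 100 subjects and 6 independent
attributes; the oracle sweeps compare each dynamic program against
exhaustive enumeration on 1000 random pairs of lengths 4–8. These sizes
give Monte-Carlo error comfortably below the decision thresholds they
feed (e.g. the null edge-rate SE is ≈ 0.003 against an acceptance band
of [0.025, 0.10]). The pairwise stages are vectorized across subjects
(`dtw_*_batch`), so a full 355 × 6 × 12 cohort with 100 imputations
remains a desk-scale computation.

## Numerical and degenerate-input conventions

* Ties among optimal warping paths break toward the diagonal step; this
  affects only the reported path, never the distance (both dynamic
  programs are verified against enumeration to 1e-12).
* A zero-variance attribute cannot be standardized and is a named error;
  the validation report warns about it beforehand.
* Silhouette for the all-singletons partition (k = K) is defined as 0.
* Subjects with no observed values for an attribute stay all-missing
  through centering; imputation of an attribute with no observed
  baseline is an error.
* CSV round trips are bit-exact: values are written with Python's
  shortest round-trip float representation and parsed with correctly
  rounded conversion.

## Known limitations

* T is small by design; DTW on six points cannot distinguish rich lag
  structure, only one-assessment precedence.
* The direction contrast is a pinned interpretation (see above), not the
  only possible reading of a "directed distance" test.
* Group aggregation is a plain mean over subjects; no heterogeneity
  model, no subject-level network inference.
* The trajectory summary is descriptive (observed per-timepoint means
  and SEs), standing in for a random-intercept mixed model, which is out
  of scope.
* No bootstrap stability analysis of the cluster count; the silhouette
  trace is exported so users can judge how sharp the optimum is.
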