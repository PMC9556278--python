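# Methods

## The coating index and its conventions

The per-subject, per-taxon IgA index is
`−(log a⁺ − log a⁻)/(log a⁺ + log a⁻)` on fraction relative abundances
`a⁺, a⁻ ∈ (0, 1)`. Because both logs are negative, `|log a⁺ − log a⁻| ≤
|log a⁺ + log a⁻|`, so the index lies in [−1, 1]; the sign convention is
fixed so that positive = preferentially coated (enriched in the IgA+
fraction), verified against the worked value `index(0.1, 0.01) = 1/3`.
The base of the logarithm cancels.

Zeros are handled by a per-cell pseudocount (default 1 read) added to
each fraction's counts before normalization; the log-ratio is undefined
at zero and the pseudocount keeps the index bounded while shrinking
low-evidence cells toward 0. A taxon undetected in *both* fractions of
a subject yields a missing value, not a pseudocount-driven 0: double
absence carries no information about coating. A taxon detected in only
one fraction does get an index — that asymmetry is exactly the signal
the assay measures.

## Enrichment calling

Within each diagnostic group, each taxon's per-subject index values are
tested against 0 with a two-sided one-sample Wilcoxon signed-rank test —
the natural paired test for a within-subject fraction contrast —
followed by Benjamini–Hochberg adjustment across taxa within (site,
group). The call (enriched / depleted) is the sign of the median index
among taxa passing the FDR threshold (default 0.05). Taxa with fewer
than `min_n = 5` informative subjects are reported as *untested* rather
than non-significant: below n = 5 the exact signed-rank test cannot
reach two-sided p < 0.05, so "ns" would be misleading. Enrichment is
assessed per group (separate patient and control panels); a pooled
variant can be had by relabelling the manifest.

Between-group differences in the index use the two-sample rank-sum
test, BH-adjusted across taxa within a site.

## Rank-test conventions

Small cohorts sit where exact and asymptotic null distributions
disagree, so the switch-over is fixed package-wide: rank-sum tests use
the exact null when both groups have ≤ 10 tie-free observations, and
the normal approximation with tie and continuity correction otherwise;
signed-rank tests are exact up to n = 25 without zeros; Spearman
p-values are exact permutation probabilities up to n = 9 (midranks for
ties) and t-approximate beyond. BH adjustment skips untested (NaN)
hypotheses without counting them toward the family size.

## Diversity

Alpha diversity: Observed richness (counts > 0), Shannon entropy with
the **natural log** (configurable in principle; the choice only scales
values, not tests, since rank tests are monotone-invariant), and
Inverse Simpson. Proportions for diversity use no pseudocount. No
rarefaction is applied anywhere: the 7,500-read retention rule already
imposes a depth floor, and rank-based comparisons are robust to modest
depth variation; this choice is deliberate and documented rather than
hidden.

Unweighted UniFrac is computed on presence/absence (counts > 0) over a
rooted tree via scikit-bio; the test suite holds it to exact agreement
with an independent brute-force per-branch XOR/OR enumeration. Taxa
missing from the tree are an error unless pruning is explicitly
requested, because silent pruning changes distances. Trees with a
multifurcating root are midpoint-rooted (logged); a perfectly balanced
polytomy, whose midpoint is the root itself, is resolved with a
zero-length internal branch, which leaves all path lengths and hence
all distances unchanged.

PCoA is the classical Gower double-centering of −½D² with an `eigh`
decomposition; negative eigenvalues (non-Euclidean distances) are
reported but carry no coordinates, and proportions explained are taken
relative to the positive-eigenvalue sum. PERMANOVA uses Anderson's
pseudo-F with free permutation of sample labels (no strata) and
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm); the seed is a required
configuration field. With small balanced groups the minimal attainable
p exceeds 1/(n_perm+1) slightly because random permutations can
reproduce the observed partition.

## Disease-activity correlation

Spearman rho of a per-subject taxon statistic against BASDAI, with the
BH family defined as all taxa tested at one site for one statistic type
(index or relative abundance) — one family per results panel. Subjects
with missing BASDAI are excluded per taxon; constant statistics are
skipped with a logged reason. Results carry a two-tier label:
`significant` below FDR 0.05 and `trend` below 0.20, reflecting common
exploratory reporting in small cohorts; both thresholds are
configuration.

## Discriminant cascade

The three-step cascade follows the published LEfSe convention with all
knobs exposed: per-sample scaling to a total of 1e6; Kruskal–Wallis
class test at `alpha_class` (presets: strict 0.05, relaxed 0.10);
a subclass-consistency step in which, for every subclass level (e.g.
sex) present in both classes, the between-class rank-sum test must
reach `alpha_sub` *and* agree in direction with the class-level mean
difference — pairings too small to ever attain `alpha_sub` (minimum
exact p above it) are skipped with a log line, and with no usable
subclass the step passes trivially with a warning; finally 30 bootstrap
rounds of two-class LDA on 2/3 subsamples, within-class scatter
ridge-regularized by `1e-6 · trace/p` so p ≫ n feature tables (KO
matrices) remain solvable. The per-feature effect size is the bootstrap
mean of `log10(1 + (|w_f·d| + |Δ_f|)/2)` with `w` the unit-norm
discriminant direction, `d` the projected class-mean separation and
`Δ_f` the raw class-mean difference; scores are signed by the enriched
class and thresholded at 2.0.

Two properties of the cascade are worth stating plainly. First, the
false-positive control at default thresholds comes mainly from the
subclass-consistency step (two independent within-sex tests must both
reach 0.05 in the same direction), not from the LDA threshold: on the
1e6 scale, features with realistic dispersion easily exceed score 2
whenever they pass the class test. The LDA gate only adds control when
within-class dispersion is small relative to ~100 scaled units; the
corresponding unit test uses tightly dispersed features to exercise
that regime explicitly. Second, compositional scaling couples features:
planting large abundance shifts in major components depresses all other
features. The synthetic function-table generator therefore plants
differential features as minor components, which is also the realistic
case for single gene families within a metagenome.

## The synthetic cohort generator

Per subject `s`: composition `π_s ~ Dirichlet(alpha_base)` (default
symmetric with concentration 1); coating probability `θ_{s,t} =
logistic(μ_t + β_t·group_s + ε_{s,t})`, `ε ~ N(0, σ_subject²)` with
σ_subject = 1 logit by default — substantial between-subject coating
variation, as sorted-fraction data show. The sort is compositional: the
IgA+ library is multinomial from `π·θ` renormalized and the IgA− one
from `π·(1−θ)`, because 16S sequencing observes composition, not
absolute load; a `carryover` parameter mixes the fractions (default 0,
as sort purity is not quantified). Depths are negative-binomial around
`depth_mean` (default 30,000; dispersion 0.3) so the read filter has
something to reject. BASDAI is `clip(b0 + b1·logit(θ_{s,t*}) + N(0,
σ_b²), 0, 10)` with defaults b0 = 3.5 (a typical active-disease
median), b1 = 1.5, σ_b = 1; it is emitted for every subject, patients
and controls alike. Defaults of 15 subjects per group and 50 taxa match
small single-center cohorts.

What the generator does *not* emulate: sequencing error and chimeras,
taxon–taxon ecological interactions, site-specific community structure,
and covariate confounding (sex is assigned alternately, independent of
group). Passing recovery tests therefore demonstrate that the
statistics detect planted coating effects under idealized sampling
noise — not that they are robust to contamination, batch effects or
confounded designs.

## Problem sizes used in validation

Null calibration uses 500 cohorts of 15 subjects per group and 30 taxa
at mean depth 10,000 (the rejection-rate tolerance is the binomial 95%
band around 0.05 for 500 draws, one cohort-level rate per draw), and
500 null Euclidean distance matrices of 20 samples with 199
permutations each, at which the permutation test's size is exactly
0.05. Recovery uses 20 cohorts of 20/group with 50 taxa at depth
30,000 (coating effects of 1.5 logits on 5 taxa) and 20 feature tables
of 40 features × 30 samples with 2-fold shifts on 3 minor-component
features. The end-to-end determinism check runs the full pipeline twice
on one 25-taxon, 2×8-subject cohort and compares output bytes.

## Known limitations

* Genus-level UniFrac requires a genus-level tree; the package computes
  UniFrac at whatever rank the supplied tree's leaves are, and
  aggregation to higher ranks is an explicit, separate step (summing
  counts over lineage prefixes) because re-classification cannot be
  reproduced from a count table alone.
* The index is undefined without a pseudocount when a taxon is absent
  from one fraction; results at very low depth are pseudocount-
  sensitive.
* PERMANOVA permutes labels freely; paired or stratified designs are
  not modelled.
* The discriminant cascade assumes exactly two classes past the class
  test; multi-class designs stop at the Kruskal–Wallis step.
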