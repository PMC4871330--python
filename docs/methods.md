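# Methods

This note documents the models, rules and numerical choices implemented in
`gaitwatch`, and what the synthetic cohort generator does and does not
emulate.

## Behavioural model and bout rules

The unit of observation is one cow-day of classified sensor output: a
contiguous posture track (lying vs upright, covering 86 400 s) plus a list
of stride events (start time, duration in ms, distance in cm), and hourly
noseband summaries (eating/ruminating times, chew and bolus counts).

Bout segmentation (`segmentation.py`):

* walking bout — maximal run of strides whose end-to-start gaps are ≤ 4 s,
  with ≥ 3 strides; bout extent = first stride start to last stride end.
  "Time between strides" is measured end-to-start, so two 1-s strides whose
  starts are 5 s apart still belong to one bout.
* lying bout — maximal lying period strictly > 50 s.
* standing bout — upright non-walking gap, > 50 s when the preceding state
  is lying and > 4 s when it is walking. The first period of the day has no
  preceding state and is treated as following lying (the stricter rule). A
  standing gap between a walking bout and a subsequent lying-down also
  counts when the duration rule holds.

All thresholds are strict inequalities; boundary-equal periods are not
bouts. Sub-threshold periods still credit their time to the state totals, so
lying + standing + walking time is conserved at 1440 min/day exactly (the
test suite asserts this to 1 s). Hourly summaries split state durations
across hour boundaries, attribute each bout to the hour containing its
start, and compute stride statistics over counted strides only.

## Aggregation

Daily values are sums of the 24 hourly values except for the four
weighted-mean variables (chews/min by ruminating time, chews/bolus by
boluses, stride duration and distance by strides), computed as
Σ(aₕxₕ)/Σ(xₕ); a day with all-zero weights yields a flagged missing value,
never a zero. Two-day averaged summaries take arithmetic means of sum
variables and re-weight the weighted variables across days by their daily
weights, which makes the result identical to the statistic over the pooled
raw events (asserted against a brute-force oracle). Derived variables
(walking speed = 10·distance/duration; lying bout duration =
lying time / lying bouts) are recomputed after every aggregation step, so
stored and recomputed values can never disagree.

Gait scoring: the mean of six half-point observer scores is rounded to the
nearest 0.5 with exact Fraction arithmetic; ties (x.25/x.75) round up,
matching the upward-rounding convention used for the body-condition score
in the same protocol. NRS ≤ 2 → group C; 2.5–3 → LI; 3.5 → LII; ≥ 4 → LIII;
lame ⇔ NRS ≥ 2.5.

Day/sensor selection: flagged days are discarded; a cow with < 2 clean days
is excluded; otherwise 2 days (and 1 of 2 accelerometers) are drawn
uniformly, seeded per cow id (CRC32 of the id mixed into the study seed), so
every "random" selection is individually reproducible and logged.

## Group statistics

Routing for the two-group comparisons follows a classical workflow the
original analysis toolchain implies but does not spell out: Shapiro-Wilk on
each group at α = 0.05 (both must pass), then an F-ratio test at α = 0.05
choosing between the equal-variance T-test and the Aspin-Welch test;
otherwise the Wilcoxon rank-sum test. The rank-sum p is exact (Mann-Whitney
enumeration) when min(n) ≤ 10 and the data are tie-free, else the
tie-corrected normal approximation with continuity correction. Four-group
comparisons use one-way ANOVA with Bonferroni-corrected pairwise T-tests on
the normal route and Kruskal-Wallis plus Dunn's rank Z tests with a
Bonferroni-corrected critical Z on the rank route. The compact letter
display assigns one letter per maximal clique of the non-significance graph,
so two groups share a letter iff their corrected pairwise test is
non-significant. IQR is Q3 − Q1 with linear-interpolation quantiles
throughout.

## Classification

Logistic models are maximum-likelihood fits (statsmodels); perfect or
quasi-perfect separation is flagged on the returned model, never silently
diverged. Odds ratios are reported per field-customary increments (30 min,
1000 chews, 10 boluses/bouts, 100 strides, 100 ms, 10 cm, 0.1 m/s). Both
McFadden and Nagelkerke pseudo-R² are attached because the original reports
do not name their variant.

ROC analysis uses the rank (Mann-Whitney) AUC with midranks (ties count ½),
candidate cutoffs at midpoints between consecutive distinct scores plus open
ends, classification "lame when score > cutoff" (ties land on the non-lame
side), and cutoff selection by maximal sensitivity + specificity with ties
resolved toward specificity. Univariable thresholds operate on the natural
variable scale with direction from the odds-ratio sign (OR < 1 → lame if
below). The published multivariable cutoffs (−0.06, 1.77, −2.08, …) are
linear-predictor values: their magnitudes are inconsistent with
probabilities, and both scales are monotone-equivalent for AUC.

Multivariable selection: candidates are the variables significant in the
two-group tests; admissible sets are the maximal cliques of the
compatibility graph with edges where pairwise Spearman |ρ| < 0.5; each
maximal set is backward-eliminated (drop the largest Wald p ≥ 0.05,
recording AUC before/after each removal) and the final model is the one with
the highest ROC AUC (ties: fewer variables, then candidate order). The
pre-elimination fit is returned alongside, since a retained non-significant
variable (eating time in the published three-variable model, Wald p ≈ 0.4)
can still be of practical interest.

## Synthetic cohort generator

The generator defines the study conditions; it is parameterised by per-group
means/SDs of the averaged 24-h summaries and defaults to the published
values for group C (n = 12) and the lame subgroups LI/LII/LIII
(n = 19/11/11). Thirteen variables are sampled as truncated normals at
physical bounds (times within [0, 1440] min, counts ≥ 0 and rounded, speeds
and durations > 0); the published medians sit close to the means, supporting
near-symmetric marginals. Optional Spearman constraints are imposed through
a Gaussian copula (ρ_gauss = 2·sin(πρ_s/6)); the default configuration needs
none because its dependences are structural:

* standing_bouts = lying_bouts + walking_bouts − skipped, with
  skipped ~ Binomial(lying_bouts, 0.14). A standing bout is opened after
  every walking bout and after every lying bout, minus the occasions a cow
  lies down within 4 s of walking; 0.14 is solved from the published group
  means (119.63 vs 9.79 + 111.17 in group C). This reproduces the published
  standing-bout means and SDs *and* the ρ ≈ 0.98 standing~walking bout
  correlation with no correlation parameter at all.
* walking_time = strides · stride_duration + (strides − walking_bouts) ·
  gap, with the mean inter-stride gap solved per group from the published
  means (0.56 s non-lame, 0.46 s lame) and jittered per day (SD 0.1 s).
  The published walking-time SDs (5.99 / 7.06 min) emerge to within
  0.1 min.
* standing_time closes the 1440-min budget; stride_distance =
  walking_speed · stride_duration / 10; lying_bout_duration =
  lying_time / lying_bouts.

The group-C stride-duration dispersion is set to 84 ms: the nominally
published value (0.84 s) contradicts both the published interquartile range
(0.14 s) and the published p-value for the group contrast, and is read as a
decimal slip.

Day-to-day within-cow variation is a free parameter (no published value):
each cow's latent mean carries SD σ·√(1 − f²/2) and each day adds N(0, (fσ)²)
noise with f = 0.2, so 2-day averages recover the published between-cow SDs
exactly. Subgroup means for walking bouts and walking speed are fixed at
values that average exactly to the pooled lame-group means and reflect the
published subgroup significance pattern (C ≈ LI for bout counts, C separated
from every lame subgroup for speed); within-subgroup SDs are shrunk so the
pooled lame-group SDs equal the published ones. Six observer scores per cow
are drawn around the subgroup's target NRS such that the rounded mean
reproduces it.

Event streams realise one day's targets exactly: equal lying bouts, walking
bouts spread round-robin over upright periods, strides equally spaced with
the gap solved from the walking-time target (generation fails loudly, naming
the violated constraint, when targets are infeasible — e.g. more walking
time than 4-s gaps allow). Segmenting a generated stream reproduces the
day's bout counts and times to rounding precision, which the round-trip
tests exploit. Halter hourly tables spread daily sums over jittered
near-uniform weights and recentre the weighted variables so daily weighted
means are exact.

What the generator does **not** emulate: raw acceleration waveforms;
diurnal activity rhythms (hourly weights are near-uniform); within-group
correlations beyond the structural ones (all other variable pairs are
independent by design); measurement disagreement between the two
accelerometers (both realise the same daily targets); oestrus behaviour
beyond a day-level flag. Consequently, passing tests demonstrate the
correctness of the pipeline's rules and the reproducibility of published
statistics *under the published moments with independent residuals* — not
performance on real herds.

## Population vs resubstitution metrics

The published confusion metrics were computed at cutoffs optimised on the
same 53 animals, which makes them optimistic relative to the population
value of the same statistic under the published group moments. Under the
moment model: frozen-model specificity ≈ Φ(...) ≈ 86–88% (published 91.7%,
i.e. 11/12), walking-speed sensitivity at 0.65 m/s ≈ Φ((0.65−0.54)/0.10) ≈
86% (published 92.7%), eating-time specificity at 297.4 min ≈
Φ((378.61−297.4)/71.40) ≈ 87% (published 100.0% — the published cutoff sits
below the minimum of only 12 non-lame values, an event with probability
≈ 0.2 under the moment model). The acceptance machinery reports the
population estimates as computed, on 20×-scaled cohorts averaged over three
replicates (problem size ≈ 3 160 cows), rather than tuning the generator to
the published small-sample values. The replicated model-selection experiment
likewise shows that with independent residuals the stride-statistic pairs
(which jointly encode walking speed) are selected more often than
{standing bouts, walking speed}; the published choice between the nearly
exchangeable standing- and walking-bout counts (univariable AUC 0.81 vs
0.82) was within-sample noise.

## Known limitations

No cross-validation or external validation (faithful to the original
design); no longitudinal change-point modelling; halter signal processing is
out of scope (halter summaries are accepted as given); the re-rating
workflow for observer disagreement > 1 point is a human procedure and not
modelled. Problem sizes in tests (500-cow moment checks, 500-seed selection
replication, 20×-scale metric estimation) were chosen as the smallest sizes
at which Monte-Carlo error is negligible relative to the tolerances checked.
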