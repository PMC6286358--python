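# Methods

## Word graphs and their attributes

A transcript is reduced to its surface word sequence: tokens are maximal
runs of Unicode letters/digits (internal apostrophes and hyphens kept by
default, splittable by option), case-folded, with no lemmatization or
stop-word removal. The word graph is the directed multigraph with one node
per unique word and one edge instance per consecutive word pair, direction
preserved; immediate repetitions are self-loops. For a sequence of L tokens
the total edge multiplicity is exactly L − 1.

Four attributes summarise a graph:

- **N** — number of nodes; lexical diversity.
- **RE** — repeated edges: the sum of edge instances over ordered node
  pairs connected more than once. A pair of multiplicity m ≥ 2 contributes
  m; pairs seen once contribute 0. Under this reading a 30-word window of
  one repeated word attains RE = 29, the combinatorial ceiling of edge
  instances in a full window. The alternative "excess" reading (m − 1 per
  pair, ceiling 28) is available as `re_mode="excess"`.
- **LSC** — node count of the largest strongly connected component of the
  directed graph, multiplicities ignored. Long-range recurrence: words that
  recur across distant contexts knit mutually reachable sets.
- **ASP** — mean shortest directed path over ordered node pairs (u, v),
  u ≠ v, for which a path exists. Unreachable pairs are excluded rather
  than given an infinite or imputed distance: speech graphs, especially
  children's, are rarely strongly connected, and excluding infinite pairs
  keeps the statistic defined for every graph with at least one reachable
  pair. A graph with none has ASP 0 by convention (warned). Self-loops
  never enter ASP. An undirected variant (`asp_mode="undirected"`) is
  provided; the directed-excluding convention is the default and the one
  all defaults and tests use.

LSC comes from networkx's strongly-connected-components; ASP uses an
in-module breadth-first search over the successor sets because the shuffle
normalization calls it hundreds of thousands of times per cohort and
per-call graph-object construction dominates otherwise. The BFS is checked
exactly against networkx's all-pairs shortest path lengths in the test
suite, along with a brute-force transitive-closure oracle for LSC.

## Windowing

Attributes are computed on moving windows of 30 words advancing 15 words
(50% overlap) and averaged per subject, so verbosity differences change
the number of windows, not the scale of the attributes. Only full windows
are used; a transcript shorter than one window contributes a single short
window and is flagged. Window length 30 and step 15 are the defaults
throughout and the bounds 30 (nodes) / 29 (edge instances) used by the
model fit derive from them.

## Shuffle normalization

To measure distance from random word order, each window is shuffled
(uniform permutation of its tokens) 100 times; graphs are rebuilt, each
attribute averaged over shuffles, and the observed value divided by that
average. The ratio is taken per window and then averaged across windows
(the per-subject-average alternative is `order="pooled"`; the two coincide
for single-window transcripts). Because permutation preserves the word
multiset, the node set of every shuffled window equals the observed one
and normalized N is exactly 1 — an identity the tests assert across a full
synthetic cohort, and a useful canary for implementation errors.

Windows whose shuffled-mean denominator is zero for an attribute (e.g. RE
on an all-distinct window: no permutation can repeat a pair) are skipped
for that attribute and counted, rather than regularised with a
pseudo-count that would bias small ratios. Randomness is driven by one
master seed; each subject's stream is derived from (seed, CRC32 of the
subject id), so results are independent of cohort iteration order.

## Maturation model

Attribute maturation over years t of age or education is modelled as

    f(t) = f0 + (f_inf − f0) (1 − e^(−t/T)),

the solution of df/dt = (f_inf − f)/T with f(0) = f0. T is the
characteristic time in years: the age/education at which 1 − 1/e ≈ 63% of
the total change |f_inf − f0| has accrued. The dynamic range |f_inf − f0|
is the model's contrast of interest: large under typical maturation
(f_inf > f0 for N, LSC, ASP; f0 > f_inf for RE), near zero when structure
does not change.

Fitting: subject values are binned at floor(t) integer years; bin means
are fit by bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method `trf`) with residuals weighted by
1/SEM (so squared residuals carry inverse-variance weights 1/SEM²;
`weight_mode` exposes 1/SEM and unweighted variants). Box constraints:
f0, f_inf ∈ [0, 30] for node-counted attributes (N, LSC), [0, 29] for
edge-counted ones (RE, ASP), T ∈ (0, 30] years (lower bound 10⁻⁹
numerically). Start points: f_inf at the maximum observed bin mean, f0 at
the minimum, T at 12 years. Because the three-parameter exponential is
multimodal under noise, the optimizer also runs from a start with f0 and
f_inf swapped (essential for decreasing attributes) and from ten jittered
starts drawn from a fixed internal stream; the lowest-cost solution wins,
stopping early on an essentially perfect fit. Single-subject bins have no
SEM; they are retained with the largest SEM observed among multi-subject
bins — the weakest finite weight — rather than dropped, which keeps sparse
old-age bins in the fit without giving them infinite influence. If no bin
has a defined positive SEM the fit is unweighted.

Goodness of fit is reported on the unweighted bin means: R² = 1 − SSE/SST
(defined as 0 for a constant series, which has no explainable variance),
SSE, and RMSE = √(SSE/bins); the weighted SSE is kept alongside. At least
4 bins are required (3 parameters + 1 degree of freedom).

The temporal-order null (`permute_time`) shuffles the time labels across
subjects, re-runs the identical analysis per surrogate (subject-level
Spearman rho; binned-level fit R², with 2 restarts to keep 1000 surrogates
affordable), and reports add-one empirical p-values: two-sided on |rho|,
one-sided on R².

## Statistical battery

- Spearman rho with midrank ties, two-sided p via the t approximation
  (standard at these sample sizes); an exact permutation variant is
  available.
- Partial Spearman: all three vectors midranked, first-order partial
  correlation r_xy·z on the ranks, t test on n − 3 degrees of freedom. A
  constant covariate degrades gracefully to the plain Spearman; rank
  collinearity (|r_xz| or |r_yz| = 1, detected at 10⁻¹² of the determinant)
  is an error. The implementation is cross-checked against
  pingouin.partial_corr to 10⁻¹⁰ in the tests.
- Multiple regression: OLS attribute ~ intercept + age + education via
  statsmodels; reports R², overall F-test p, both slopes and their
  difference (education − age).
- Group tests: Kruskal-Wallis (tie-corrected) across groups, then
  two-tailed Wilcoxon rank-sum per requested pair — exact when both
  groups have ≤ 10 untied observations, otherwise the normal approximation
  with tie and continuity corrections. The reported statistic is the rank
  sum W of the first group.
- Distribution checks: per-group one-sample KS against a normal with the
  group's estimated moments — explicitly flagged approximate (estimated
  parameters make it conservative), used as a screen motivating the
  nonparametric battery, not as a calibrated test — plus Levene's
  homogeneity test (mean center by default, median = Brown-Forsythe as
  option).
- Proportions: 2×2 chi-square without continuity correction by default
  (Yates optional).
- Bonferroni: alpha/m kept exact for decisions, rounded to 4 decimals for
  reporting (0.05/8 → 0.0063, 0.05/4 → 0.0125, 0.05/6 → 0.0083).

Calibration of every test (type-I error within three binomial standard
errors of nominal α over 1000 null replicates) is asserted in the
acceptance tests; the KS check there uses a fully specified null, since
the estimated-moment screen is by construction not calibrated.

## Synthetic cohort generator

Real transcripts of this kind are not publicly distributable, so the
pipeline is exercised end to end on a generator whose dials map one-to-one
onto the recurrence axes the attributes measure. Each token is drawn by a
three-way mixture:

- `theta_new`: emit a previously unseen word, drawn from a Zipf-ranked
  unbounded pool (exponent 1.5) — drives N;
- `theta_persev`: re-emit the successor of the current word's previous
  occurrence, replaying bigrams — drives RE;
- `theta_return`: jump to a uniformly chosen earlier word, closing long
  loops — drives LSC;
- residual mass: re-emit one of the last 5 tokens.

A mixture rather than a fitted language model keeps the dials independent
and interpretable and needs no training data; monotone dial→attribute
links are verified by simulation sweeps in the tests.

Cohorts default to 135 controls and 65 psychosis-like subjects, ages
uniform on [2, 58] years. Education is age minus a schooling start of 6
years (floored at 0, capped at 18); subjects drawn as school dropouts
(probability 0.28 for controls, 0.62 for the psychosis group) have it
truncated uniformly. Control dials follow the maturation curve in
*education* years — the generative claim under test is that education, not
age per se, drives structural maturation — with defaults
(f0, f_inf, T) = (0.15, 0.55, 2.0) for novelty, (0.50, 0.08, 1.5) for
perseveration (fast early dynamics) and (0.04, 0.22, 9.0) for return
(slow, adolescent-scale dynamics), plus Gaussian jitter (sd 0.02) and
renormalization into a valid mixture. Psychosis-like dials stay at the
child-like f0 level at every age and education. Transcript length defaults
to 300 tokens (≈ 19 full windows); cohort-scale tests that hammer the
shuffle normalization use 150-token transcripts (9 windows), which leaves
every exact identity unchanged while keeping hundreds of thousands of
graph constructions affordable.

What the generator does **not** emulate: syntax, semantics, realistic
vocabulary, age-dependent verbosity, medication or symptom effects on
speech, or the attribute magnitudes of any real cohort. Passing tests
therefore demonstrate that the pipeline recovers the structure it is
pointed at — sign patterns, parameter recovery, null calibration — not
that any real population behaves this way.

## Known limitations

- RE's definition admits two readings; both are implemented but results
  switch with `re_mode`.
- ASP's unreachable-pair convention is a dialect choice; comparisons with
  software using a different convention require matching modes.
- The estimated-moment KS screen is not a calibrated normality test
  (Lilliefors-type bias); it is labelled approximate in its output.
- The exponential fit's R² on few, unevenly filled bins can be unstable;
  the permutation null is the more robust evidence of temporal structure.
- The generator's dials interact mildly through the mixture constraint
  (renormalization when the jittered sum exceeds 1), so extreme parameter
  combinations compress each other.
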