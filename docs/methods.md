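# Methods

This note documents the models behind `socialnull`: what each permutation
null holds fixed, how the synthetic scenarios are generated, which numerical
and design choices were open and how they were settled, and what the bundled
tests do and do not establish about real data.

## Networks from observations

All three observation modes reduce to a **group-by-individual (GBI) matrix**:
a binary K x N matrix with one row per sampling event and one column per
individual. Under the gambit of the group, everyone recorded in the same
event is taken to be associating.

* Group sightings are GBI rows directly.
* A focal sample (focal individual + recorded associates) becomes a row whose
  members are the focal and its associates.
* Discretised trajectories produce one event per (day, step, occupied grid
  cell): individuals in the same cell at the same step form a group. A
  Chebyshev co-occurrence radius > 0 merges near-adjacent cells by single
  linkage; the default radius is 0 (same cell), the minimal rule for a grid
  world.

Edge weights are the **simple ratio index**, SRI(i,j) = x / (x + y_i + y_j),
with x the number of events containing both individuals and y_i, y_j those
containing only one of them. Each GBI row is a single sighting event, so
"seen but not associated" cannot occur within a row and the denominator is
simply the number of events containing i or j. The index estimates the
proportion of time a dyad associates under even sampling; 0/0 is defined as
0. Raw co-occurrence counts are available as an alternative weight. The
choice of index does not interact with the choice of null model, because
null networks are always rebuilt with the same index.

The node-level test statistic throughout is the OLS **slope** of a node value
(weighted degree/strength by default) on a node attribute (sex by default,
binary attributes coded 0/1 with the alphabetically first level as
reference, so `sex` slopes are male effects). Slopes describe the data; t or
Z statistics measure departure from a parametric null that permutation
testing replaces, so they make poor permutation statistics. Network-level
hypotheses use the metric itself (mean degree, mean strength, density,
coefficient of variation of edge weights).

Median binarisation (used when a binary network is required) keeps edges
strictly above the median of the *nonzero* edge weights; with all weights
tied, every edge is removed. This pins down tie behaviour, which "keep the
top 50% of edges" alone does not.

## Permutation null models

**Node permutation.** All attribute vectors are jointly reassigned by one
uniform permutation; the network and each node's `n_observations` (a
property of sampling, not phenotype) stay fixed. Tests whether phenotypes
map non-randomly onto network positions. The restricted variant permutes
within classes of a grouping label (e.g. trapping site), preserving spatial
composition.

**Edge permutation.** The multiset of nonzero edge weights is reassigned to
dyads drawn uniformly without replacement; edge count and weight
distribution are exact invariants.

**Data-stream (checkerboard) permutation.** A 2x2 submatrix with pattern
(1,0 / 0,1) is drawn and flipped, moving one observation of individual i
from event a to event b and one of j the other way. Row sums (group sizes)
and column sums (per-individual observation counts) are exact invariants.
Swaps can be restricted to events sharing a day, period or location, and to
individuals sharing a phenotype. Candidates are found by rejection sampling
(uniform draws of (i,j,a,b), default budget 10,000 attempts per swap), which
is unbiased among candidate patterns and fast on sparse matrices; the
stationary distribution of the resulting chain over matrices is that of the
classical swap algorithm, not the exactly uniform fixed-margin law (exact
samplers such as trial-swap or curveball are out of scope). If the budget is
exhausted the step records the unchanged statistic and a counter, never
looping silently.

**Focal swap.** Two samples with different focals are drawn; one associate
from each is exchanged, provided the two focals and the two associates are
four distinct individuals and neither associate already occurs in the
destination sample (including as its focal). Per-sample associate counts and
per-individual appearance totals are exact invariants. `within_class`
restrictions apply to the two focal individuals, optionally also to the
swapped associates.

**Trajectory day-shuffle.** Each individual's day labels are permuted
*within that individual*: every animal keeps exactly its own multiset of
daily tracks — its space use and its missingness pattern — while the
temporal alignment between individuals is randomised. This is the
recommended null for autocorrelated movement data.

**Track-identity swap (contrast method).** Within each day, that day's
tracks are reassigned among individuals. The day-level track set is
preserved but an individual's own data are not: whole chunks of data move
between animals, which makes this null a node permutation in disguise. It is
implemented to demonstrate that failure mode, not for use.

### Serial vs independent chains

Data-stream and focal swaps are cumulative Markov chains: the data are
incrementally randomised, `swaps_per_step` swaps per recorded statistic
after `burn_in` unrecorded swaps. Node, edge, day-shuffle and identity-swap
statistics are independent redraws from the original data. The default
`burn_in` is 0 and `swaps_per_step` is 1 — the runner imposes no hidden
burn-in; instead, inspect the stabilisation series (null statistic and
running p against permutation number) and choose spacing explicitly.

Mixing matters for serial chains in two ways. For *detection* it suffices
that the chain reaches stationarity within the run (the demonstrations here
use burn_in = 1000 and 10 swaps per recorded statistic on a 200 x 50 GBI
with ~1300 occurrences). For *calibrated p-values under a true null* the
recorded statistics must also be approximately exchangeable with the
observed one, which requires near-independent records: with short spacing
the null series is strongly autocorrelated, the empirical p is noisy, and
the type-I error inflates well above nominal. The baseline calibration runs
therefore use burn_in = 2000 and 100 swaps between records, which brings the
rejection rate at alpha = 0.05 to the nominal level on this problem size.
These are properties of chain configuration, not of the data; the
stabilisation diagnostics exist precisely so users can check them.

### P-values

p_upper is the proportion of null statistics >= the observed one, p_lower
the proportion <= it (ties fall in both tails, conservatively), and the
two-tailed value is twice the smaller proportion, clamped at 1: 2.5% of null
values beyond the observed statistic in either direction marks P = 0.05.
Statistics that are non-finite on a permuted dataset are recorded as missing
and excluded from the denominators, with a count reported.

## Dyadic regression (QAP / MRQAP)

Observations are unordered dyads (the upper triangle; the networks here are
symmetric, so using each dyad once avoids double counting). Three
permutation schemes share one OLS estimator:

* **QAP (dependent-network permutation):** simultaneous row/column
  permutations of the dependent matrix generate the null slopes.
* **MRQAP-DSP (double semi-partialing):** each predictor is residualised on
  the remaining predictors by dyadic OLS; the symmetric residual matrix is
  node-permuted and substituted into the model, and the permuted-residual
  coefficient forms the null for that predictor. Estimation is unchanged —
  only inference differs — and with one predictor the scheme reduces
  statistically to QAP. The double-semi-partialing literature fixes the idea
  but not every detail; the implementation here residualises with an intercept and
  permutes the residual matrix rows/columns simultaneously.
* **Custom null:** the same model refitted on any caller-supplied ensemble
  of null networks — in particular networks recorded along a data-stream
  chain (`datastream_null_networks`), which is how pre-network permutation
  plugs into dyadic regression.

Sex-category predictors code dyads 1 = both males, 2 = male-female, 3 = both
females and enter as a single numeric variable (an option expands them to
indicators), mirroring the single-slope sex-similarity test. Note the
direction this coding implies: when female-female edges are stronger than
the sampling-conditioned null, the observed coefficient falls *above* the
null distribution (the proportion of null slopes below the observed one
approaches 1). The node-level mirror image — the male-effect slope on
strength falling *below* its null — is the same finding on the other scale.

**Two-network comparison** uses metric(A) - metric(B) as the statistic and
randomises both datasets simultaneously, one swap in each per chain step, so
the null difference distribution reflects both sampling designs.

## Synthetic scenarios

All generators are seed-deterministic, export their full specification, and
exist so that every null model, and the headline type-I/type-II
demonstrations, run with no external data.

### Group and focal scenario

The biological premise: females truly have stronger bonds, and an
observation bias then hides this. The mechanism is a latent event-type
model. A fraction f of events (default 0.5) are *social events*; males
attend any event with probability p_base = mean_group_size / n_individuals
(default 7.5/50 = 0.15), while females attend social events with
p_hi = p_base (1+e)/(1+fe) and ordinary events with p_lo = p_base/(1+fe),
where e is `female_sociality_effect` (default 2.0). Female *marginal*
attendance equals the male rate, but because many females choose the same
social events, female-female dyads co-occur in excess of the product of
their attendance rates: females have genuinely stronger bonds at equal
observation effort.

The crucial property of this mechanism is that the excess co-occurrence
lives beyond the GBI's row and column margins. A generator in which females
are merely more gregarious (higher independent per-event attendance) puts
*all* of its structure into the margins: conditional on the margins such a
matrix is uniform over the fixed-margin class, so a checkerboard-swap null
has exactly zero power against it, and no bias demonstration is possible.
Event-level co-attendance is what the margin-conditioned null can see.

The observation bias deletes each 1-cell of a female with probability
`bias_fraction` (default 0.2) — the animal was present but unrecorded —
and drops emptied events. Defaults were fixed from the first-order
cancellation condition: with f = 0.5, e = 2.0, p_base = 0.15 and 20% female
loss, the expected post-bias female-female SRI equals the male-male SRI
(~0.081), so observed female and male strengths are equal in expectation and
the raw sex difference vanishes — while the within-event concentration
survives thinning and remains visible to the data-stream null. At these
defaults, across replicates: the true data show females ~15% stronger; the
naive OLS and node-permutation tests on the biased data are non-significant
(the type-II trap); and the data-stream test rejects at P < 0.01 with the
observed male-effect slope in the lower tail, its null series stabilising at
clearly positive values (females were recorded less often, so
count-conditioned null networks make males look stronger).

The focal variant rotates focals in shuffled rounds (every individual is
focal at least once when samples >= individuals); associates join with the
group scenario's probabilities, with the social-event boost applying to
female associates of female focals. The bias deletes female *associate*
records only — the follow itself happened. Events carry a sampling-period
index (blocks of 10 consecutive events) usable by time-restricted swaps.

### GPS scenario

Individuals move on a bounded grid, one step per time unit within their
clipped Moore neighbourhood (staying put allowed), updating simultaneously
against previous-step occupancy. Males weight all options equally; females
weight a cell `attraction_multiplier` (default 5) times higher if it held at
least one other individual at the previous step. Each day starts from fresh
uniform positions, so daily tracks are self-contained — the unit the
day-shuffle null permutes. The bias deletes each female (day, step) point
with probability 0.2 after the movement is simulated (observation, not
behaviour).

The default arena (4 x 4 grid, 20 individuals, 8 days x 40 steps) is a
coarse discretisation of a heavily shared area — think a refuge site —
chosen so that random spatial overlap produces substantial co-occurrence.
This is the regime in which confusing spatial overlap with sociality is most
dangerous, and in which the observation bias masks the female attraction
from any null blind to per-individual sampling: at these densities the 5x
attraction weight nearly saturates (most neighbouring cells hold someone),
so the bias deficit offsets the attraction excess in raw strength, the
identity-swap null typically fails to reject, and the day-shuffle null —
whose null distribution is centred on the positive male-effect slope implied
by the females' thinner sampling — detects the attraction in >= 80% of
replicates. In sparse arenas the attraction excess dominates instead and
*every* null detects it, which demonstrates nothing about null-model choice.

### What the generators do not emulate

Real data have unequal sampling effort across sites and seasons, group
detection that depends on group size, spatial structure in group scenarios
(events have no locations unless supplied), demographic turnover, and
movement with home-range fidelity across days (daily tracks here restart at
random positions, which slightly flatters the day-shuffle null's assumption
of exchangeable days). Passing tests show that each method behaves as
designed under its own assumptions — conservation laws hold exactly,
calibration holds under a true null, and the documented bias produces the
documented error patterns — not that any particular field dataset satisfies
those assumptions.

## Numerical and interface choices

* Hot-loop slopes use closed-form least squares; the user-facing `ols_fit`
  uses statsmodels and reports the parametric ("naive") p-value for
  contrast. QAP observed coefficients are computed with the same
  pseudo-inverse as the null fits so that degenerate ensembles produce exact
  ties (and p = 1) rather than floating-point noise.
* A single seeded `numpy` Generator drives each run; identical seed and
  configuration reproduce results bit for bit.
* Empty GBI events are illegal (a recorded group has a member); generators
  redraw empty events, and the bias drops emptied ones.
* Trajectory containers allow missing points (sentinel -1) so that thinned
  observations travel with their daily track under day-shuffling; the file
  reader is strict by default and accepts gaps only with `allow_missing`.
* Degenerate chains (no legal swap within the attempt budget) record the
  unchanged statistic and a diagnostic count.
* CSV dialects (headers, `;`-separated associates, 1-based days/steps in
  files) are this package's own conventions, documented in `socialnull.io`.

## Problem sizes used by the bundled checks

The demonstration suite runs the group scenario at its default size
(50 individuals, 200 events) with 1000 recorded permutations (10 swaps
apart, burn-in 1000), 20 replicates; baseline calibration at 200 replicates
with 200 recorded permutations (100 swaps apart, burn-in 2000); the GPS
scenario at its default size with 500 recorded permutations and 20
replicates; and MRQAP consistency checks at 1000 permutations with 500
custom-null networks. These sizes give Monte-Carlo resolution comfortably
finer than the thresholds being checked while keeping the full suite fast.

## Known limitations

* The checkerboard chain's stationary law is the classical one, not exactly
  uniform over fixed-margin matrices; on the sparse matrices used here the
  discrepancy is not measurable in the calibration tests, but exact
  uniformity would require trial-swap/curveball samplers.
* Serial-chain p-values are only as good as the chain's mixing; the package
  reports stabilisation series rather than guessing a burn-in.
* Dyadic regressions assume symmetric networks (undirected associations);
  directed interaction networks are out of scope.
* ERGM fitting, Bayesian edge models and mixed-effects node models are out
  of scope; the slope statistic contract covers what the permutation
  framework needs.
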