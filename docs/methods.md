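# Methods

`flocknet` implements the analysis chain for a feeder-access manipulation
experiment on a wild, PIT-tagged songbird population, together with a
generative model of the experiment that makes every inference stage
verifiable without field data. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
tests do and do not demonstrate.

## The experiment being modelled

A population of tagged birds forages at automated feeder stations that
log every antenna read. After an acclimation period, each feeder site is
replaced by a pair of selective feeders: one opens only for tags ending
in an odd digit, the other only for even digits, splitting the
population into two arbitrary, socially meaningless classes. After a
long exposure the restriction is lifted for a short post period. Two
further contexts are recorded without any restriction: short-lived
ephemeral food patches and RFID loggers on nest-box entrance holes
during breeding-territory prospecting. The analysis asks (i) whether the
imposed segregation appears in the foraging network, (ii) whether it
carries over into the unmanipulated contexts, (iii) whether it is driven
by social association rather than shared space, and (iv) how the network
recovers when the constraint is removed.

## Inference chain

**Gathering events.** Feeder and patch detections arrive in bursts as
flocks come in to feed. Per location and calendar day (days are 86,400-s
half-open windows from scenario start), a one-dimensional Gaussian
mixture is fitted to detection timestamps. The mixture order K is chosen
by BIC over K = 1..K_max, stopping once BIC has not improved for 3
consecutive orders; a variational alternative (Bayesian mixture at K_max
with empty components pruned) is available behind the same interface.
K_max is capped at half the number of reads — a component supported by a
single read is not separable, and allowing K equal to the sample size
makes the variational fit collapse. Each detection is assigned to its
maximum-responsibility component (ties to the earlier-mean component);
components whose detection-time intervals overlap by more than 80% of
the shorter interval are merged. EM is initialised k-means++ on
timestamps with a seed derived from (location, day) via CRC-32, with 3
restarts — 1-D mixtures initialised this way converge to near-identical
optima, so more restarts buy nothing measurable. Because the seed
depends only on (location, day) and inputs are sorted before fitting,
the partition is invariant to input record order. Nest-box streams skip
the mixture: a group is simply the set of distinct individuals detected
on one box during one day, since box visits are sparse (≈1.7 visitors
per box-day) and spread over hours.

**Networks.** Events become a K×N group-by-individual matrix (repeat
reads of a tag within an event count once for membership). Dyadic
association uses the half-weight index, HWI = x / (x + (yA + yB)/2) =
2x / (nA + nB), where x counts events containing both individuals and
nA, nB the events containing each. Each gathering event is its own
sampling unit, so the general index's "both seen apart in the same
period" term is structurally zero. Individuals with no events in a
window are dropped from that window's roster rather than kept as
isolates; rosters are ordered lexicographically by tag everywhere.
Time-windowed networks partition each period into consecutive windows
from the period boundary (trailing partial windows included). Matrix
comparisons are restricted to the sorted common roster (minimum 3
shared individuals).

**Assortment.** With e_ij the fraction of total edge weight joining
type-i to type-j ends (each dyad contributes half its weight to each
ordered end) and a_i = Σ_j e_ij, the weighted discrete assortativity is
r = (Σ_i e_ii − Σ_i a_i²)/(1 − Σ_i a_i²). A perfectly segregated network
scores exactly 1; a network in which a single type carries all weight
leaves r undefined and is reported as NaN, excluded from summaries. The
standard error is an edge jackknife: se² = Σ_m (r₍₋ₘ₎ − r)² over all
nonzero dyads, r₍₋ₘ₎ computed with dyad m's weight zeroed. Significance
comes from a node-permutation null: type labels are shuffled across
nodes (equivalently, rows and columns are jointly permuted), preserving
the weight multiset, each node's weighted degree and the type counts.
The null is summarised by its empirical 2.5/97.5 percentiles (linear
interpolation, matching the vertical-bar presentation of permutation
ranges) and an add-one Monte-Carlo p-value, two-tailed by default with a
one-tailed option — the add-one estimator never returns exactly zero.

**Matrix comparisons.** The Mantel statistic is the Pearson correlation
of the strictly-lower-triangle vectors of two aligned symmetric
matrices; its p-value comes from joint row/column permutations of the
second matrix (add-one, two-tailed). The 95% interval is an
individual-level bootstrap — nodes resampled with replacement, both
matrices re-indexed, self-pairs of duplicated nodes masked, percentile
limits — an interpretation chosen because a "95% range" on a Mantel
statistic is not otherwise standardised. MRQAP with double
semi-partialing regresses the dependent triangle on predictor triangles
by OLS with intercept (coefficients reported unstandardised); for each
predictor the residual of that predictor on the others is permuted as a
matrix and substituted back, and the permuted |β| distribution gives the
add-one two-tailed p. Raw-coefficient nulls are used rather than pivotal
t-statistics. Collinear predictors are rejected with the offender named.
Diagonals are always excluded; missing dyads are not supported because
alignment guarantees complete matrices.

## The generative model

The simulator emulates the study design at configurable scale: default
339 individuals, 6 sites, 40/90/6-day periods, 50 events/site/day, mean
flock size 3.8, mean event duration 191 s, ≈1.7 nest-box visitors per
box-day. Each bird holds 1–3 home sites, contiguous on the ring of
sites (spatial locality).

**Flocks.** Events per site and day are Poisson; event times are uniform
within the day; durations gamma-distributed (shape 4) around the mean;
flock size is 1 + Poisson(mean − 1), so the configured mean is exact.
Composition is sequential recruitment from the site's current residents:
a uniform seed bird, then candidates weighted multiplicatively by
1 + s·P[c, m] for every already-recruited member m, where P is the
latent preference matrix and s the preference strength.

**Preference dynamics.** P is updated daily toward the day's realised
co-membership counts (row-normalised, symmetrised) by exponential
smoothing: P′ = (1−ρ)P + ρC. Only granted feeder co-foraging updates P —
denied reads record presence, not foraging. With ρ = 0.7/day the
preference memory is short (≈1.4 days): it carries currently-enforced
segregation into simultaneous unmanipulated contexts, and lets imposed
structure dissolve within days of the restriction lifting — matching the
immediate recovery the experimental design is built to detect.

**Slow drift.** A single fast preference matrix cannot also produce the
gradual, weeks-scale drift of network structure (each window more
similar to the post state than the last). That drift is generated by a
second, parity-neutral process: home-range turnover. Each day each bird
swaps, with probability 0.05, one home site for a ring neighbour.
Because this never references tag parity it cannot create or destroy
assortment, but it makes temporally closer windows structurally more
similar — the observed monotone approach of during-period networks to
the post reference. An earlier design iteration used a second, slow
preference matrix instead; it was rejected because any preference
component slow enough to drive drift accumulates parity polarisation
during the manipulation and falsely re-creates assortment after it ends.

**Manipulation mechanics.** During the manipulation each site's events
are split between its odd-only and even-only feeder (rate halved each).
Granted members are recruited from the matching-parity residents; with
probability 0.1 per granted member, a mismatched-parity bird follows its
flock-mates to the wrong feeder and is logged with access_granted=false
(the antenna records all visits; the feeder simply does not open). A
configurable learning lag (default 0) raises that probability to 0.5
while birds have not yet learned which feeder admits them. By
construction the granted membership of any restricted-feeder event is
single-parity — the access rule is absolute.

**Unmanipulated contexts.** Patches are 4 short-lived locations anchored
at random sites, with burst events and the same recruitment rule, no
restriction. Nest-box visitor sets are sampled per box-day
(1 + Poisson(0.7) visitors when occupied) with the same
preference-weighted joint-visit rule but a larger strength (60 vs 6):
joint prospecting at a specific box is a tie-driven pair activity, while
feeder flocks are open aggregations at a resource — with only ~2 birds
per box-day, a single multiplicative factor must carry the whole social
signal. Context simulations consume daily preference snapshots from the
feeder timeline, so carried-over and dissolving structure is expressed
faithfully; their random streams are separate, so adding a context never
perturbs another's draws.

**Calibration.** Generator constants not fixed by the study design
(preference strength 6, update rate 0.7/day, nest-box strength 60,
denied-visit rate 0.1, site-switch rate 0.05/day) were chosen once,
during generator development, so that the simulator exhibits the
qualitative behaviour the experiment documents — no pre-period
assortment, strong imposed assortment, carry-over in simultaneous
contexts, immediate post recovery, gradual structural drift — and then
frozen. They are not fitted to any quantitative field value.

## Scales used in tests and analyses

The bundled analyses and the test suite run a desk-scale scenario
preserving the design: 100 individuals, 6 sites, 10/20/6-day periods,
12 events/site/day, one pre and two during patch deployments, 12 nest
boxes over the final 6 manipulation days plus the post period, 1,000
permutations. The drift analysis uses a leaner feeder-only scenario (60
individuals, 4 sites, 6/18/6 days) replicated over 20 seeds. These sizes
keep a complete simulate–detect–analyse cycle in minutes while leaving
every qualitative signature detectable.

## Known limitations

* Residual carry-over can make the post-period nest-box network weakly
  assorted in a minority of replicates — the preference snapshot on the
  first post days is still polarised. The real system's recovery is, if
  anything, faster than the generator's.
* The generator has no species structure, no energetics or breeding
  outcomes, and no explicit movement between detections; spatial
  structure is entirely site-membership.
* Denied visits are included in network construction by default (the
  antennas record all visits; whether the original analysis included
  them is not documented) — a switch excludes them.
* Mixture segmentation is per location-day, which bounds K and makes
  partitions reproducible, but cannot represent events spanning
  midnight; the generator draws event start times within the day, so
  boundary effects are limited to rare tail reads.
* The bootstrap CI for the Mantel statistic and the add-one two-tailed
  permutation p-values are reasoned choices where the field has no
  single convention; one-tailed alternatives are available.

Passing the synthetic tests shows the chain recovers imposed structure,
calibrated null behaviour and known coefficients under the generator's
assumptions (Poisson bursts, multiplicative recruitment, site-based
space use). It does not validate those assumptions against real
foraging data.
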