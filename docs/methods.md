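# Methods

This note documents the models, conventions and numerical choices behind
`polyethnet`, and what the synthetic-data tests do and do not demonstrate.

## Data model

One observation is a scan sample: at a fixed time slot (hours 0, 3, …, 21;
8 per day) each ant is assigned exactly one behaviour from the closed
vocabulary {walking, inactive, egg_care, larva_care, pupa_care, foraging}
over a 3-day window. Missing scans (lost tags, out-of-view ants) are simply
absent rows; nothing is imputed, so an ant's margin can be below
8 × n_days. Duplicate (ant, day, slot) rows and out-of-vocabulary labels are
hard errors at read time.

The bipartite network has ants as rows and behaviour-nodes as columns under
one of three column schemes:

* `behaviour_by_day` (default, the unit of the main analysis): behaviour ×
  observation day, cell weight ≤ 8;
* `behaviour_aggregate`: behaviour only, weight ≤ 8 × n_days (24 for the
  standard design) — used for summary/plot exports;
* `behaviour_by_period`: behaviour × {daytime, nighttime} with daytime =
  slots 9–18 and nighttime = slots 21–6, aggregating days.

All-zero rows and columns are pruned (and logged) before any network
statistic: modularity, nestedness and the specialization scores are
ill-defined on empty margins. The queen is an ordinary row by default; an
`exclude_queen` flag removes her records first, since whether reproductives
belong in a worker task-allocation network is a question for the analyst,
not the package.

## Modularity

Weighted bipartite modularity of a partition assigning module labels g to
rows and h to columns:

    Q_W = (1/M) Σ_i Σ_j (A_ij − y_i z_j / M) · [g_i = h_j]

with margins y, z and total weight M. Maximization is a two-stage search in
the LPAwb+ style:

1. **Label propagation.** Given column labels, each row's contribution is
   separable, so reassigning every row to its best column-module (the label
   maximizing Σ_{j in module} (A_ij − y_i z_j/M)) can only increase Q_W;
   likewise for columns given rows. A node whose best attainable
   contribution is negative gets a fresh singleton label (contribution 0).
   Sweeps alternate until Q_W stops increasing — the alternating update is
   monotone, which the test suite asserts.
2. **Agglomeration.** Module pairs are merged greedily while the merge gain
   (the cross-module weight-above-expectation in both directions) is
   positive, then stage 1 reruns; the loop ends when neither stage improves.

The DIRT-style wrapper restarts this search from random initial label
counts (2 … min(r, s), uniform assignment), plus one restart with every row
its own module. Defaults: 20 restarts for an empirical network, 2 per null
replicate (cost control; both configurable). Tie-breaks are uniform under a
seeded generator; null-replicate seeds are spawned from the root seed via
NumPy SeedSequence so results do not depend on execution order. On all small
matrices where exhaustive enumeration of every joint row/column partition is
feasible (≤ 4×4), the search attains the global optimum in the test suite.

**Normalization.** Q_W is divided by the maximum attainable under perfect
module separation with the same margins and total weight. Concentrating each
row's weight inside its own module makes the within-module weight sum to M
regardless of how it is spread, so the idealized maximum reduces to
Q_max = 1 − Σ_{within} y_i z_j / M². Q_norm = Q_W / Q_max is clipped to
[0, 1] and defined as 0 for a single module. (The reference normalization is
described only as "the possible network configuration with the same total
weight"; this closed form is the package's reading of that idealization and
reproduces the required extremes: 1 for block-diagonal networks with their
block partition, 0 for one module.)

**Significance.** 1000 (default) Patefield draws with the empirical margins;
each is re-maximized and p = (1 + #{null ≥ observed}) / (1 + n_null). The
add-one rule avoids p = 0 and ties count against significance; the same rule
serves every statistic in the package so significance stars mean one thing.
Under the null hypothesis each ant allocates scans in proportion to overall
task demand; the number of realized links is free, so null connectance may
differ from the data — that is a property of the null, not an error.

## Nestedness (WNODF)

For the matrix sorted by decreasing fill (number of non-zero cells), margin
totals breaking ties, an ordered row pair (u above v) scores 0 unless v has
strictly fewer realized cells than u, and otherwise scores
100 · #{j : 0 < A_vj < A_uj} / fill(v); columns symmetric. WNODFr/WNODFc are
the means of row/column pair scores, WNODF the mean over all pairs. These
conventions follow the reference implementation (vegan's `nestednodf` with
`weighted = TRUE`), against which the implementation was verified exactly on
random matrices during development; the shipped test suite checks it against
an independent brute-force pairwise oracle instead, so no R dependency
remains. Ties in fill score 0 by the strict inequality, which makes the
statistic invariant to input row/column order. Significance uses the same
fixed-margin null and upper-tail add-one rule as modularity.

## Module network and specialization scores

* q_ij = (total weight from module i's ants into module j's behaviour-nodes)
  / (number of ants in module i): a per-individual mean, matching the
  arrow-width reading of module-network figures. The label-propagation
  search can produce modules containing only behaviour-nodes; their q rows
  are undefined and reported as NaN (an exact integer accounting identity,
  Σ_j q_ij · |module i| = weight emitted by module i, is asserted in tests).
* c_i = 1 − Σ_j (d_ij/d_i)², with d_ij the ant's weight into module j.
  Range [0, 1 − 1/N_M]; 0 iff the ant works only inside one module, the
  upper bound iff its weight is spread exactly evenly across modules.
* d′ is the standardized Kullback–Leibler specialization: raw
  d = Σ_j p_j ln(p_j/q_j) with p the ant's use proportions and q the
  availability proportions, rescaled by the attainable extremes for the
  ant's integer total: d_max concentrates the weight on the column least
  used by others (availabilities recomputed under the reallocation), d_min
  comes from a largest-remainder proportional allocation refined by
  single-unit moves. Both heuristics match exhaustive enumeration of all
  allocations on small margins in the test suite; d′ is clipped to [0, 1]
  and defined as 0 when the range degenerates (e.g. a single column). A
  module specialist (c = 0) need not be an information-theoretic specialist
  (d′ = 1) — the suite carries an explicit counterexample.

## Day/night and age analyses

`split_by_period` maps slots {9,12,15,18} to daytime and {21,0,3,6} to
nighttime (each ant-day contributes at most 4 scans per period). On the
behaviour × period network, `period_mixing` reports, per behaviour observed
in both periods, whether its day and night nodes share a module, and the
fraction of modules containing nodes of both periods; behaviours seen in
only one period are excluded and listed. The default day/night columns
aggregate the 3 days; behaviour × period × day is available through the
general column machinery if finer resolution is wanted.

Ages among modules are compared with the Steel–Dwass all-pairs procedure:
each pair's tie-corrected standardized rank-sum statistic t is referred to
the studentized range distribution via q = √2·|t| with the number of groups
as range parameter (df = 10⁶ as the large-sample reference, since the exact
statistic is asymptotic anyway). When either group has fewer than 8 members
the reference switches to a seeded permutation distribution (10 000
permutations by default). A compact letter display is built as a greedy
clique cover of the non-significant-pair graph at α = 0.05 (groups share a
letter iff their difference is not significant — asserted as a property
test). The same machinery compares c-scores among modules.

Behaviour-proportion regressions are ordinary least squares of (executions /
scans observed, 24 for a complete record) on age in days; slope, R², p and
the 95% slope CI are reported. Ages of cohort-marked ants should be entered
as cohort midpoints in days by the data preparer.

## Synthetic colonies

The generator emulates the study design: n_ants (default 60, within the
33–122 range of real analysed colonies), 3 days × 8 slots, one behaviour per
detected scan, detection probability 0.95 (real matrices are incomplete),
ages uniform on 0–365 days (≈ the species' lifespan). Each ant draws a
latent role (nurse 0.30, forager 0.25, walker 0.20, inactive specialist
0.15, generalist 0.10) with a role-specific propensity vector over the six
behaviours, chosen to caricature monomorphic ponerine colonies. Age enters
only through an exponential tilt exp(k·(age − mid)/365) multiplying the
foraging propensity and dividing the brood-care and inactive propensities
(default k = 1.5, which yields foraging-age slopes of a few 10⁻⁴ per day,
the order seen in real colonies); setting k = 0 gives an age-independent
colony, so one knob spans both the planted-polyethism and the
no-age-signal regimes. Circadian modulation multiplies foraging and walking
by 1 + A·cos(2π(slot − 13.5)/24) (A = 0 by default: the package's own
day/night analysis of the default colony is a true negative control). Scans
are exchangeable by default; a Markov persistence parameter exists but
defaults to 0, because the analyses treat scans as counts.

What passing synthetic tests show: the pipeline recovers planted role
partitions (ARI ≥ 0.9 when roles are ≥ 0.92 concentrated), detects planted
age coupling, and does not hallucinate day/night structure that is not
there. What they do not show: real colonies have behavioural persistence,
context-dependent task switching, spatial structure and demographic
turnover that the generator deliberately omits; results on real data depend
on those, and on censoring choices (queen, lost tags) exposed as flags.

## Problem sizes and reproducibility

Default analyses (60-ant colony, 20 restarts, 1000 nulls with 2 restarts
each) run in seconds on one core; the test suite uses 20-seed batches for
stochastic claims and small matrices wherever an exhaustive oracle is the
comparator. Every stochastic entry point takes a seed, and derived child
seeds are spawned deterministically, so identical configs + seeds give
identical outputs (asserted byte-for-byte on pipeline CSVs).

## Known limitations

* Exact reproduction of published modularity values for the deposited
  colonies is restart-count dependent (the original analysis does not state
  how many searches were run); modularity comparisons should use stochastic
  tolerances.
* The q matrix and c-score depend on the detected partition; with near-tied
  optima, different seeds can flip borderline module assignments.
* The Steel–Dwass asymptotic reference is anticonservative for very small
  groups; the permutation fallback handles those, at a computational cost.
* Binary nestedness variants (NODF on presence/absence, WINE, temperature)
  and unipartite/overlapping community detection are out of scope.
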