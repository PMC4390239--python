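# Methods

## Association model

Association is sampled by the gambit of the group: all individuals
identified within one group encounter are scored as associated, and the
encounter is the sampling unit throughout (no daily or temporal pooling
of encounters). For a dyad (a, b), X counts encounters containing both,
Y_a those containing a only, Y_b those containing b only, and the
half-weight association index is HWI = X / (X + 0.5 (Y_a + Y_b)).
Equivalently HWI = 2X / (n_a + n_b) where n_i is the individual's
encounter count in the analysed set; the implementation uses this form,
stored at full float precision (rounding happens only in reports). A
dyad with X = Y_a = Y_b = 0 has no defined index; by convention 0 is
returned. Such dyads cannot arise when the analysed ids come from the
catalogue itself, since every catalogued individual has at least one
sighting.

Only permanently marked individuals enter the network analysis (their
identities are stable across years); all of them are included regardless
of sighting frequency, because the object of inference is the community,
not the dyad.

## Communities

A community is operationalised as a connected component of the HWI >
threshold graph, with threshold 0 by default (an edge iff the pair ever
co-occurred). No modularity or clustering algorithm is applied: the
target structure is fully separated components, and a cut at HWI > 0
finds exactly those. Components are labelled A, B, C, … by decreasing
size, ties broken by lexicographically smallest member id, making the
labelling total and deterministic ("A" is always the largest
community).

Secondary assignment: a temporarily or superficially marked individual
is assigned to a community iff the set of community labels of all
permanently marked individuals it ever shared an encounter with has
exactly one element; with zero or several labels it is reported
UNASSIGNED (an explicit outcome, never silently dropped). Co-occurrence
(X ≥ 1), not HWI magnitude, is the criterion — the rule is about who the
associates are, not how strong the bond is.

## Contingency statistics

Pearson chi-square without continuity correction:
E_ij = R_i C_j / N, χ² = Σ (O − E)²/E, df = (r−1)(c−1), p from the
chi-square upper tail (`scipy.stats.chi2.sf`). The no-correction choice
was validated by recomputing published pairwise 2×2 statistics from
their count margins; with Yates correction the values do not reproduce.
A continuity-corrected variant is deliberately not offered as a default
anywhere. Tables with a zero row or column margin raise (single tables)
or are reported untestable (pairwise batches), never silently skipped.

Pairwise community comparisons use one 2×2 test per unordered community
pair on a binary feature (permanently marked vs other grades, or
dorsal-tip damage vs none). The Bonferroni denominator defaults to the
number of pairs actually tested (10 for five communities, 5 choose 2);
an explicit `n_comparisons_override` reproduces other conventions (such
as a denominator of 9 seen in some published tables). Significance
flags compare full-precision p to the corrected alpha; reports print p
to 3 decimals.

Known discrepancies in the published table this machinery was checked
against: one cell prints "P = 0.201" for χ = 5.4 with df 1, whose upper
tail is actually ≈ 0.020 (evidently a typo; the package reports the
computed p); two cells print 0.67 and 4.9 where the margins give 0.679
(→ 0.68) and 5.00. The published tip-damage statistic (χ = 23.4,
N = 152) cannot be reconstructed unambiguously from the printed
marginal percentages (which imply denominators 192/94 and a statistic
near 30.7), so it is not used as a check; the package simply computes
the test from the data it is given.

## Spatial comparison

Distances are great-circle km on a sphere of radius 6371.0088 km (IUGG
mean). Point-to-coastline distance is the minimum over polyline
segments evaluated in a local equirectangular projection centred on the
query point, floored by the exact haversine distances to the vertices
(the projection can overestimate by a few tenths of a percent at
100+ km; vertex distances are exact, so the reported distance never
exceeds them). Distances supplied in the input CSV always take
precedence over computed ones.

The inshore/offshore comparison treats the encounter as the sampling
unit (the per-encounter distance is one observation). Each encounter is
attributed to a grouping side by the majority community membership of
its identified individuals; exact ties and encounters with no labelled
members are excluded and counted in the summary. The test is a
two-sided Mann-Whitney U: exact null distribution when n1·n2 ≤ 400 and
the pooled sample is tie-free, otherwise a normal approximation with
tie and continuity corrections (`scipy.stats.mannwhitneyu` supplies
both). `mann_whitney_u` reports U for its first sample (wins count 1,
ties 0.5); the encounter-level comparison reports U for the side with
the larger rank sum — the convention under which complete separation of
the two distance distributions prints the maximal U = n1·n2, matching
how such results are conventionally quoted.

## Synthetic data generator

The generator emulates a two-community coastal study design:

* **Fluid (inshore) community** — default 192 individuals over 56
  encounters. Group sizes are lognormal with observed-scale mean 10.4
  and SD 11.1 (the lognormal is parameterised by moment matching),
  rounded and truncated to [1, n]; members are drawn uniformly without
  replacement per encounter (a null fission-fusion model: the analyses
  depend only on co-membership topology, so no dyadic preference
  structure is simulated; an optional gregariousness weight vector is
  accepted). Mark grades are drawn per individual with probabilities
  72/192, 74/192, 46/192 (permanent/temporary/superficial), tip damage
  with probability 0.07. Encounter distances are |N(0.61, 0.61)| km
  clipped to [0.05, 3.0]; encounters fall in two coastal areas with
  probabilities 47/56 and 9/56.

  Uniform membership draws leave a small probability that some sighted
  permanent individual shares no encounter with another permanent
  individual, which would split the association graph and contradict
  the cohesive-community structure the generator is defined to produce.
  The generator therefore finishes with a minimal *fusion repair*: each
  stray permanent component has one member added to one encounter of
  the main component (one extra identification per stray component,
  drawn from the community's own stream). After repair, the sighted
  permanent members form exactly one connected component — cohesion is
  a guaranteed property of the fluid model, not a typical-case outcome.

* **Transient (offshore) community** — default 94 individuals in 4
  encounters. Encounters partition the individuals, each sighted
  exactly once. The configured group sizes (8, 9, 30, 33) specify the
  number of *permanently marked* members per encounter: grades are
  drawn first (probabilities 80/94, 8/94, 6/94; tip damage 0.48), then
  permanent and non-permanent individuals are allocated to encounters
  by largest-remainder quotas proportional to the configured sizes, so
  the permanent group sizes are exactly 8/9/30/33 whenever the realised
  permanent count is 80. Distances are uniform on [4.6, 40.5] km.

With cross-community co-membership probability 0 (the default) no
encounter mixes communities, so community detection recovers the true
partition exactly in every replicate: one inshore component plus one
component per transient encounter (five in the default configuration).
Each transient encounter is recorded as its own true sub-community in
the ground truth for precisely this reason. A positive
cross-community probability injects one foreign individual per selected
encounter and destroys the separation, which the `sweep` recovery
report quantifies.

Randomness: one root `SeedSequence` per run, spawned into one child
stream per community plus one for cross-community mixing, so editing
one community's spec leaves the other communities' draws unchanged.
The catalogue contains exactly the individuals identified at least once
(about 4–5 % of the default inshore community is never sighted, so a
default run catalogues ~280 of the 286 generated individuals).

What the generator does **not** emulate: dyadic association
preferences within a community, temporal autocorrelation or seasonal
structure in encounters, mark-grade transitions over time,
heterogeneous per-encounter detectability (beyond a global capture
probability), and spatially explicit movement. Passing recovery tests
therefore show that the pipeline correctly recovers separated
co-membership structure at study scale — not that it would resolve
weakly separated or preference-structured real populations.

## Numerical and reporting conventions

* Percentages in summaries are rounded half-up to integers (reporting
  style); raw fractions are retained alongside. Computed values are
  reported even where a published source rounds differently (e.g.
  52/286 = 18.2 % superficial prints as 18 %, though "19 %" appears in
  some published text).
* Group-size SD is the sample SD (ddof = 1).
* The photo-quality filter is a pass-through mechanism: rank 1 is
  best, identifications with rank worse than the configured threshold
  are dropped, and identifications without a recorded rank are kept.
  No quality criteria are operationalised.
* Analytic pipeline outputs contain no timestamps; reruns on identical
  input and configuration are byte-identical.

## Problem sizes used in the test suite

Oracle-equivalence checks run on randomly drawn catalogues of ≤ 20
individuals and ≤ 50 encounters (100 fixtures); partition-recovery
checks run the full default study-scale configuration for 20 seeds;
replicated sweep tests use a scaled-down two-community configuration
(30 + 12 individuals) with 10 replicates. The exact Mann-Whitney check
enumerates every tie-free rank configuration with n1 + n2 ≤ 10.

## Limitations

* Community detection is connected components; populations whose
  communities overlap socially (non-zero between-community association)
  need a modularity- or likelihood-based method, for which the
  partition interface leaves room but which is not shipped.
* No permutation tests for preferred/avoided associations, lagged
  association rates, or standardised/simple-ratio indices.
* The Mann-Whitney exact method refuses tied data rather than
  enumerating the conditional distribution with ties.
* Published U statistics for the group-size and distance comparisons
  depend on unpublished raw per-encounter values and an unstated
  direction convention; they are reproduced structurally (U = n1·n2
  under complete separation) rather than checked numerically.
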