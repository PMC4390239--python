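# podnet

Social-structure analysis for photo-identification sighting records of
cetaceans (or any animals individually identifiable from natural marks).
Starting from a long-format sighting table — one row per individual
identified within a group encounter — the package computes pairwise
half-weight association indices, partitions the association network into
communities, assigns less reliably marked individuals to communities
through their associates, compares fin-marking composition between
communities with chi-square contingency tests, and tests
inshore/offshore spatial segregation with a Mann-Whitney U test on
encounter distances from shore. A synthetic fission-fusion data
generator with ground truth makes the whole pipeline testable without
field data.

It is aimed at behavioural ecologists running photo-ID catalogues of
coastal dolphin populations, where the question is whether the animals
encountered form one community or several spatially and socially
segregated ones.

## The model

Individuals identified in the same group are taken to be associated
(the *gambit of the group*). For a dyad (a, b), over the analysed
encounter set, let *X* be the number of groups containing both, *Y_a*
the number containing a but not b, and *Y_b* the number containing b but
not a. The half-weight association index is

```
HWI = X / (X + 0.5 (Y_a + Y_b))
```

ranging from 0 (never associated) to 1 (always associated). The
sociogram has an edge wherever HWI exceeds a threshold (default 0, i.e.
any co-occurrence); a *community* is a connected component of that
graph, labelled A, B, C, … by decreasing size. Only permanently marked
individuals — those whose fin scars persist across years — enter the
network analysis; a temporarily or superficially marked individual is
then assigned to a community iff **all** of its permanently marked
associates belong to that one community, and is otherwise UNASSIGNED.

Community composition (permanent-mark share, dorsal-fin tip damage) is
compared between communities with Pearson chi-square tests (no
continuity correction) under a Bonferroni correction; spatial
segregation is tested on encounter-level distances from shore.

## Worked example

```
$ podnet simulate --defaults --seed 1 --out sim/
281 individuals, 60 encounters, 735 identifications; grades {'PERMANENT': 153, 'TEMPORARY': 73, 'SUPERFICIAL': 55}

$ podnet analyze --sightings sim/sightings.csv --out report/
wrote 15 files to report
communities: {'A': 68, 'B': 35, 'C': 32, 'D': 10, 'E': 8}
```

The simulated study contains one cohesive inshore community surveyed
over 56 encounters plus four transient offshore groups seen once each.
`analyze` recovers five communities: the large resighted inshore
network A and four offshore networks B–E whose members are never
resighted. The report directory contains the catalogue summary
(JSON), the association matrix (long and square CSV), the sociogram
(GraphML, with community labels, mark grades and tip-damage flags as
node attributes), the community partition (CSV with PRIMARY/SECONDARY
provenance), mark-severity composition tables, the lower-triangular
pairwise chi-square table, and the distance-from-shore comparison. In
this run the distance test gives U = 224 with n1 = 56, n2 = 4 — complete
separation of inshore (≤ 3 km) and offshore (≥ 4.6 km) encounters.

The same analyses are available as library functions
(`podnet.association_matrix`, `podnet.detect_communities`,
`podnet.pairwise_network_tests`, `podnet.compare_group_distances`, …)
for use on real catalogues.

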